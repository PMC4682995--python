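"""Exception hierarchy for modcal."""


class ModcalError(Exception):
    """Base class for all modcal errors."""


class ConfigurationError(ModcalError):
    """Invalid algorithm name, settings or distribution arguments."""


class InputError(ModcalError, ValueError):
    """Invalid user input (dimension mismatch, out-of-range argument)."""


class UndefinedObjectiveError(ModcalError):
    """Objective is mathematically undefined for the given series
    (zero variance, zero mean denominator, too few finite pairs)."""


class DataError(ModcalError):
    """Schema mismatch or empty/inconsistent result store."""


class DegenerateGeometryError(ModcalError):
    """Retained point cloud too small for depth-based candidate generation."""
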