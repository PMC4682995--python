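"""Goodness-of-fit measures between an evaluation series and a simulation.

Eleven objective functions share the signature ``objective(o, s) -> float``
where ``o`` is the observed (evaluation) series and ``s`` the simulated
series of equal length.  Non-finite entries are removed pairwise before
any computation; if fewer than two pairs remain the objective is
undefined.

Sign conventions
----------------
* ``bias`` is observation minus simulation: positive means the model
  underestimates on average.
* Error measures (``rmse``, ``rrmse``, ``mae``, ``drmse``) are
  non-negative with 0 = perfect fit; the sampling engine negates them
  when the setup direction is "minimize", so internally a larger score
  is always better.
* ``nse`` and ``ai`` equal 1 for a perfect fit; ``nse`` is 0 when the
  simulation is the observed mean.

``drmse`` decomposes the mean squared error into a squared-bias term, a
variance-mismatch term ``(sigma_s - sigma_o)^2`` and a phase term
``2*sigma_s*sigma_o*(1 - r)`` (Kobayashi-Salam decomposition); the
scalar objective returns sqrt of the total, the components are exposed
through :func:`drmse_components`.

All objectives are registered by lower-case name in :data:`OBJECTIVES`.
"""

from __future__ import annotations

from typing import Callable

import numpy as np

from .errors import InputError, UndefinedObjectiveError

__all__ = [
    "OBJECTIVES",
    "MINIMIZED",
    "get_objective",
    "bias",
    "nse",
    "lognse",
    "r",
    "r2",
    "cov",
    "drmse",
    "drmse_components",
    "rrmse",
    "rmse",
    "mae",
    "ai",
]


def _paired(o, s, min_pairs: int = 2) -> tuple[np.ndarray, np.ndarray]:
    # moment-free measures (bias, error family, AI) remain defined for a
    # single pair — benchmark surfaces compare length-1 series — while
    # the variance-based measures need at least two
    o = np.asarray(o, dtype=float).ravel()
    s = np.asarray(s, dtype=float).ravel()
    if o.shape != s.shape:
        raise InputError(
            f"evaluation and simulation lengths differ: {o.size} vs {s.size}"
        )
    keep = np.isfinite(o) & np.isfinite(s)
    if keep.sum() < min_pairs:
        raise UndefinedObjectiveError(
            f"fewer than {min_pairs} finite pairs remain after paired "
            f"deletion ({int(keep.sum())} of {o.size})"
        )
    return o[keep], s[keep]


def bias(o, s) -> float:
    """Mean error, observation minus simulation."""
    o, s = _paired(o, s, min_pairs=1)
    return float(np.mean(o - s))


def nse(o, s) -> float:
    """Nash-Sutcliffe efficiency: 1 - SSE / variance-of-observations."""
    o, s = _paired(o, s)
    denom = np.sum((o - o.mean()) ** 2)
    if denom == 0:
        raise UndefinedObjectiveError("NSE undefined for constant observations")
    return float(1.0 - np.sum((o - s) ** 2) / denom)


def lognse(o, s, epsilon: float | None = None) -> float:
    """NSE of log-transformed series; a small offset guards zeros.

    The default offset is 1e-6 times the largest absolute observation.
    """
    o, s = _paired(o, s)
    if epsilon is None:
        epsilon = 1e-6 * float(np.max(np.abs(o))) or 1e-6
    if np.any(o + epsilon <= 0) or np.any(s + epsilon <= 0):
        raise UndefinedObjectiveError("logNSE requires positive offset series")
    return nse(np.log(o + epsilon), np.log(s + epsilon))


def r(o, s) -> float:
    """Pearson correlation coefficient."""
    o, s = _paired(o, s)
    so, ss = o.std(), s.std()
    if so == 0 or ss == 0:
        raise UndefinedObjectiveError("correlation undefined for constant series")
    return float(np.mean((o - o.mean()) * (s - s.mean())) / (so * ss))


def r2(o, s) -> float:
    """Coefficient of determination (square of Pearson's r)."""
    return r(o, s) ** 2


def cov(o, s) -> float:
    """Covariance with population divisor T."""
    o, s = _paired(o, s)
    return float(np.mean((o - o.mean()) * (s - s.mean())))


def rmse(o, s) -> float:
    """Root mean squared error."""
    o, s = _paired(o, s, min_pairs=1)
    return float(np.sqrt(np.mean((s - o) ** 2)))


def rrmse(o, s) -> float:
    """Relative RMSE in percent of the observed mean."""
    o, s = _paired(o, s, min_pairs=1)
    om = o.mean()
    if om == 0:
        raise UndefinedObjectiveError("rRMSE undefined for zero-mean observations")
    return float(100.0 * np.sqrt(np.mean((s - o) ** 2)) / om)


def mae(o, s) -> float:
    """Mean absolute error."""
    o, s = _paired(o, s, min_pairs=1)
    return float(np.mean(np.abs(s - o)))


def drmse_components(o, s) -> dict[str, float]:
    """MSE decomposition into bias^2, (sigma_s-sigma_o)^2 and phase terms.

    Returns a dict with keys ``bias_squared``, ``variance_mismatch``,
    ``phase`` and ``total`` (= MSE); the three components sum to the
    total exactly.
    """
    o, s = _paired(o, s, min_pairs=1)
    so, ss = o.std(), s.std()
    b2 = (s.mean() - o.mean()) ** 2
    vm = (ss - so) ** 2
    if so == 0 or ss == 0:
        rr = 0.0
    else:
        rr = float(np.mean((o - o.mean()) * (s - s.mean())) / (so * ss))
    phase = 2.0 * ss * so * (1.0 - rr)
    return {
        "bias_squared": float(b2),
        "variance_mismatch": float(vm),
        "phase": float(phase),
        "total": float(b2 + vm + phase),
    }


def drmse(o, s) -> float:
    """Decomposed RMSE scalar: sqrt of the decomposition total (= RMSE)."""
    return float(np.sqrt(drmse_components(o, s)["total"]))


def ai(o, s) -> float:
    """Willmott agreement index, 1 = perfect fit, 0 = total disagreement."""
    o, s = _paired(o, s, min_pairs=1)
    om = o.mean()
    denom = np.sum((np.abs(s - om) + np.abs(o - om)) ** 2)
    if denom == 0:
        raise UndefinedObjectiveError(
            "agreement index undefined: both series constant at the observed mean"
        )
    return float(1.0 - np.sum((o - s) ** 2) / denom)


#: registry of the eleven named objectives
OBJECTIVES: dict[str, Callable] = {
    "bias": bias,
    "nse": nse,
    "lognse": lognse,
    "r": r,
    "r2": r2,
    "cov": cov,
    "drmse": drmse,
    "rrmse": rrmse,
    "rmse": rmse,
    "mae": mae,
    "ai": ai,
}

#: objectives whose natural direction is "smaller is better"
MINIMIZED = frozenset({"bias", "drmse", "rrmse", "rmse", "mae"})


def get_objective(name: str) -> Callable:
    """Look up an objective by its lower-case registry name."""
    try:
        return OBJECTIVES[name.lower()]
    except KeyError:
        raise InputError(
            f"unknown objective {name!r}; known: {sorted(OBJECTIVES)}"
        ) from None
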