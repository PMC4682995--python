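"""Prior distributions for calibratable parameters.

Eight named prior families are supported; each is addressable by a
lower-case name and backed by the corresponding ``scipy.stats``
distribution.  Canonical parameterizations:

===========  =======================  =========================
name         dist_args                scipy backend
===========  =======================  =========================
uniform      low, high                ``uniform(low, high-low)``
normal       mean, sd                 ``norm(mean, sd)``
lognormal    mean_log, sd_log         ``lognorm(sd_log, scale=exp(mean_log))``
chisquare    df                       ``chi2(df)``
exponential  rate                     ``expon(scale=1/rate)``
gamma        shape, scale             ``gamma(shape, scale=scale)``
wald         mean, scale              ``invgauss(mean/scale, scale=scale)``
weibull      shape, scale             ``weibull_min(shape, scale=scale)``
===========  =======================  =========================

``wald`` is the inverse-Gaussian distribution.  A plug-in hook is
provided through :func:`register_distribution` for user-defined priors.

When a :class:`~modcal.core.ParameterSpec` carries hard bounds that are
tighter than the distribution's support, sampling uses rejection so no
probability mass piles up on the bounds.
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np
from scipy import stats

from .errors import ConfigurationError, InputError

__all__ = [
    "DISTRIBUTIONS",
    "make_frozen",
    "register_distribution",
    "sample_prior",
    "quantile",
    "cdf",
]


def _uniform(low: float, high: float):
    if not low < high:
        raise ConfigurationError(f"uniform requires low < high, got ({low}, {high})")
    return stats.uniform(loc=low, scale=high - low)


def _normal(mean: float, sd: float):
    if sd <= 0:
        raise ConfigurationError(f"normal requires sd > 0, got {sd}")
    return stats.norm(loc=mean, scale=sd)


def _lognormal(mean_log: float, sd_log: float):
    if sd_log <= 0:
        raise ConfigurationError(f"lognormal requires sd_log > 0, got {sd_log}")
    return stats.lognorm(s=sd_log, scale=float(np.exp(mean_log)))


def _chisquare(df: float):
    if df <= 0:
        raise ConfigurationError(f"chisquare requires df > 0, got {df}")
    return stats.chi2(df)


def _exponential(rate: float):
    if rate <= 0:
        raise ConfigurationError(f"exponential requires rate > 0, got {rate}")
    return stats.expon(scale=1.0 / rate)


def _gamma(shape: float, scale: float):
    if shape <= 0 or scale <= 0:
        raise ConfigurationError(f"gamma requires shape, scale > 0, got ({shape}, {scale})")
    return stats.gamma(shape, scale=scale)


def _wald(mean: float, scale: float):
    if mean <= 0 or scale <= 0:
        raise ConfigurationError(f"wald requires mean, scale > 0, got ({mean}, {scale})")
    return stats.invgauss(mean / scale, scale=scale)


def _weibull(shape: float, scale: float):
    if shape <= 0 or scale <= 0:
        raise ConfigurationError(f"weibull requires shape, scale > 0, got ({shape}, {scale})")
    return stats.weibull_min(shape, scale=scale)


#: registry mapping distribution name -> factory(dist_args) -> frozen scipy dist
DISTRIBUTIONS: dict[str, Callable] = {
    "uniform": _uniform,
    "normal": _normal,
    "lognormal": _lognormal,
    "chisquare": _chisquare,
    "exponential": _exponential,
    "gamma": _gamma,
    "wald": _wald,
    "weibull": _weibull,
}


def register_distribution(name: str, factory: Callable) -> None:
    """Register a custom prior family.

    ``factory(*dist_args)`` must return an object with ``rvs``, ``ppf``
    and ``cdf`` methods (a frozen scipy distribution qualifies).
    """
    DISTRIBUTIONS[name.lower()] = factory


def make_frozen(kind: str, dist_args: Sequence[float]):
    """Build the frozen scipy distribution for a named prior."""
    try:
        factory = DISTRIBUTIONS[kind.lower()]
    except KeyError:
        raise ConfigurationError(
            f"unknown distribution {kind!r}; known: {sorted(DISTRIBUTIONS)}"
        ) from None
    return factory(*dist_args)


def sample_prior(spec, n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw ``n`` values from a parameter's prior.

    Values outside the spec's hard bounds (if any) are rejected and
    redrawn, so the returned sample follows the prior truncated to
    ``[low, high]``.
    """
    if n < 1:
        raise InputError(f"n must be >= 1, got {n}")
    frozen = spec.frozen
    out = np.asarray(frozen.rvs(size=n, random_state=rng), dtype=float)
    lo, hi = spec.low, spec.high
    if lo is None and hi is None:
        return out
    lo_ = -np.inf if lo is None else lo
    hi_ = np.inf if hi is None else hi
    for _ in range(1000):
        bad = (out < lo_) | (out > hi_)
        if not bad.any():
            return out
        out[bad] = frozen.rvs(size=int(bad.sum()), random_state=rng)
    raise ConfigurationError(
        f"could not sample parameter {spec.name!r} within bounds "
        f"[{lo_}, {hi_}] after 1000 rejection rounds; prior mass in the "
        "bounds appears to be negligible"
    )


def quantile(spec, q) -> np.ndarray | float:
    """Inverse CDF of the (untruncated) prior at probability ``q``."""
    q_arr = np.asarray(q, dtype=float)
    if np.any(q_arr < 0) or np.any(q_arr > 1):
        raise InputError(f"quantile probability must lie in [0, 1], got {q}")
    res = spec.frozen.ppf(q_arr)
    return float(res) if np.isscalar(q) or q_arr.ndim == 0 else res


def cdf(spec, x) -> np.ndarray | float:
    """CDF of the (untruncated) prior at ``x``."""
    res = spec.frozen.cdf(np.asarray(x, dtype=float))
    return float(res) if np.isscalar(x) else res
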