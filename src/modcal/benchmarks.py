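"""Built-in calibration fixtures.

Three analytic benchmark surfaces — Rosenbrock, 2-D Griewank and the
d-dimensional Ackley function — wrapped as :class:`ModelSetup` objects
whose "simulation" returns the single function value, whose evaluation
series is ``[0]`` and whose objective is RMSE (minimized).  The RMSE
against the zero target then equals the function value itself, so the
engine score is the negated surface.

A fourth fixture is a synthetic single-reservoir soil-moisture model:
a bucket with storage S (mm) forced by a seeded intermittent rainfall
series and a seasonal sinusoidal potential evapotranspiration,

    S[t+1] = max(0, S[t] + P[t] - k*S[t] - c*PET[t]*min(1, S[t]/100))

with outflow rate k (1/day), initial storage S0 (mm) and ET
coefficient c (-).  Observations are the storage trace at a known true
parameter set plus additive Gaussian noise, which makes parameter
recovery and GLUE coverage exactly checkable.

Fixtures are addressable by registry name: ``rosenbrock``, ``griewank``,
``ackley:<d>``, ``reservoir``.
"""

from __future__ import annotations

import math

import numpy as np

from .core import ModelSetup, ParameterSpec
from .errors import InputError

__all__ = [
    "rosenbrock",
    "griewank2d",
    "ackley",
    "rosenbrock_setup",
    "griewank_setup",
    "ackley_setup",
    "make_reservoir_setup",
    "reservoir_simulate",
    "get_setup",
    "SETUPS",
]

ROSENBROCK_BOUND = 10.0
GRIEWANK_BOUND = 50.0
ACKLEY_BOUND = 32.768


# ---------------------------------------------------------------------------
# Analytic surfaces
# ---------------------------------------------------------------------------

def rosenbrock(x: float, y: float) -> float:
    """Rosenbrock banana valley on [-10, 10]^2; zero only at (1, 1)."""
    if not (-ROSENBROCK_BOUND <= x <= ROSENBROCK_BOUND
            and -ROSENBROCK_BOUND <= y <= ROSENBROCK_BOUND):
        raise InputError(f"({x}, {y}) outside [-10, 10]^2")
    return (1.0 - x) ** 2 + 100.0 * (y - x * x) ** 2


def griewank2d(x, y,
               cos_args: tuple[float, float] = (math.sqrt(2.0), math.sqrt(3.0))
               ):
    """2-D Griewank surface on [-50, 50]^2; zero at the origin.

    Many regularly spaced local minima surround the global optimum.
    ``cos_args`` are the divisors inside the two cosines; the default
    (sqrt(2), sqrt(3)) can be overridden (e.g. to the (sqrt(1),
    sqrt(2)) convention) — the optimum at (0, 0) and the multimodal
    structure hold under either choice.  Accepts scalars or
    broadcastable arrays (handy for grid evaluation).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.any(np.abs(x) > GRIEWANK_BOUND) or np.any(np.abs(y) > GRIEWANK_BOUND):
        raise InputError("coordinates outside [-50, 50]^2")
    ax, ay = cos_args
    out = ((x * x + y * y) / 4000.0
           - np.cos(x / ax) * np.cos(y / ay) + 1.0)
    return float(out) if out.ndim == 0 else out


def ackley(x) -> float:
    """d-dimensional Ackley function on [-32.768, 32.768]^d.

    f(x) = -20 exp(-0.2 sqrt(mean(x_i^2))) - exp(mean(cos(2 pi x_i)))
           + 20 + e; zero at the origin for every d, with a narrow
    central funnel surrounded by regular local minima.
    """
    x = np.asarray(x, dtype=float).ravel()
    if x.size < 1:
        raise InputError("ackley needs at least one coordinate")
    if np.any(np.abs(x) > ACKLEY_BOUND):
        raise InputError(f"coordinates outside [-{ACKLEY_BOUND}, {ACKLEY_BOUND}]")
    d = x.size
    term1 = -20.0 * math.exp(-0.2 * math.sqrt(float(np.sum(x * x)) / d))
    term2 = -math.exp(float(np.sum(np.cos(2.0 * math.pi * x))) / d)
    return term1 + term2 + 20.0 + math.e


# ---------------------------------------------------------------------------
# ModelSetup wrappers
# ---------------------------------------------------------------------------
# module-level simulation callables keep the setups picklable for the
# process-parallel evaluator

def _sim_rosenbrock(theta):
    return [rosenbrock(theta[0], theta[1])]


def _sim_griewank(theta):
    return [griewank2d(theta[0], theta[1])]


def _sim_ackley(theta):
    return [ackley(theta)]


def rosenbrock_setup() -> ModelSetup:
    """2-D Rosenbrock calibration problem (RMSE vs the zero target).

    Both parameters use step 1.5 and start at 3.0 — a moderate jump
    scale (7.5% of the range) and a start well away from the optimum.
    """
    pars = [
        ParameterSpec("x", "uniform", (-10.0, 10.0), step=1.5, optguess=3.0),
        ParameterSpec("y", "uniform", (-10.0, 10.0), step=1.5, optguess=3.0),
    ]
    return ModelSetup(pars, _sim_rosenbrock, [0.0], "rmse", "minimize")


def griewank_setup() -> ModelSetup:
    """2-D Griewank calibration problem on [-50, 50]^2."""
    pars = [
        ParameterSpec("x", "uniform", (-50.0, 50.0), step=2.5, optguess=20.0),
        ParameterSpec("y", "uniform", (-50.0, 50.0), step=2.5, optguess=20.0),
    ]
    return ModelSetup(pars, _sim_griewank, [0.0], "rmse", "minimize")


def ackley_setup(d: int = 30) -> ModelSetup:
    """d-dimensional Ackley calibration problem."""
    if d < 1:
        raise InputError("ackley dimension must be >= 1")
    pars = [
        ParameterSpec(f"x{i}", "uniform", (-ACKLEY_BOUND, ACKLEY_BOUND),
                      step=1.5, optguess=10.0)
        for i in range(d)
    ]
    return ModelSetup(pars, _sim_ackley, [0.0], "rmse", "minimize")


# ---------------------------------------------------------------------------
# Synthetic reservoir fixture
# ---------------------------------------------------------------------------

RESERVOIR_BOUNDS = {"k": (0.01, 0.5), "S0": (0.0, 100.0), "c": (0.0, 1.0)}
_RES_DAYS = 365
_CAPACITY = 100.0  # mm; storage scale for ET limitation


def _reservoir_forcing(seed: int, days: int = _RES_DAYS):
    """Seeded daily rainfall (intermittent exponential) and seasonal PET."""
    rng = np.random.default_rng(seed)
    wet = rng.uniform(size=days) < 0.3
    rain = np.where(wet, rng.exponential(scale=5.0, size=days), 0.0)
    t = np.arange(days)
    pet = 2.0 + 1.5 * np.sin(2.0 * math.pi * (t - 90) / 365.0)
    return rain, pet


def reservoir_simulate(theta, rain: np.ndarray, pet: np.ndarray) -> np.ndarray:
    """Daily storage trace of the bucket model for theta = (k, S0, c)."""
    k, s0, c = float(theta[0]), float(theta[1]), float(theta[2])
    storage = np.empty(rain.size)
    s = s0
    for t in range(rain.size):
        et = c * pet[t] * min(1.0, s / _CAPACITY)
        s = max(0.0, s + rain[t] - k * s - et)
        storage[t] = s
    return storage


class _ReservoirSim:
    """Picklable simulation closure over the forcing series."""

    def __init__(self, rain, pet):
        self.rain = rain
        self.pet = pet

    def __call__(self, theta):
        return reservoir_simulate(theta, self.rain, self.pet)


def make_reservoir_setup(true_theta=(0.1, 40.0, 0.5), noise_sd: float = 1.0,
                         seed: int = 0) -> ModelSetup:
    """Reservoir calibration problem with known truth.

    Observations are the noiseless storage trace at ``true_theta``
    plus N(0, noise_sd^2) noise; with ``noise_sd=0`` the truth
    reproduces its observations exactly (RMSE 0).  The returned setup
    carries ``true_theta`` as an attribute for recovery checks.
    """
    true_theta = np.asarray(true_theta, dtype=float)
    if noise_sd < 0:
        raise InputError("noise_sd must be >= 0")
    for val, (name, (lo, hi)) in zip(true_theta, RESERVOIR_BOUNDS.items()):
        if not lo <= val <= hi:
            raise InputError(f"true {name} = {val} outside [{lo}, {hi}]")
    rain, pet = _reservoir_forcing(seed)
    sim = _ReservoirSim(rain, pet)
    clean = sim(true_theta)
    rng = np.random.default_rng(seed + 1)
    obs = clean + (rng.normal(scale=noise_sd, size=clean.size) if noise_sd else 0.0)
    pars = [
        ParameterSpec(name, "uniform", (lo, hi))
        for name, (lo, hi) in RESERVOIR_BOUNDS.items()
    ]
    setup = ModelSetup(pars, sim, obs, "rmse", "minimize")
    setup.true_theta = true_theta
    return setup


# ---------------------------------------------------------------------------
# Registry
# ---------------------------------------------------------------------------

SETUPS = {
    "rosenbrock": rosenbrock_setup,
    "griewank": griewank_setup,
    "ackley": ackley_setup,
    "reservoir": make_reservoir_setup,
}


def get_setup(name: str) -> ModelSetup:
    """Build a fixture by registry name; ``ackley:<d>`` selects dimension."""
    name = name.lower()
    if name.startswith("ackley"):
        _, _, d = name.partition(":")
        return ackley_setup(int(d) if d else 30)
    try:
        return SETUPS[name]()
    except KeyError:
        raise InputError(
            f"unknown setup {name!r}; known: {sorted(SETUPS)} (ackley:<d>)"
        ) from None
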