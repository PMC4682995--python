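"""Model-setup contract and the sampling engine shared by all algorithms.

A calibration problem is described by a :class:`ModelSetup`: an ordered
list of :class:`ParameterSpec` (name, prior, proposal step, start
point, bounds), a ``simulation`` callable mapping a parameter vector to
a series of simulated values, a fixed ``evaluation`` series of
observations, a named (or callable) objective function and an
optimization ``direction``.

The engine internally always MAXIMIZES a scalar score.  When
``direction`` is ``"minimize"`` the objective value is negated, so an
error measure such as RMSE becomes a score ranging from minus infinity
(total disagreement) to 0 (perfect fit).

Model evaluations are funnelled through an :class:`Evaluator`:
:class:`SequentialEvaluator` runs them in-process;
:class:`MultiprocessingEvaluator` fans a batch out to worker processes
and returns results in submission order, so deterministic setups give
identical results on either backend.  Algorithms that carry serial
Markov state (MLE, MCMC, SA) only accept the sequential backend.
"""

from __future__ import annotations

import logging
import math
from concurrent.futures import ProcessPoolExecutor
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from . import distributions as dists
from .errors import ConfigurationError, InputError
from .objectives import MINIMIZED, OBJECTIVES, get_objective

logger = logging.getLogger("modcal")

__all__ = [
    "ParameterSpec",
    "ModelSetup",
    "RunConfig",
    "Evaluator",
    "SequentialEvaluator",
    "MultiprocessingEvaluator",
    "MPIEvaluator",
    "evaluate_batch",
    "run_sampler",
    "sample",
]


@dataclass
class ParameterSpec:
    """One calibratable parameter.

    Parameters
    ----------
    name:
        Unique identifier; used for database column naming.
    distribution:
        Prior family name (see :mod:`modcal.distributions`).
    dist_args:
        Distribution parameters in the canonical parameterization.
    step:
        Proposal scale used by the random-walk samplers (MLE, MCMC, SA)
        to jump to the next point.  Defaults to the prior's standard
        deviation divided by 10 (or 5% of the bound range for uniform).
    optguess:
        Start point for the walkers; defaults to the prior median.
    low, high:
        Optional hard bounds; proposals outside are resampled.
    """

    name: str
    distribution: str = "uniform"
    dist_args: tuple = (0.0, 1.0)
    step: float | None = None
    optguess: float | None = None
    low: float | None = None
    high: float | None = None

    def __post_init__(self):
        self.distribution = self.distribution.lower()
        self.frozen = dists.make_frozen(self.distribution, self.dist_args)
        if self.distribution == "uniform" and self.low is None and self.high is None:
            self.low, self.high = float(self.dist_args[0]), float(self.dist_args[1])
        if self.low is not None and self.high is not None and not self.low < self.high:
            raise ConfigurationError(
                f"parameter {self.name!r}: low must be < high, got "
                f"({self.low}, {self.high})"
            )
        if self.step is None:
            if self.low is not None and self.high is not None:
                self.step = 0.05 * (self.high - self.low)
            else:
                self.step = float(self.frozen.std()) / 10.0
        if self.step <= 0:
            raise ConfigurationError(f"parameter {self.name!r}: step must be > 0")
        if self.optguess is None:
            self.optguess = float(self.frozen.median())
        if self.low is not None and self.optguess < self.low or (
            self.high is not None and self.optguess > self.high
        ):
            raise ConfigurationError(
                f"parameter {self.name!r}: optguess {self.optguess} outside "
                f"bounds [{self.low}, {self.high}]"
            )

    # convenience passthroughs
    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        return dists.sample_prior(self, n, rng)

    def quantile(self, q):
        return dists.quantile(self, q)

    def cdf(self, x):
        return dists.cdf(self, x)


@dataclass
class ModelSetup:
    """The black-box calibration problem.

    ``simulation(theta)`` must return a finite series whose length
    matches ``evaluation`` (unless the objective is length-free).
    ``objective`` is a registry name, a callable ``(o, s) -> float``,
    or a list of either; with several objectives the FIRST drives all
    algorithmic decisions and the rest are recorded alongside.
    ``direction`` defaults to the natural direction of the first named
    objective (minimize for error measures, maximize otherwise).
    """

    parameters: Sequence[ParameterSpec]
    simulation: Callable[[np.ndarray], Sequence[float]]
    evaluation: Sequence[float]
    objective: object = "rmse"
    direction: str | None = None

    def __post_init__(self):
        names = [p.name for p in self.parameters]
        if len(set(names)) != len(names):
            raise ConfigurationError(f"duplicate parameter names: {names}")
        self.evaluation = np.asarray(self.evaluation, dtype=float)
        objs = self.objective if isinstance(self.objective, (list, tuple)) else [self.objective]
        self._objectives: list[Callable] = []
        self._objective_names: list[str] = []
        for ob in objs:
            if callable(ob):
                self._objectives.append(ob)
                self._objective_names.append(getattr(ob, "__name__", "custom"))
            else:
                self._objectives.append(get_objective(ob))
                self._objective_names.append(ob.lower())
        if self.direction is None:
            first = self._objective_names[0]
            self.direction = "minimize" if first in MINIMIZED else "maximize"
        if self.direction not in ("minimize", "maximize"):
            raise ConfigurationError(f"direction must be minimize|maximize, got {self.direction!r}")

    # ---- engine-facing helpers -------------------------------------
    @property
    def dim(self) -> int:
        return len(self.parameters)

    @property
    def names(self) -> list[str]:
        return [p.name for p in self.parameters]

    @property
    def n_objectives(self) -> int:
        return len(self._objectives)

    @property
    def objective_names(self) -> list[str]:
        return list(self._objective_names)

    def lower_bounds(self) -> np.ndarray:
        return np.array([-np.inf if p.low is None else p.low for p in self.parameters])

    def upper_bounds(self) -> np.ndarray:
        return np.array([np.inf if p.high is None else p.high for p in self.parameters])

    def optguess(self) -> np.ndarray:
        return np.array([p.optguess for p in self.parameters], dtype=float)

    def steps(self) -> np.ndarray:
        return np.array([p.step for p in self.parameters], dtype=float)

    def sample_priors(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """n x dim matrix of independent prior draws."""
        return np.column_stack([p.sample(n, rng) for p in self.parameters])

    def in_bounds(self, theta: np.ndarray) -> bool:
        theta = np.asarray(theta, dtype=float)
        return bool(
            np.all(theta >= self.lower_bounds()) and np.all(theta <= self.upper_bounds())
        )

    def likes(self, sim) -> list[float]:
        """All objective values for one simulation (raw, not negated)."""
        return [ob(self.evaluation, sim) for ob in self._objectives]

    def score(self, like1: float) -> float:
        """Engine score (maximized) from the first objective value."""
        return -like1 if self.direction == "minimize" else like1


@dataclass
class RunConfig:
    """Run-level plumbing: budget, seed and database choice."""

    repetitions: int = 1000
    seed: int = 42
    db_name: str = "modcal_run"
    db_format: str = "ram"
    save_simulations: bool = False

    def __post_init__(self):
        if self.repetitions < 1:
            raise ConfigurationError("repetitions must be >= 1")
        if self.db_format not in ("ram", "csv"):
            raise ConfigurationError(f"db_format must be ram|csv, got {self.db_format!r}")


# ---------------------------------------------------------------------------
# Evaluators
# ---------------------------------------------------------------------------

class Evaluator:
    """Batch-evaluation contract: simulations in submission order."""

    #: whether stateful serial algorithms may use this backend
    parallel = False

    def map(self, simulation: Callable, thetas: Sequence[np.ndarray]) -> list:
        raise NotImplementedError

    def close(self):  # pragma: no cover - trivial
        pass


class SequentialEvaluator(Evaluator):
    """In-process evaluation, one theta at a time."""

    def map(self, simulation, thetas):
        return [simulation(np.asarray(t, dtype=float)) for t in thetas]


class MultiprocessingEvaluator(Evaluator):
    """Process-pool evaluation; results are returned in job order."""

    parallel = True

    def __init__(self, workers: int = 2):
        if workers < 1:
            raise ConfigurationError("workers must be >= 1")
        self._pool = ProcessPoolExecutor(max_workers=workers)

    def map(self, simulation, thetas):
        thetas = [np.asarray(t, dtype=float) for t in thetas]
        return list(self._pool.map(simulation, thetas))

    def close(self):
        self._pool.shutdown()


class MPIEvaluator(Evaluator):  # pragma: no cover - optional adapter
    """Optional MPI adapter over mpi4py; untested stub for HPC use."""

    parallel = True

    def __init__(self):
        try:
            from mpi4py import MPI  # noqa: F401
        except ImportError as exc:
            raise ConfigurationError(
                "MPIEvaluator requires the optional mpi4py package"
            ) from exc
        from mpi4py.futures import MPIPoolExecutor

        self._pool = MPIPoolExecutor()

    def map(self, simulation, thetas):
        return list(self._pool.map(simulation, [np.asarray(t) for t in thetas]))

    def close(self):
        self._pool.shutdown()


def evaluate_batch(evaluator: Evaluator, setup: ModelSetup, thetas) -> list:
    """Run the setup's simulation for each theta, preserving order."""
    thetas = [np.asarray(t, dtype=float) for t in thetas]
    for t in thetas:
        if t.shape != (setup.dim,):
            raise InputError(
                f"theta has shape {t.shape}, expected ({setup.dim},)"
            )
    if not thetas:
        return []
    return evaluator.map(setup.simulation, thetas)


# ---------------------------------------------------------------------------
# Proposal helper shared by the random-walk samplers
# ---------------------------------------------------------------------------

def propose_gaussian(
    setup: ModelSetup,
    center: np.ndarray,
    rng: np.random.Generator,
    scale: float = 1.0,
    max_tries: int = 1000,
) -> np.ndarray:
    """Symmetric Gaussian jump from ``center`` with per-dimension step.

    Out-of-bounds proposals are redrawn (up to ``max_tries``) rather
    than clipped, so no probability mass accumulates on the bounds.
    """
    steps = setup.steps() * scale
    lo, hi = setup.lower_bounds(), setup.upper_bounds()
    for _ in range(max_tries):
        cand = center + rng.normal(size=setup.dim) * steps
        if np.all(cand >= lo) and np.all(cand <= hi):
            return cand
    # pathological geometry: fall back to a prior draw
    return setup.sample_priors(1, rng)[0]


# ---------------------------------------------------------------------------
# Engine loop
# ---------------------------------------------------------------------------

class Recorder:
    """Budget accounting + database writing used by every algorithm.

    ``submit`` evaluates a batch of parameter vectors through the
    evaluator, computes the objective(s), appends one record per theta
    and returns the engine scores (maximized orientation).  A failing
    simulation is logged and skipped; it still consumes budget.
    """

    def __init__(self, setup: ModelSetup, store, evaluator: Evaluator, repetitions: int):
        self.setup = setup
        self.store = store
        self.evaluator = evaluator
        self.repetitions = repetitions
        self.evaluations = 0
        self.best_score = -math.inf
        self.best_theta: np.ndarray | None = None

    @property
    def remaining(self) -> int:
        return self.repetitions - self.evaluations

    def evaluate_only(self, thetas) -> list[tuple[float, list | None, object]]:
        """Evaluate a batch without writing records.

        Returns ``(score, likes, sim)`` per theta; consumes budget and
        updates the best-so-far.  A failing simulation is logged,
        skipped (score ``-inf``) and still consumes budget.
        """
        thetas = [np.asarray(t, dtype=float) for t in thetas]
        try:
            sims = evaluate_batch(self.evaluator, self.setup, thetas)
        except InputError:
            raise
        except Exception:
            # batch backends may fail wholesale; retry one at a time
            sims = []
            for t in thetas:
                try:
                    sims.append(self.setup.simulation(t))
                except Exception as exc:  # skip-and-log
                    logger.warning("simulation failed for theta=%s: %s", t, exc)
                    sims.append(None)
        out: list[tuple[float, list | None, object]] = []
        for theta, sim in zip(thetas, sims):
            self.evaluations += 1
            if sim is None:
                out.append((-math.inf, None, None))
                continue
            try:
                likes = self.setup.likes(sim)
            except Exception as exc:
                logger.warning("objective failed for theta=%s: %s", theta, exc)
                out.append((-math.inf, None, None))
                continue
            score = self.setup.score(likes[0])
            if score > self.best_score:
                self.best_score = score
                self.best_theta = theta.copy()
            out.append((score, likes, sim))
        return out

    def record(self, likes, theta, sim, chain: int = 0) -> None:
        """Write one record (used by chain samplers that repeat states)."""
        self.store.append(likes, theta, sim, chain)

    def submit(self, thetas, chains=None) -> list[float]:
        """Evaluate a batch and record every successful evaluation."""
        thetas = [np.asarray(t, dtype=float) for t in thetas]
        if chains is None:
            chains = [0] * len(thetas)
        results = self.evaluate_only(thetas)
        scores: list[float] = []
        for theta, chain, (score, likes, sim) in zip(thetas, chains, results):
            if likes is not None:
                self.store.append(likes, theta, sim, chain)
            scores.append(score)
        return scores

    def submit_one(self, theta, chain: int = 0) -> float:
        return self.submit([theta], [chain])[0]


def run_sampler(
    setup: ModelSetup,
    algorithm: str,
    settings=None,
    config: RunConfig | None = None,
    evaluator: Evaluator | None = None,
):
    """Run a named algorithm on a setup and return the ResultStore.

    ``algorithm`` is one of the registry names (``mc``, ``lhs``,
    ``mle``, ``mcmc``, ``sceua``, ``sa``, ``demcz``, ``rope``).
    """
    from .algorithms import ALGORITHMS, PARALLEL_CAPABLE, AlgorithmSettings
    from .database import ResultStore

    config = config or RunConfig()
    algorithm = algorithm.lower()
    if algorithm not in ALGORITHMS:
        raise ConfigurationError(
            f"unknown algorithm {algorithm!r}; known: {sorted(ALGORITHMS)}"
        )
    evaluator = evaluator or SequentialEvaluator()
    if evaluator.parallel and algorithm not in PARALLEL_CAPABLE:
        raise ConfigurationError(
            f"algorithm {algorithm!r} carries serial chain state and only "
            "accepts the sequential evaluator"
        )
    settings = settings or AlgorithmSettings.for_setup(setup)
    store = ResultStore(
        objective_names=[f"like{i + 1}" for i in range(setup.n_objectives)],
        parameter_names=setup.names,
        n_simulation=len(setup.evaluation) if config.save_simulations else 0,
        backend=config.db_format,
        path=config.db_name + ".csv" if config.db_format == "csv" else None,
    )
    rng = np.random.default_rng(config.seed)
    rec = Recorder(setup, store, evaluator, config.repetitions)
    ALGORITHMS[algorithm](setup, rec, settings, rng)
    store.finalize()
    return store


def sample(setup, algorithm="mc", repetitions=1000, seed=42, settings=None,
           evaluator=None, db_format="ram", db_name="modcal_run",
           save_simulations=False):
    """Convenience wrapper around :func:`run_sampler`."""
    cfg = RunConfig(repetitions=repetitions, seed=seed, db_name=db_name,
                    db_format=db_format, save_simulations=save_simulations)
    return run_sampler(setup, algorithm, settings=settings, config=cfg,
                       evaluator=evaluator)
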