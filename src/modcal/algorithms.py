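"""The eight parameter search / uncertainty algorithms.

Registry names: ``mc``, ``lhs``, ``mle``, ``mcmc``, ``sceua``, ``sa``,
``demcz``, ``rope``.  Every algorithm draws its candidates from the
setup's priors (or by jumps whose scale is the per-parameter ``step``),
funnels all model evaluations through the engine's
:class:`~modcal.core.Recorder` (which enforces the repetition budget
and writes the database) and maximizes the engine score — error
objectives arrive already negated.

Acceptance rules for stochastic moves use ``exp(score_new -
score_old)``, i.e. the score is treated as a log-likelihood.  With an
error objective this is a decreasing-error acceptance; the mapping is
scale-free and numerically stable, and documented here because the
choice of likelihood map materially shapes MCMC/SA behaviour.

Which backends an algorithm accepts: population methods (``mc``,
``lhs``, ``sceua``, ``demcz``, ``rope``) work with any evaluator;
``mle``, ``mcmc`` and ``sa`` carry serial chain state and reject
parallel backends.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np

from .core import ModelSetup, Recorder, propose_gaussian
from .errors import ConfigurationError, DegenerateGeometryError

__all__ = ["ALGORITHMS", "PARALLEL_CAPABLE", "AlgorithmSettings"]


@dataclass
class AlgorithmSettings:
    """Per-algorithm tuning constants.

    Defaults follow the package's standard settings: MLE/MCMC dedicate
    10% of the repetitions to burn-in; SCE-UA uses ngs = 2*dim
    complexes with kstop=50, pcento=1e-5, peps=1e-4; SA starts at
    temperature 10, reduced by factor 0.99 every 10 trials; DE-MC_Z
    runs max(3, 2*dim) chains with DEpairs=2, thin=1, eps=0.04; ROPE
    runs 5 subsets retaining the best 5%.

    ``convergence_criterion`` (0.9) is stored verbatim for
    compatibility but is not an R-hat threshold (R-hat >= 1 by
    construction); DE-MC_Z convergence checks use ``r_hat_threshold``
    and only stop the run early when ``stop_on_convergence`` is set.
    """

    # MLE / MCMC
    burn_in: float = 0.10
    # SCE-UA
    ngs: int | None = None          # complexes; default 2*dim
    kstop: int = 50
    pcento: float = 1e-5
    peps: float = 1e-4
    # SA
    tini: float = 10.0
    ntemp: int = 10
    alpha: float = 0.99
    # DE-MC_Z
    n_chains: int | None = None     # default max(3, 2*dim)
    de_pairs: int = 2
    thin: int = 1
    eps: float = 0.04
    convergence_criterion: float = 0.9
    r_hat_threshold: float = 1.2
    stop_on_convergence: bool = False
    auto_adapt: bool = True
    # ROPE
    subsets: int = 5
    percentage: float = 0.05
    depth_projections: int | None = None  # default 100*dim

    def __post_init__(self):
        if not 0 < self.burn_in < 1:
            raise ConfigurationError("burn_in must lie in (0, 1)")
        if self.ngs is not None and self.ngs < 1:
            raise ConfigurationError("ngs must be >= 1")
        if not 0 < self.alpha < 1:
            raise ConfigurationError("alpha must lie in (0, 1)")
        if self.n_chains is not None and self.n_chains < 3:
            raise ConfigurationError("DE-MC_Z requires at least 3 chains")
        if not 0 < self.percentage < 1:
            raise ConfigurationError("percentage must lie in (0, 1)")
        if self.subsets < 2:
            raise ConfigurationError("subsets must be >= 2")

    @classmethod
    def for_setup(cls, setup: ModelSetup, **overrides) -> "AlgorithmSettings":
        """Defaults with the dim-dependent values resolved for a setup."""
        s = cls(**overrides)
        if s.ngs is None:
            s.ngs = 2 * setup.dim
        if s.n_chains is None:
            s.n_chains = max(3, 2 * setup.dim)
        if s.depth_projections is None:
            s.depth_projections = 100 * setup.dim
        return s


# ---------------------------------------------------------------------------
# Monte Carlo & Latin Hypercube
# ---------------------------------------------------------------------------

def mc(setup: ModelSetup, rec: Recorder, settings: AlgorithmSettings,
       rng: np.random.Generator) -> None:
    """Plain Monte-Carlo sampling of the priors."""
    while rec.remaining > 0:
        n = min(rec.remaining, 1000)
        rec.submit(setup.sample_priors(n, rng))


def lhs(setup: ModelSetup, rec: Recorder, settings: AlgorithmSettings,
        rng: np.random.Generator) -> None:
    """Latin hypercube sampling.

    Each prior is subdivided into m = repetitions equally probable,
    non-overlapping intervals; exactly one draw falls in each interval,
    with independent per-parameter permutations.
    """
    m = rec.remaining
    cols = []
    for p in setup.parameters:
        perm = rng.permutation(m)
        q = (perm + rng.uniform(size=m)) / m
        cols.append(p.quantile(q))
    thetas = np.column_stack(cols)
    for start in range(0, m, 1000):
        rec.submit(thetas[start:start + 1000])


# ---------------------------------------------------------------------------
# Hill climbing / Metropolis / annealing (serial walkers)
# ---------------------------------------------------------------------------

def _burn_in_phase(setup, rec, settings, rng):
    """Prior-draw warm-up shared by MLE and MCMC; returns the best state."""
    nburn = math.ceil(settings.burn_in * rec.repetitions)
    nburn = min(nburn, rec.remaining)
    rec.store.burn_in = nburn
    best = (-math.inf, None, None, None)  # score, likes, theta, sim
    for _ in range(nburn):
        theta = setup.sample_priors(1, rng)[0]
        (score, likes, sim), = rec.evaluate_only([theta])
        if likes is not None:
            rec.record(likes, theta, sim, 0)
            if score > best[0]:
                best = (score, likes, theta, sim)
    if best[1] is None:
        raise ConfigurationError("all burn-in simulations failed")
    return best


def mle(setup: ModelSetup, rec: Recorder, settings: AlgorithmSettings,
        rng: np.random.Generator) -> None:
    """Maximum-likelihood hill climber.

    After the burn-in (prior draws, best one taken as the start) the
    incumbent only moves to proposals with a non-worse score; the
    recorded trace therefore is non-decreasing after burn-in.
    """
    score, likes, theta, sim = _burn_in_phase(setup, rec, settings, rng)
    while rec.remaining > 0:
        cand = propose_gaussian(setup, theta, rng)
        (s_new, l_new, sim_new), = rec.evaluate_only([cand])
        if l_new is not None and s_new >= score:
            score, likes, theta, sim = s_new, l_new, cand, sim_new
        rec.record(likes, theta, sim, 0)


def mcmc(setup: ModelSetup, rec: Recorder, settings: AlgorithmSettings,
         rng: np.random.Generator) -> None:
    """Standard Metropolis sampler with symmetric Gaussian proposals.

    Proposal scale per dimension is the parameter's ``step``.  Rejected
    proposals repeat the current state in the database, so the stored
    trace is the Markov chain itself.
    """
    score, likes, theta, sim = _burn_in_phase(setup, rec, settings, rng)
    while rec.remaining > 0:
        cand = propose_gaussian(setup, theta, rng)
        (s_new, l_new, sim_new), = rec.evaluate_only([cand])
        if l_new is not None and math.log(rng.uniform()) < s_new - score:
            score, likes, theta, sim = s_new, l_new, cand, sim_new
        rec.record(likes, theta, sim, 0)


def sa_temperature(trials: int, tini: float = 10.0, ntemp: int = 10,
                   alpha: float = 0.99) -> float:
    """Annealing temperature after ``trials`` trials.

    The temperature starts at ``tini`` and is multiplied by ``alpha``
    after every ``ntemp`` trials: T = tini * alpha**(trials // ntemp).
    """
    return tini * alpha ** (trials // ntemp)


def sa(setup: ModelSetup, rec: Recorder, settings: AlgorithmSettings,
       rng: np.random.Generator) -> None:
    """Simulated annealing with a Boltzmann acceptance rule.

    The temperature starts at ``tini`` and is multiplied by ``alpha``
    after every ``ntemp`` trials.  A worse candidate is accepted with
    probability exp(-delta/T); when a candidate is rejected the next
    proposal is drawn fresh from the priors instead of around the
    incumbent (the sampler "jumps to a new parameter value").
    """
    theta = setup.optguess()
    (score, likes, sim), = rec.evaluate_only([theta])
    if likes is None:
        raise ConfigurationError("simulation failed at the optimal guess")
    rec.record(likes, theta, sim, 0)
    trials = 1
    jump_from_prior = False
    while rec.remaining > 0:
        temp = sa_temperature(trials, settings.tini, settings.ntemp,
                              settings.alpha)
        if jump_from_prior:
            cand = setup.sample_priors(1, rng)[0]
        else:
            cand = propose_gaussian(setup, theta, rng)
        (s_new, l_new, sim_new), = rec.evaluate_only([cand])
        accept = False
        if l_new is not None:
            rec.record(l_new, cand, sim_new, 0)
            delta = score - s_new
            accept = delta <= 0 or rng.uniform() < math.exp(-delta / temp)
        if accept:
            score, likes, theta, sim = s_new, l_new, cand, sim_new
            jump_from_prior = False
        else:
            jump_from_prior = True
        trials += 1


# ---------------------------------------------------------------------------
# SCE-UA (shuffled complex evolution)
# ---------------------------------------------------------------------------

def sceua(setup: ModelSetup, rec: Recorder, settings: AlgorithmSettings,
          rng: np.random.Generator) -> None:
    """Shuffled Complex Evolution (Duan et al. formulation).

    ngs complexes of npg = 2*dim+1 points evolve independently by
    competitive complex evolution — simplex reflection / contraction /
    mutation on subcomplexes of dim+1 points chosen with triangular
    probability — and are periodically shuffled.  The search stops when
    the budget is exhausted, the relative improvement over ``kstop``
    shuffling loops falls below ``pcento`` percent, or the normalized
    parameter-space extent of the population falls below ``peps``.
    """
    dim = setup.dim
    ngs = settings.ngs or 2 * dim
    npg = 2 * dim + 1
    nps = dim + 1
    nspl = npg
    npt = ngs * npg
    if rec.repetitions < npt:
        raise ConfigurationError(
            f"SCE-UA needs at least one population: ngs*(2*dim+1) = {npt} "
            f"evaluations, but repetitions = {rec.repetitions}"
        )
    lo, hi = setup.lower_bounds(), setup.upper_bounds()
    bound_range = np.where(np.isfinite(hi - lo), hi - lo, 1.0)

    # initial population: the optimal guess plus prior draws
    x = np.vstack([setup.optguess(), setup.sample_priors(npt - 1, rng)])
    f = np.asarray(rec.submit(x), dtype=float)
    order = np.argsort(-f)  # best first
    x, f = x[order], f[order]

    # triangular selection probabilities over a sorted complex
    weights = 2.0 * (npg - np.arange(npg)) / (npg * (npg + 1))
    criter: list[float] = []

    while rec.remaining > 0:
        for igs in range(ngs):
            idx = igs + ngs * np.arange(npg)   # systematic partition
            cx, cf = x[idx].copy(), f[idx].copy()
            for _ in range(nspl):
                if rec.remaining <= 0:
                    break
                sub = np.sort(rng.choice(npg, size=nps, replace=False, p=weights))
                sx, sf = cx[sub], cf[sub]
                worst = np.argmin(sf)
                others = np.delete(np.arange(nps), worst)
                centroid = sx[others].mean(axis=0)
                cmin, cmax = cx.min(axis=0), cx.max(axis=0)

                def _mutate():
                    return cmin + rng.uniform(size=dim) * (cmax - cmin)

                new = 2.0 * centroid - sx[worst]          # reflection
                if np.any(new < lo) or np.any(new > hi):
                    new = _mutate()
                fnew = rec.submit_one(new, chain=igs + 1)
                if fnew <= sf[worst] and rec.remaining > 0:
                    new = 0.5 * (centroid + sx[worst])    # contraction
                    fnew = rec.submit_one(new, chain=igs + 1)
                    if fnew <= sf[worst] and rec.remaining > 0:
                        new = _mutate()                   # forced mutation
                        fnew = rec.submit_one(new, chain=igs + 1)
                cx[sub[worst]], cf[sub[worst]] = new, fnew
                order = np.argsort(-cf)
                cx, cf = cx[order], cf[order]
            x[idx], f[idx] = cx, cf
        order = np.argsort(-f)                            # shuffle
        x, f = x[order], f[order]
        criter.append(f[0])

        # convergence: normalized geometric range of the population
        rng_ext = (x.max(axis=0) - x.min(axis=0)) / bound_range
        gnrng = float(np.exp(np.mean(np.log(np.maximum(rng_ext, 1e-300)))))
        if gnrng < settings.peps:
            break
        # convergence: relative criterion change over kstop loops
        if len(criter) >= settings.kstop:
            window = np.abs(criter[-settings.kstop:])
            denom = float(np.mean(window))
            if denom > 0:
                change = abs(criter[-1] - criter[-settings.kstop]) * 100.0 / denom
                if change < settings.pcento:
                    break


# ---------------------------------------------------------------------------
# DE-MC_Z (differential-evolution Markov chain with archive)
# ---------------------------------------------------------------------------

def demcz(setup: ModelSetup, rec: Recorder, settings: AlgorithmSettings,
          rng: np.random.Generator) -> None:
    """DE-MC with a growing archive of past states (DE-MC_Z).

    N >= 3 chains propose ``x* = x_i + (1+e)*gamma*(sum z_a - sum z_b)
    + nu`` with 2*DEpairs distinct archive members z, ``gamma =
    2.38/sqrt(2*DEpairs*dim)`` (gamma = 1 every 10th generation when
    ``auto_adapt`` is on, enabling mode jumps), the jitter factor ``e ~
    U(-eps, eps)`` and a tiny symmetric noise ``nu`` that keeps the
    proposal density non-degenerate.  Because the jitter multiplies the
    archive differences, proposal scale shrinks with the population —
    the sampler refines automatically as it converges.
    Acceptance is Metropolis; the current states are
    appended to the archive every ``thin`` generations.  Per-parameter
    Gelman-Rubin R-hat is tracked online (``store.gelman_rubin_history``)
    and can optionally stop the run early.
    """
    dim = setup.dim
    n_chains = settings.n_chains or max(3, 2 * dim)
    if n_chains < 3:
        raise ConfigurationError("DE-MC_Z requires at least 3 chains")
    m0 = max(10 * dim, n_chains)
    archive = setup.sample_priors(m0, rng)  # positions only, not evaluated

    states = setup.sample_priors(n_chains, rng)
    results = rec.evaluate_only(states)
    scores = np.full(n_chains, -math.inf)
    likes: list = [None] * n_chains
    sims: list = [None] * n_chains
    for i, (s, l, sm) in enumerate(results):
        scores[i], likes[i], sims[i] = s, l, sm
        if l is not None:
            rec.record(l, states[i], sm, i)

    gamma0 = 2.38 / math.sqrt(2.0 * settings.de_pairs * dim)
    lo, hi = setup.lower_bounds(), setup.upper_bounds()
    history: list[np.ndarray] = [states.copy()]
    rhat_history: list[tuple[int, np.ndarray]] = []
    # one record per chain per generation: cap generations so the record
    # count never exceeds the repetition budget
    max_gen = rec.repetitions // n_chains - 1
    gen = 0
    while rec.remaining > 0 and gen < max_gen:
        gen += 1
        gamma = 1.0 if (settings.auto_adapt and gen % 10 == 0) else gamma0
        cands = np.empty_like(states)
        in_b = np.zeros(n_chains, dtype=bool)
        log_prior_ratio = np.zeros(n_chains)
        for i in range(n_chains):
            # out-of-bounds proposals are resampled, not clipped
            for _ in range(1000):
                if rng.uniform() < 0.1:
                    # snooker update along the line to an archive anchor;
                    # essential for elongated (banana-shaped) targets
                    zi = rng.choice(len(archive), size=3, replace=False)
                    anchor, z1, z2 = archive[zi]
                    line = states[i] - anchor
                    norm2 = float(line @ line)
                    if norm2 == 0:
                        continue
                    proj = ((z1 - z2) @ line) / norm2 * line
                    cands[i] = states[i] + rng.uniform(1.2, 2.2) * proj
                    dn = float(np.linalg.norm(cands[i] - anchor))
                    do = float(np.linalg.norm(states[i] - anchor))
                    if dn == 0 or do == 0:
                        continue
                    log_prior_ratio[i] = (dim - 1) * (math.log(dn) - math.log(do))
                else:
                    zi = rng.choice(len(archive), size=2 * settings.de_pairs,
                                    replace=False)
                    za = archive[zi[: settings.de_pairs]].sum(axis=0)
                    zb = archive[zi[settings.de_pairs:]].sum(axis=0)
                    jitter = 1.0 + rng.uniform(-settings.eps, settings.eps,
                                               size=dim)
                    cands[i] = (states[i] + jitter * gamma * (za - zb)
                                + rng.normal(scale=1e-9, size=dim))
                    log_prior_ratio[i] = 0.0
                if np.all(cands[i] >= lo) and np.all(cands[i] <= hi):
                    in_b[i] = True
                    break
        eval_idx = [i for i in range(n_chains) if in_b[i]][: max(rec.remaining, 0)]
        results = rec.evaluate_only(cands[eval_idx]) if eval_idx else []
        for i, (s_new, l_new, sim_new) in zip(eval_idx, results):
            if l_new is not None and math.log(rng.uniform()) < (
                s_new - scores[i] + log_prior_ratio[i]
            ):
                scores[i], likes[i], sims[i] = s_new, l_new, sim_new
                states[i] = cands[i]
        for i in range(n_chains):
            if likes[i] is not None:
                rec.record(likes[i], states[i], sims[i], i)
        if gen % settings.thin == 0:
            archive = np.vstack([archive, states])
        history.append(states.copy())

        if gen % 10 == 0 and len(history) >= 20:
            from .analyser import gelman_rubin

            half = np.asarray(history[len(history) // 2:])  # (n, m, dim)
            chains = np.moveaxis(half, 1, 0)                # (m, n, dim)
            try:
                rhat = gelman_rubin(chains)
            except Exception:
                rhat = np.full(dim, np.inf)
            rhat_history.append((rec.evaluations, np.asarray(rhat)))
            if settings.stop_on_convergence and np.all(
                np.asarray(rhat) < settings.r_hat_threshold
            ):
                break
    rec.store.gelman_rubin_history = rhat_history


# ---------------------------------------------------------------------------
# ROPE (robust parameter estimation via data depth)
# ---------------------------------------------------------------------------

def _approx_depth(points: np.ndarray, proj: np.ndarray, u: np.ndarray,
                  cand: np.ndarray) -> float:
    """Approximate Tukey (halfspace) depth of ``cand`` in ``points``.

    Uses K random projection directions ``u`` (proj = points @ u.T
    precomputed); the depth is the minimum over directions of the
    smaller side count, as a fraction of the cloud size.
    """
    pc = cand @ u.T
    left = (proj <= pc).sum(axis=0)
    right = (proj >= pc).sum(axis=0)
    return float(np.minimum(left, right).min()) / len(points)


def rope(setup: ModelSetup, rec: Recorder, settings: AlgorithmSettings,
         rng: np.random.Generator) -> None:
    """Robust parameter estimation with Tukey data depth.

    The budget is split evenly over ``subsets`` optimization cycles.
    Cycle 1 samples the priors; each later cycle retains the best
    ``percentage`` of all points evaluated so far and generates new
    candidates as random convex combinations of dim+1 retained points,
    kept only if their approximate halfspace depth with respect to the
    retained set is positive.
    """
    dim = setup.dim
    per_subset = rec.repetitions // settings.subsets
    if per_subset < 1:
        raise ConfigurationError("repetitions too small for the ROPE subsets")
    k_proj = settings.depth_projections or 100 * dim

    thetas = setup.sample_priors(min(per_subset, rec.remaining), rng)
    scores = rec.submit(thetas, chains=[1] * len(thetas))
    all_x = np.asarray(thetas, dtype=float)
    all_f = np.asarray(scores, dtype=float)

    for subset in range(2, settings.subsets + 1):
        if rec.remaining <= 0:
            break
        n_keep = math.ceil(settings.percentage * len(all_x))
        if n_keep < dim + 1:
            raise DegenerateGeometryError(
                f"retained set of {n_keep} point(s) is smaller than dim+1 = "
                f"{dim + 1}; raise `percentage` or the repetition budget"
            )
        keep = np.argsort(-all_f)[:n_keep]
        retained = all_x[keep]
        u = rng.normal(size=(k_proj, dim))
        u /= np.linalg.norm(u, axis=1, keepdims=True)
        proj = retained @ u.T

        n_new = min(per_subset, rec.remaining)
        cands = np.empty((n_new, dim))
        for j in range(n_new):
            for _ in range(1000):
                pick = rng.choice(n_keep, size=dim + 1,
                                  replace=n_keep < dim + 1)
                w = rng.dirichlet(np.ones(dim + 1))
                cand = w @ retained[pick]
                if _approx_depth(retained, proj, u, cand) > 0:
                    cands[j] = cand
                    break
            else:  # pragma: no cover - convex combos essentially always pass
                cands[j] = retained[rng.integers(n_keep)]
        scores = rec.submit(cands, chains=[subset] * n_new)
        all_x = np.vstack([all_x, cands])
        all_f = np.concatenate([all_f, scores])


#: algorithm registry, addressable by lower-case name
ALGORITHMS: dict[str, Callable] = {
    "mc": mc,
    "lhs": lhs,
    "mle": mle,
    "mcmc": mcmc,
    "sceua": sceua,
    "sa": sa,
    "demcz": demcz,
    "rope": rope,
}

#: algorithms that accept any (incl. parallel) evaluator
PARALLEL_CAPABLE = frozenset({"mc", "lhs", "sceua", "demcz", "rope"})
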