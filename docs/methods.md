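# Methods

This note documents the models, algorithmic conventions and numerical
choices behind `modcal`, in the order a user meets them: the black-box
calibration contract, the priors, the objectives, the eight samplers,
the diagnostics, and the built-in fixtures the test-suite and the
acceptance script run on.

## The calibration contract

A problem is a `ModelSetup`: an ordered list of parameters (name,
prior, proposal step, start value, optional hard bounds), a
`simulation` callable θ → S, a fixed evaluation series X, an objective
and a direction.  The engine always **maximizes** a scalar score; when
the direction is `minimize` the first objective value is negated, so an
error measure such as RMSE becomes a score running from −∞ (total
disagreement) to 0 (perfect fit).  Stochastic acceptance rules
(Metropolis, Boltzmann) treat this score as a log-likelihood and use
`exp(score_new − score_old)`.  This map is scale-free and numerically
stable, but it fixes the sharpness of the implied posterior: for the
benchmark surfaces the stationary law of the Metropolis samplers is
∝ exp(−RMSE).  Users calibrating a formal likelihood can pass any
callable `(o, s) -> log-likelihood` as the objective and direction
`maximize`.

Conventions shared by all algorithms:

- `repetitions` counts **model evaluations**, not outer loops;
  population algorithms spend budget per member.
- One root seed per run (`numpy.random.default_rng`); everything
  derives from it, so a fixed seed with the sequential evaluator
  reproduces a run bit-for-bit.
- Proposals falling outside hard bounds are **resampled** (up to 1000
  tries), never clipped, so no probability mass piles up on the
  bounds.  The marginal acceptance bias this introduces is confined to
  states within one proposal scale of a bound; the statistical tests
  place their targets away from bounds.
- A simulation that raises is logged and skipped; it still consumes
  budget.  Long stochastic runs thereby survive isolated model
  failures.
- Multiple objectives may be listed; all are stored (`like1..likeK`)
  but the first drives every algorithmic decision.
- MLE and MCMC write their burn-in draws to the database (the count is
  exposed as `store.burn_in`); the analyser drops burn-in on request
  rather than the sampler hiding it.

## Priors

Eight named families backed by `scipy.stats` with fixed canonical
parameterizations (documented in `modcal.distributions`): uniform(low,
high), normal(mean, sd), lognormal(mean-log, sd-log), chisquare(df),
exponential(rate), gamma(shape, scale), wald = inverse-Gaussian(mean,
scale), weibull(shape, scale).  Latin-hypercube stratification uses
the exact quantile function; bounds tighter than the support are
honoured by rejection sampling.  A registry hook accepts user-defined
families exposing `rvs`/`ppf`/`cdf`.

## Objectives

Eleven measures with the signature `objective(o, s)`; non-finite
entries are deleted pairwise first.  Definitions are the textbook
ones; two conventions deserve note.  `bias` is observation −
simulation, so positive bias means the model underestimates.  `drmse`
uses the Kobayashi–Salam decomposition MSE = (s̄ − ō)² + (σ_s − σ_o)²
+ 2σ_sσ_o(1 − r); the scalar form returns √MSE and the three
components are available separately and sum to the MSE exactly (tested
to 1e-9).  The moment-free measures (bias, RMSE family, MAE, AI)
remain defined for a single pair — the analytic benchmarks compare
length-1 series — while variance-based measures require at least two.
logNSE guards zeros with an offset of 1e-6·max|o| (configurable).

## Algorithms

**mc** — independent prior draws; the reference against which
everything else is judged, and (with **lhs**) the basis for GLUE.

**lhs** — each prior is split into m = repetitions equally probable
intervals; one draw per interval per parameter, permuted independently
per parameter.  Stratification is exact by construction and asserted
in the tests for every prior family.

**mle** — 10% of the budget as prior-draw burn-in, best draw taken as
the incumbent, then Gaussian jumps (per-parameter `step`) accepted
only when not worse.  The recorded trace after burn-in is monotone.

**mcmc** — same burn-in, then standard Metropolis with symmetric
Gaussian proposals scaled by `step`.  Rejected proposals repeat the
current state in the database, so the stored trace is the chain
itself.  Correctness is pinned by two oracles: a 3-cell
piecewise-constant density whose empirical cell frequencies must match
the brute-force normalized density within 2% at 1e5 steps, and a
standard-normal target recovered to mean/sd ±0.05.

**sa** — starts at the optimal guess with temperature Tini = 10,
multiplied by alpha = 0.99 after every Ntemp = 10 trials; worse moves
accepted with probability exp(−Δ/T).  After a rejection the next
candidate is a fresh prior draw rather than a local jump — the sampler
"jumps to a new parameter value" — which makes SA behave like
hill-climbing with restarts on sharply peaked surfaces.

**sceua** — Shuffled Complex Evolution in the standard formulation:
ngs = 2·dim complexes of npg = 2·dim + 1 points, each evolved npg
times per shuffling loop by competitive complex evolution (subcomplex
of dim+1 points chosen with triangular probability; reflection of the
worst through the others' centroid, then contraction, then a forced
random point inside the complex's bounding box).  Termination: budget
exhausted, or best-score change over kstop = 50 loops below pcento =
1e-5 percent, or normalized geometric parameter range of the
population below peps = 1e-4.  The second criterion's denominator is
the mean absolute criterion over the window; when the best score is
exactly 0 the range criterion terminates instead.

**demcz** — differential-evolution Markov chain with a growing archive
of past states.  N = max(3, 2·dim) chains; proposal x* = x +
(1+e)·γ·(Σz_a − Σz_b) + ν with 2·DEpairs = 4 distinct archive members,
γ = 2.38/√(2·DEpairs·dim), jitter factor e ~ U(−0.04, 0.04) and tiny
symmetric noise ν.  The Table of defaults reads eps as a jitter
*factor*, hence multiplicative: proposal scale then shrinks with the
archive spread and the sampler refines automatically.  Every 10th
generation γ = 1 (mode-jumping); with probability 0.1 a snooker update
proposes along the line to a random archive anchor (with the
|x*−z|^(d−1) Metropolis correction), which is what lets chains travel
along elongated valleys.  States are archived every `thin`
generations.  Per-parameter Gelman-Rubin R-hat is computed online on
the second half of the history (`store.gelman_rubin_history`); early
stopping on R-hat < 1.2 is available but off by default, since the
reference behaviour for the benchmark studies is to spend the full
budget.  The Table-1 "convergence criterion 0.9" is stored verbatim in
the settings for compatibility but has no defined meaning for R-hat
(which is ≥ 1) and is unused.

**rope** — robust parameter estimation by data depth.  The budget is
split evenly over 5 subsets; subset 1 samples the priors, each later
subset retains the best 5% of *all* points evaluated so far and
generates candidates as Dirichlet-weighted convex combinations of
dim+1 retained points, accepted only with positive approximate Tukey
depth.  Exact halfspace depth is exponential in dimension, so depth is
approximated with K = 100·dim random projection directions (the
minimum over directions of the smaller side count).  Convex
combinations with strictly positive weights always have positive true
depth; the approximation is asserted in tests.  A retained set smaller
than dim+1 raises a dedicated error advising a larger retention
percentage.

## Analyser

`get_best` (ties: first record wins), `get_posterior` (GLUE: the best
⌈fraction·N⌉ records, default 10%), burn-in removal, chain splitting.
Gelman-Rubin follows the classic two-level formula: W = mean
within-chain variance (divisor n−1), B = n·variance of chain means
(divisor m−1), V̂ = (n−1)/n·W + B/n, R̂ = √(V̂/W); chains of unequal
length are truncated to the shortest.  The Geweke test compares the
first 10% and last 50% of a chain with plain segment variances — a
deliberate simplification of Geweke's spectral-density estimator,
adequate for the gross non-stationarity checks it serves here, and
slightly anti-conservative for strongly autocorrelated chains.
Plotting is minimal (trace panels); the numbers behind every panel are
available as arrays.

## Fixtures and what the tests do (and do not) show

The three analytic surfaces use the conventions stated in the README;
for the Griewank cosine arguments the divisors (√2, √3) are used and
are configurable — the global optimum at the origin and the multimodal
structure are unaffected by that choice, so no result depends on it.
Each surface is wrapped with evaluation series [0] and objective RMSE,
making the RMSE equal to the function value.

The reservoir fixture stands in for a daily soil-moisture column: a
single bucket S (mm) with S(t+1) = max(0, S + P − k·S − c·PET·min(1,
S/100)), forced by a seeded intermittent exponential rainfall (30%
wet days, mean 5 mm) and a seasonal sinusoidal PET (2 ± 1.5 mm/day),
with parameters k ∈ [0.01, 0.5] /day, S₀ ∈ [0, 100] mm, c ∈ [0, 1]
and default truth (0.1, 40, 0.5).  Observations are the noiseless
storage trace at the truth plus Gaussian noise (default sd 1 mm).
This fixture is linear-reservoir simple: it shares with real
soil-moisture calibration the nonlinear parameter interactions of
storage dynamics and seasonal forcing, but none of the structural
error, input error or heteroscedastic observation noise of field
data.  Passing recovery and coverage tests on it demonstrates the
sampling machinery, not field-scale skill.

Problem sizes throughout are the benchmark-study ones — 5,000
repetitions for the 2-D surfaces, 15,000 for the 30-D Ackley runs
(with the ngs = 2 efficiency override), 10-seed (5-seed for 30-D)
medians for every stochastic summary — chosen as the package's
standard desk-scale configuration; the full suite runs in well under
a minute.

## Known limitations

- The score-as-log-likelihood convention means "posterior" spreads
  from the Metropolis samplers depend on the objective's scale; it is
  the user's job to supply a formal likelihood when calibrated
  uncertainty is required.
- Boundary resampling of proposals is not exactly detailed-balanced
  near hard bounds.
- The MPI evaluator is an untested adapter kept for API completeness;
  the process-parallel evaluator is the tested parallel path.
- ROPE's depth is approximate; in high dimensions (≳20) K = 100·dim
  projections can overestimate depth for hull-boundary points.
- Geweke variances are not spectral estimates (see above).
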