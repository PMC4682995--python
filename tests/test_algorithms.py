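"""Behavioural checks of the eight search algorithms."""

import numpy as np
import pytest

import modcal
from modcal import benchmarks
from modcal.algorithms import (
    ALGORITHMS,
    PARALLEL_CAPABLE,
    AlgorithmSettings,
    _approx_depth,
    sa_temperature,
)
from modcal.core import ModelSetup, ParameterSpec
from modcal.errors import ConfigurationError, DegenerateGeometryError

from conftest import first_hit


def _identity_setup(objective, low=-20.0, high=20.0, step=2.4, dim=1):
    """Setup whose 'simulation' is the parameter vector itself, so an
    arbitrary log-density can be calibrated against."""
    pars = [ParameterSpec(f"x{i}", "uniform", (low, high), step=step)
            for i in range(dim)]
    sim = _IdentitySim(dim)
    return ModelSetup(pars, sim, [0.0] * dim, objective, "maximize")


class _IdentitySim:
    def __init__(self, dim):
        self.dim = dim

    def __call__(self, theta):
        return [float(t) for t in theta[: self.dim]]


def test_eight_algorithms_registered():
    assert len(ALGORITHMS) == 8
    assert set(ALGORITHMS) == {"mc", "lhs", "mle", "mcmc", "sceua", "sa",
                               "demcz", "rope"}
    assert PARALLEL_CAPABLE == {"mc", "lhs", "sceua", "demcz", "rope"}


def test_settings_invariants():
    with pytest.raises(ConfigurationError):
        AlgorithmSettings(burn_in=1.5)
    with pytest.raises(ConfigurationError):
        AlgorithmSettings(n_chains=2)
    with pytest.raises(ConfigurationError):
        AlgorithmSettings(percentage=0.0)
    with pytest.raises(ConfigurationError):
        AlgorithmSettings(subsets=1)


# ---------------------------------------------------------------- MC / LHS

def test_mc_marginals_match_prior(rng):
    setup = _identity_setup("mae", low=0.0, high=1.0, dim=1)
    df = modcal.sample(setup, "mc", 10_000, seed=21).getdata()
    from scipy import stats

    stat = stats.kstest(df["parx0"].to_numpy(), "uniform").statistic
    assert stat < 1.628 / np.sqrt(10_000)


@pytest.mark.parametrize("m", [1, 4, 1000])
def test_lhs_stratification_uniform(m):
    setup = _identity_setup("mae", low=0.0, high=1.0, dim=2)
    df = modcal.sample(setup, "lhs", m, seed=5).getdata()
    for col in ("parx0", "parx1"):
        bins = np.floor(df[col].to_numpy() * m).astype(int)
        assert sorted(bins) == list(range(m))


def test_lhs_stratification_under_normal_cdf():
    from scipy import stats

    m = 500
    pars = [ParameterSpec("x", "normal", (3.0, 2.0), step=0.5)]
    setup = ModelSetup(pars, _IdentitySim(1), [0.0], "mae", "minimize")
    df = modcal.sample(setup, "lhs", m, seed=8).getdata()
    q = stats.norm(3.0, 2.0).cdf(df["parx"].to_numpy())
    assert sorted(np.floor(q * m).astype(int)) == list(range(m))


# ---------------------------------------------------------------- MLE

def test_mle_finds_quadratic_optimum_and_is_monotone():
    def neg_quad(o, s):
        return -(s[0] - 3.0) ** 2

    setup = _identity_setup(neg_quad, low=0.0, high=10.0, step=0.5)
    store = modcal.sample(setup, "mle", 2000, seed=3)
    df = store.getdata()
    assert store.burn_in == 200
    assert abs(df["parx0"].iloc[-1] - 3.0) < 0.1
    post = df["like1"].to_numpy()[store.burn_in:]
    assert np.all(np.diff(post) >= 0)


def test_mle_burn_in_count_is_ten_percent(rosen_setup):
    store = modcal.sample(rosen_setup, "mle", 5000, seed=1)
    assert store.burn_in == 500


# ---------------------------------------------------------------- MCMC

def test_mcmc_recovers_standard_normal_target():
    def log_std_normal(o, s):
        return -0.5 * s[0] ** 2

    setup = _identity_setup(log_std_normal, step=2.4)
    df = modcal.sample(setup, "mcmc", 20_000, seed=5).getdata()
    x = df["parx0"].to_numpy()[2000:]
    assert abs(x.mean()) < 0.05
    assert abs(x.std() - 1.0) < 0.05


def test_mcmc_three_state_frequencies_match_bruteforce():
    """Empirical cell frequencies of a piecewise-constant density match
    the normalized density (the brute-force stationary distribution)."""
    weights = np.array([1.0, 2.0, 4.0])

    def log_density(o, s):
        x = s[0]
        if 0 <= x < 3:
            return float(np.log(weights[int(x)]))
        return -1e9

    pars = [ParameterSpec("x", "uniform", (-10.0, 13.0), step=0.8,
                          optguess=1.5)]
    setup = ModelSetup(pars, _IdentitySim(1), [0.0], log_density, "maximize")
    df = modcal.sample(setup, "mcmc", 100_000, seed=11).getdata()
    x = df["parx"].to_numpy()[10_000:]
    x = x[(x >= 0) & (x < 3)]
    freq = np.array([np.mean((x >= i) & (x < i + 1)) for i in range(3)])
    np.testing.assert_allclose(freq, weights / weights.sum(), atol=0.02)


# ---------------------------------------------------------------- SA

def test_sa_temperature_schedule_closed_form():
    # after 10*ntemp trials the temperature is tini*alpha**10
    assert sa_temperature(100, 10.0, 10, 0.99) == pytest.approx(10 * 0.99**10)
    assert sa_temperature(0) == 10.0
    assert sa_temperature(9) == 10.0  # first reduction only after ntemp trials


def test_sa_best_so_far_is_monotone_and_finds_valley(rosen_setup):
    df = modcal.sample(rosen_setup, "sa", 5000, seed=4).getdata()
    best = np.minimum.accumulate(df["like1"].to_numpy())
    assert np.all(np.diff(best) <= 0)
    assert best[-1] < 1.0


# ---------------------------------------------------------------- SCE-UA

def test_sceua_rosenbrock_terminates_early_at_optimum(rosen_setup):
    df = modcal.sample(rosen_setup, "sceua", 5000, seed=1).getdata()
    assert len(df) < 5000          # convergence criteria fired
    assert df["like1"].min() <= 1e-4


def test_sceua_best_score_never_degrades(rosen_setup):
    df = modcal.sample(rosen_setup, "sceua", 2000, seed=6).getdata()
    best = np.minimum.accumulate(df["like1"].to_numpy())
    assert np.all(np.diff(best) <= 0)


def test_sceua_needs_one_population(rosen_setup):
    with pytest.raises(ConfigurationError):
        modcal.sample(rosen_setup, "sceua", 10, seed=1)


# ---------------------------------------------------------------- DE-MC_Z

def test_demcz_rejects_fewer_than_three_chains(rosen_setup):
    with pytest.raises(ConfigurationError):
        AlgorithmSettings(n_chains=2)


def test_demcz_recovers_correlated_gaussian_posterior():
    mu = np.array([1.0, -1.0])
    cov = np.array([[1.0, 0.6], [0.6, 2.0]])
    prec = np.linalg.inv(cov)

    def log_gauss(o, s):
        d = np.array([s[0] - mu[0], s[1] - mu[1]])
        return float(-0.5 * d @ prec @ d)

    pars = [ParameterSpec("a", "uniform", (-15, 15), step=1.0),
            ParameterSpec("b", "uniform", (-15, 15), step=1.0)]
    setup = ModelSetup(pars, _IdentitySim(2), [0.0, 0.0], log_gauss,
                       "maximize")
    df = modcal.sample(setup, "demcz", 30_000, seed=7).getdata()
    x = df[["para", "parb"]].to_numpy()[len(df) // 2:]
    np.testing.assert_allclose(x.mean(axis=0), mu, atol=0.05)
    np.testing.assert_allclose(np.cov(x.T), cov, rtol=0.15)


def test_demcz_tracks_gelman_rubin_online(rosen_setup):
    store = modcal.sample(rosen_setup, "demcz", 2000, seed=2)
    hist = store.gelman_rubin_history
    assert len(hist) > 0
    evals, rhat = hist[-1]
    assert rhat.shape == (2,) and evals <= 2000


# ---------------------------------------------------------------- ROPE

def test_rope_ranges_shrink_across_subsets(rosen_setup):
    df = modcal.sample(rosen_setup, "rope", 5000, seed=2).getdata()
    subsets = sorted(df["chain"].unique())
    assert len(subsets) == 5
    widths = []
    for s in subsets:
        g = df[df["chain"] == s]
        widths.append([g["parx"].max() - g["parx"].min(),
                       g["pary"].max() - g["pary"].min()])
    widths = np.asarray(widths)
    assert np.all(np.diff(widths, axis=0) <= 1e-9)


def test_rope_candidates_have_positive_depth(rng):
    """Convex combinations of dim+1 retained points always carry
    positive approximate halfspace depth; distant points carry none."""
    retained = rng.normal(size=(50, 2))
    u = rng.normal(size=(200, 2))
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    proj = retained @ u.T
    for _ in range(100):
        pick = rng.choice(50, size=3, replace=False)
        w = rng.dirichlet(np.ones(3))
        cand = w @ retained[pick]
        assert _approx_depth(retained, proj, u, cand) > 0
    assert _approx_depth(retained, proj, u, np.array([100.0, 100.0])) == 0.0


def test_rope_centroid_approaches_known_optimum():
    def neg_norm2(o, s):
        return -(s[0] ** 2 + s[1] ** 2)

    setup = _identity_setup(neg_norm2, low=-5.0, high=5.0, dim=2)
    df = modcal.sample(setup, "rope", 5000, seed=9).getdata()
    last = df[df["chain"] == df["chain"].max()]
    centroid = last[["parx0", "parx1"]].mean().to_numpy()
    assert np.linalg.norm(centroid) < 0.2


def test_rope_degenerate_retained_set_raises(rosen_setup):
    settings = AlgorithmSettings.for_setup(rosen_setup, percentage=0.01)
    with pytest.raises(DegenerateGeometryError):
        modcal.sample(rosen_setup, "rope", 200, seed=1, settings=settings)


# ---------------------------------------------------------------- recovery

def test_sceua_recovers_reservoir_parameters_noiseless():
    setup = benchmarks.make_reservoir_setup(noise_sd=0.0)
    df = modcal.sample(setup, "sceua", 5000, seed=3).getdata()
    from modcal import analyser

    pars, score = analyser.get_best(df, "minimize")
    ranges = np.array([hi - lo for lo, hi in
                       benchmarks.RESERVOIR_BOUNDS.values()])
    assert np.all(np.abs(pars - setup.true_theta) / ranges < 0.05)
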