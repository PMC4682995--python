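"""Model-setup contract, evaluators and the engine loop."""

import numpy as np
import pytest

import modcal
from modcal import benchmarks
from modcal.core import (
    ModelSetup,
    MultiprocessingEvaluator,
    ParameterSpec,
    RunConfig,
    SequentialEvaluator,
    evaluate_batch,
)
from modcal.errors import ConfigurationError, InputError


def test_parameter_spec_invariants():
    with pytest.raises(ConfigurationError):
        ParameterSpec("a", "uniform", (0.0, 1.0), step=-0.1)
    with pytest.raises(ConfigurationError):
        ParameterSpec("a", "uniform", (0.0, 1.0), low=2.0, high=1.0)
    with pytest.raises(ConfigurationError):
        ParameterSpec("a", "uniform", (0.0, 1.0), optguess=5.0)
    # defaults: bounds from uniform args, optguess at the median
    p = ParameterSpec("a", "uniform", (0.0, 10.0))
    assert (p.low, p.high) == (0.0, 10.0)
    assert p.optguess == pytest.approx(5.0)
    assert p.step > 0


def test_duplicate_parameter_names_rejected():
    pars = [ParameterSpec("x", "uniform", (0, 1)),
            ParameterSpec("x", "uniform", (0, 1))]
    with pytest.raises(ConfigurationError):
        ModelSetup(pars, lambda t: [t[0]], [0.0], "rmse")


def test_direction_defaults_to_objective_nature():
    pars = [ParameterSpec("x", "uniform", (0, 1))]
    sim = lambda t: [t[0]]
    assert ModelSetup(pars, sim, [0.0], "rmse").direction == "minimize"
    assert ModelSetup(pars, sim, [0.0, 1.0], "nse").direction == "maximize"


def test_evaluate_batch_order_and_errors(rosen_setup):
    assert evaluate_batch(SequentialEvaluator(), rosen_setup, []) == []
    out = evaluate_batch(SequentialEvaluator(), rosen_setup, [(1.0, 1.0)])
    assert out == [[0.0]]
    with pytest.raises(InputError):
        evaluate_batch(SequentialEvaluator(), rosen_setup, [(1.0, 1.0, 1.0)])


def test_parallel_backend_matches_sequential(rosen_setup, rng):
    thetas = rng.uniform(-10, 10, size=(50, 2))
    seq = evaluate_batch(SequentialEvaluator(), rosen_setup, thetas)
    mp = MultiprocessingEvaluator(workers=2)
    try:
        par = evaluate_batch(mp, rosen_setup, thetas)
    finally:
        mp.close()
    assert seq == par


@pytest.mark.parametrize("algorithm", sorted(modcal.ALGORITHMS))
def test_fixed_seed_runs_are_identical(algorithm, rosen_setup):
    """Same seed + sequential evaluator => byte-identical stores."""
    reps = 400
    a = modcal.sample(rosen_setup, algorithm, reps, seed=7).getdata()
    b = modcal.sample(rosen_setup, algorithm, reps, seed=7).getdata()
    assert a.to_csv(index=False) == b.to_csv(index=False)


@pytest.mark.parametrize("algorithm", sorted(modcal.ALGORITHMS))
def test_budget_and_bounds_respected(algorithm, rosen_setup):
    reps = 400
    df = modcal.sample(rosen_setup, algorithm, reps, seed=3).getdata()
    assert 1 <= len(df) <= reps
    assert df["parx"].between(-10, 10).all()
    assert df["pary"].between(-10, 10).all()


def test_mc_exact_repetition_count(rosen_setup):
    df = modcal.sample(rosen_setup, "mc", 100, seed=1).getdata()
    assert len(df) == 100
    df = modcal.sample(rosen_setup, "mc", 1, seed=1).getdata()
    assert len(df) == 1


def test_unknown_algorithm_is_configuration_error(rosen_setup):
    with pytest.raises(ConfigurationError):
        modcal.sample(rosen_setup, "nosuch", 10)


def test_serial_walkers_reject_parallel_evaluator(rosen_setup):
    mp = MultiprocessingEvaluator(workers=2)
    try:
        for algorithm in ("mle", "mcmc", "sa"):
            with pytest.raises(ConfigurationError):
                modcal.sample(rosen_setup, algorithm, 100, evaluator=mp)
        # population algorithms accept it
        df = modcal.sample(rosen_setup, "mc", 50, seed=2, evaluator=mp).getdata()
        assert len(df) == 50
    finally:
        mp.close()


def test_failed_simulations_are_skipped_not_fatal():
    calls = {"n": 0}

    def flaky(theta):
        calls["n"] += 1
        if calls["n"] % 5 == 0:
            raise RuntimeError("solver blew up")
        return [float(theta[0])]

    pars = [ParameterSpec("x", "uniform", (0.0, 1.0))]
    setup = ModelSetup(pars, flaky, [0.5], "rmse")
    df = modcal.sample(setup, "mc", 50, seed=1).getdata()
    assert len(df) == 40  # every 5th evaluation failed but consumed budget


def test_run_config_validation():
    with pytest.raises(ConfigurationError):
        RunConfig(repetitions=0)
    with pytest.raises(ConfigurationError):
        RunConfig(db_format="hdf5")


def test_multiple_objectives_recorded_first_drives(rosen_setup):
    setup = benchmarks.rosenbrock_setup()
    setup.objective = ["rmse", "mae", "bias"]
    setup.__post_init__()
    df = modcal.sample(setup, "mc", 30, seed=4).getdata()
    assert {"like1", "like2", "like3"} <= set(df.columns)
    # first objective (rmse of a length-1 series) equals mae here
    np.testing.assert_allclose(df["like1"], df["like2"])
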