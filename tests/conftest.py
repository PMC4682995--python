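import numpy as np
import pytest

from modcal import benchmarks


def first_hit(df, tol):
    """1-based index of the first record with like1 <= tol, else None."""
    a = df["like1"].to_numpy()
    idx = np.nonzero(a <= tol)[0]
    return int(idx[0]) + 1 if len(idx) else None


@pytest.fixture
def rosen_setup():
    return benchmarks.rosenbrock_setup()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
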