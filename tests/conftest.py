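import numpy as np
import pytest

from otfti import GradientSeries


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def iid_series(rng):
    """Stationary white-noise gradient series, 5000 samples at 1 ps."""
    return GradientSeries(0.5, 0.001, rng.normal(0.0, 1.0, 5000))


def make_series(values, dt=0.001, lam=0.0):
    return GradientSeries(lam, dt, np.asarray(values, dtype=float))
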