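import numpy as np
import pytest

from timescales import Ar1Spec, TimeSeriesSample, center_series, simulate_ar1


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def centered_random_series(rng):
    """A generic centered series with no special structure."""
    return center_series(TimeSeriesSample(values=rng.standard_normal(50)))


@pytest.fixture
def long_ar1_series():
    """A single long AR(1) realization at phi = 0.6, T = 4800."""
    x = simulate_ar1(Ar1Spec(phi=0.6, T=4800, seed=101))
    return center_series(x)
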