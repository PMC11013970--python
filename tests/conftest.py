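import numpy as np
import pytest

from stackdmd import ImageStack, SeriesSpec, make_series


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def rank2_stack():
    """Noiseless rank-2 linear system with known eigenvalues 0.95 and 0.80."""
    gen = np.random.default_rng(7)
    n, m = 200, 30
    v = np.linalg.qr(gen.standard_normal((n, 2)))[0]
    mus = np.array([0.95, 0.80])
    X = (v * np.array([3.0, 1.5])) @ np.vander(mus, N=m, increasing=True)
    stack = ImageStack(data=X.reshape(20, 10, m))
    return stack, mus


@pytest.fixture
def bleach_pair():
    """Poisson-corrupted exponentially bleaching series and its truth."""
    spec = SeriesSpec(kind="bleach", m=40, background=0.0, photon_scale=2.0, seed=5)
    return make_series(spec)


@pytest.fixture
def polarimetry_pair():
    """Angle sweep: static background + bleaching + modulated cos 2theta."""
    spec = SeriesSpec(
        kind="polarimetry", m=36, theta0=100.0, photon_scale=5.0, seed=1
    )
    return make_series(spec)
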