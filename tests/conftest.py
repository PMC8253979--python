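import numpy as np
import pytest
from hypothesis import settings

from moltenfit.simulate import BandModel, NoiseModel, gen_irf

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_irf():
    """A compact Gaussian IRF (512 channels) for fast reconvolution tests."""
    return gen_irf(fwhm=1.0, t0=3.0, n_channels=512, channel_width=0.055)


@pytest.fixture(scope="session")
def full_irf():
    """Full-range IRF matching the instrument settings (200 ns window)."""
    return gen_irf(fwhm=1.0, t0=5.0, n_channels=3641, channel_width=0.055)


@pytest.fixture
def trp_band():
    """A tryptophan-like asymmetric emission band."""
    return BandModel(center=336.0, width=25.0, shape="lognormal")


@pytest.fixture
def noiseless():
    return NoiseModel(seed=0)
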