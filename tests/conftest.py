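import numpy as np
import pytest

from proteofret import AcquisitionParams, FretLevels


@pytest.fixture
def acq():
    return AcquisitionParams()


@pytest.fixture
def noiseless_acq():
    """Zero-noise, zero-background acquisition for exact-value contracts."""
    return AcquisitionParams(noise_sd=0.0, background=0.0)


@pytest.fixture
def levels():
    return FretLevels()


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
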