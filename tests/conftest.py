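import numpy as np
import pytest

from foldstab.relaxfit import SpinSystemConstants


@pytest.fixture(scope="session")
def constants():
    return SpinSystemConstants()


@pytest.fixture(scope="session")
def constants_no_csa():
    return SpinSystemConstants(delta_sigma_ppm=0.0)


@pytest.fixture
def rng():
    return np.random.default_rng(20161219 % 2**31)
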