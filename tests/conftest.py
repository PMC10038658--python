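import numpy as np
import pytest

from mechgate.kinetic_model import default_scheme, two_state_scheme
from mechgate.stochastic_sim import ObservationModel


@pytest.fixture(scope="session")
def mso():
    return default_scheme("MSO")


@pytest.fixture(scope="session")
def msa():
    return default_scheme("MSA")


@pytest.fixture(scope="session")
def pore_scheme():
    """Truncated C5-O6 model at the default opening/closing rates."""
    return two_state_scheme()


@pytest.fixture
def om():
    """Default observation model: 6.7 pS, +55 mV reversal, 0.25 pA noise."""
    return ObservationModel()


@pytest.fixture
def om_clean():
    """Noise-free observation model."""
    return ObservationModel(noise_sd_pA=0.0)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
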