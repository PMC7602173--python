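import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import nanoferry as nf
from nanoferry.config import carrier_from_config
from nanoferry.dynamics import Environment

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def ref_model():
    """The published membrane-resistance transfer function (Ts = 1 ps)."""
    return nf.reference_model()


@pytest.fixture(scope="session")
def carrier():
    """Default 100 nm x 10 nm carrier, rho = 5000 kg/m^3, chi = 0.17."""
    return carrier_from_config()


@pytest.fixture(scope="session")
def env():
    return Environment()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
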