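import numpy as np
import pytest
from hypothesis import settings

from mangrove_growth.params import load_params

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def sp():
    """Default species parameter set (R. apiculata calibration)."""
    sp, _, _ = load_params()
    return sp


@pytest.fixture(scope="session")
def mp():
    """Default multiplier parameter set (published regression estimates)."""
    _, mp, _ = load_params()
    return mp


@pytest.fixture(scope="session")
def raw_params():
    _, _, raw = load_params()
    return raw


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
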