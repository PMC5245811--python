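import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from boats.core import EconParams, EcoParams, default_community
from boats.ecology import Forcing


@pytest.fixture(scope="session")
def eco():
    return EcoParams()


@pytest.fixture(scope="session")
def econ():
    return EconParams()


@pytest.fixture(scope="session")
def community():
    return default_community()


@pytest.fixture(scope="session")
def site_forcing():
    """One temperate, productive site (annual-average forcing)."""
    return Forcing(npp=[1500.0], temperature=[10.0], area=[1.0])


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20171)
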