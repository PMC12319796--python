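import numpy as np
import pytest
from hypothesis import settings

from capox import DEFAULT_CONSTANTS, HemodynamicSummary

settings.register_profile("default", derandomize=True, deadline=None)
settings.load_profile("default")


@pytest.fixture(scope="session")
def constants():
    """Default model constants: PtO2 = 21.8 mmHg, k = 68 1/s."""
    return DEFAULT_CONSTANTS


@pytest.fixture(scope="session")
def nawm():
    """Cohort-mean normal-appearing-white-matter hemodynamics."""
    return HemodynamicSummary(mtt=4.52, cth=5.45)


@pytest.fixture(scope="session")
def gm():
    """Cohort-mean gray-matter hemodynamics."""
    return HemodynamicSummary(mtt=3.40, cth=4.08)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
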