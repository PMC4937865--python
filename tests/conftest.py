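import numpy as np
import pytest
from hypothesis import settings

from uhiacclim import SimulationConfig, simulate

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def small_sim():
    """3-year, 5-group dataset with no acclimatization (gamma_true = 1)."""
    return simulate(SimulationConfig.small(gamma_true=1.0, seed=11))


@pytest.fixture(scope="session")
def small_sim_gamma0():
    """3-year, 5-group dataset with full acclimatization."""
    return simulate(SimulationConfig.small(gamma_true=0.0, seed=11))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
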