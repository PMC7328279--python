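import numpy as np
import pytest

from thiogvb.simulate import SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """One default synthetic cohort (320 subjects) shared across tests."""
    return simulate_cohort(SimulationConfig(seed=20260923))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
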