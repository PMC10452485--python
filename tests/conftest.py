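import pytest

from liqbio_mrd.simulate import SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    return SimulationConfig(n_patients=12, seed=11)


@pytest.fixture(scope="session")
def small_cohort(small_config):
    """One simulated cohort shared across read-only tests."""
    return simulate_cohort(small_config)
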