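import pytest

from taascan import synthetic_data as sd


@pytest.fixture(scope="session")
def sim_config():
    return sd.SimulationConfig(seed=12345)


@pytest.fixture(scope="session")
def hpa_fixture(sim_config):
    """Generated normal-tissue records, pathology profiles, and planted truth."""
    return sd.gen_hpa_tables(sim_config)
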