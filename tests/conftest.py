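import pytest

from felnc.synthetic_data import SimConfig, simulate_study


@pytest.fixture(scope="session")
def study():
    """Default synthetic study, shared read-only across tests."""
    return simulate_study(SimConfig(seed=20240901))


@pytest.fixture(scope="session")
def small_genome():
    return {"chr1": "ACGTACGTACGTACGTACGTACGTACGTACGT" * 10}
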