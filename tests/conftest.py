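import pytest

from bioscrub.plant import PlantConfig, simulate_plant


@pytest.fixture(scope="session")
def baseline_cs():
    """Chemical-scrubber baseline solved once per test session."""
    return simulate_plant(PlantConfig(scenario="CS"))


@pytest.fixture(scope="session")
def baseline_bs():
    """Bioscrubber (pure glycerin) baseline solved once per test session."""
    return simulate_plant(PlantConfig(scenario="BS-PG"))
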