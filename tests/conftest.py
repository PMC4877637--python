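import pytest

from episcreen.synthetic import SimulationConfig, generate_bundle


@pytest.fixture(scope="session")
def default_bundle():
    """One default synthetic bundle shared across read-only tests."""
    return generate_bundle(SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def default_config():
    return SimulationConfig(seed=1)
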