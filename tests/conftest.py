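import pytest

from plastevol import synthetic_data as sd


@pytest.fixture(scope="session")
def toy_config():
    return sd.toy_config(seed=11)


@pytest.fixture(scope="session")
def toy_bundle(toy_config):
    """One seed's worth of every synthetic input, shared across tests."""
    return sd.generate_bundle(toy_config)


@pytest.fixture(scope="session")
def toy_simulation(toy_bundle):
    return toy_bundle.simulation
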