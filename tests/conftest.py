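import numpy as np
import pytest
from hypothesis import settings

from flimplate.simulate import SimulationConfig, simulate_reference

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def config():
    """Default generator settings: 16 x 500 ps gates, CFP-like donor."""
    return SimulationConfig()


@pytest.fixture(scope="session")
def reference(config):
    """Noise-free reference-dye measurement on the default schedule."""
    return simulate_reference(config, rng=None)


@pytest.fixture
def rng():
    return np.random.default_rng(20261001)
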