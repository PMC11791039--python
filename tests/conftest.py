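import numpy as np
import pytest

from lucppi import SimulationConfig, simulate_reference_screen


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def small_screen():
    """One deterministic reference screen reused across read-only tests."""
    return simulate_reference_screen(SimulationConfig(seed=7))
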