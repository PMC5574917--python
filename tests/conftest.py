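import numpy as np
import pytest

from flyway import Colony, GridSpec, synth_environment


@pytest.fixture
def grid16():
    """Coarse global grid (16 x 32, 11.25 deg cells)."""
    return GridSpec(16, 32, 11.25)


@pytest.fixture
def grid32():
    return GridSpec(32, 64, 5.625)


@pytest.fixture
def ring_env(grid32):
    """Calm, zonally symmetric ocean channel with uniform resource (April)."""
    return synth_environment("ring_world", grid32, months=(4,))[0]


@pytest.fixture
def colony_south():
    return Colony("test-colony", -50.0, 0.0)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
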