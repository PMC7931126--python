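import numpy as np
import pytest

from oncosim import generate_world


@pytest.fixture(scope="session")
def world():
    """Small shared world for unit tests (8k people, 5 quantiles)."""
    return generate_world(seed=11, scale=8000, n_quantiles=5)


@pytest.fixture(scope="session")
def profile(world):
    return world.profile


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260928)
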