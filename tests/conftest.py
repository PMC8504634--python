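import numpy as np
import pytest

from wassdd import simulate_null_reference


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def small_reference():
    """Shared reduced Brownian-bridge reference for ASY tests."""
    return simulate_null_reference(n_sims=20_000, grid_size=500, seed=11)
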