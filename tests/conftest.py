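import numpy as np
import pytest

from gridsdm import generate_predictor_grid


@pytest.fixture(scope="session")
def small_grid():
    """A 300-cell grid shared by unit tests that only need realistic fields."""
    return generate_predictor_grid(n_cells=300, seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
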