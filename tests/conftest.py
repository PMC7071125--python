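import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)


@pytest.fixture
def random_masks(rng):
    """A batch of small random binary masks with mixed densities."""

    def make(n=20, shape=(24, 32)):
        return [rng.random(shape) < p for p in np.linspace(0.1, 0.9, n)]

    return make
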