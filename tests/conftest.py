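import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20260924)


@pytest.fixture
def random_raster(rng):
    """Factory for small random binary rasters."""

    def make(t_steps=60, n=4, p=0.1, seed=None):
        gen = np.random.default_rng(seed) if seed is not None else rng
        return (gen.random((t_steps, n)) < p).astype(np.uint8)

    return make
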