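import numpy as np
import pytest

from hsiph import PhantomConfig

CROP_NM = (1042.16, 1578.13)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def small_config():
    """A small, fast phantom scene with the default optics and pH population."""
    return PhantomConfig(n_rows=48, n_cols=48, dish_center=(24, 24),
                         dish_radius=19.0, edge_ring_width=3.0, seed=7)


@pytest.fixture
def coarse_config():
    """Coarse 64-band axis over the same range; quick selection problems."""
    return PhantomConfig(n_bands=64, pixel_noise_sd=0.001, seed=3)
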