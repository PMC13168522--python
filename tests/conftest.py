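import numpy as np
import pytest
from scipy import ndimage

from uslr import ImageGrid, VelocityField
from uslr.phantom import PhantomConfig, make_phantom_template, simulate_longitudinal_series


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_grid():
    """1 mm isotropic 24-cube centred at the origin."""
    return ImageGrid.isotropic((24, 24, 24))


def smooth_field(grid, amplitude, seed, sigma=4.0):
    """Gaussian-smoothed random vector field scaled to a given max magnitude."""
    r = np.random.default_rng(seed)
    vals = r.standard_normal(grid.shape + (3,))
    for j in range(3):
        vals[..., j] = ndimage.gaussian_filter(vals[..., j], sigma)
    vals *= amplitude / np.linalg.norm(vals, axis=-1).max()
    return VelocityField(grid, vals)


@pytest.fixture
def smooth_velocity(small_grid):
    return smooth_field(small_grid, 2.0, seed=7)


@pytest.fixture(scope="session")
def default_phantom():
    """One default-condition phantom shared by read-only tests."""
    cfg = PhantomConfig(seed=5)
    tpl = make_phantom_template(cfg)
    series = simulate_longitudinal_series(tpl, cfg)
    return cfg, tpl, series
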