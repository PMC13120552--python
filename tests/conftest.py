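import numpy as np
import pytest

import tomoeval as te


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def spec64():
    """Variant-1 phantom on a quick 64-pixel grid (4 mm pixels)."""
    return te.build_shepp_logan_spec(variant=1, grid_n=64, fov_mm=256.0)


@pytest.fixture(scope="session")
def raster64(spec64):
    return te.rasterize(spec64)


def disc_image(n: int, radius: float, value: float = 1.0, pixel_mm: float = 1.0):
    """Centered uniform disc; use odd n so the center lands on a pixel."""
    c = (n - 1) / 2.0
    yy, xx = np.mgrid[0:n, 0:n]
    x = (xx - c) * pixel_mm
    y = (c - yy) * pixel_mm
    return te.ActivityImage((x**2 + y**2 <= radius**2) * value, pixel_mm)
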