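import numpy as np
import pytest

from renalperf import KidneyMask, ParametricMap
from renalperf.synthetic import MaskGeometry, generate_kidney_mask


@pytest.fixture(scope="session")
def disk_mask() -> KidneyMask:
    """Disk of radius 24 px centered on a 60x60 grid."""
    yy, xx = np.mgrid[0:60, 0:60]
    return KidneyMask(grid=(yy - 30.0) ** 2 + (xx - 30.0) ** 2 < 24.0**2)


@pytest.fixture(scope="session")
def ellipse_mask() -> KidneyMask:
    """Axis-aligned ellipse, semi-axes 30 (pole) x 15 px, on a 100x100 grid."""
    geom = MaskGeometry(grid_shape=(100, 100), semi_major=30.0, semi_minor=15.0,
                        jitter=0.0)
    return generate_kidney_mask(geom, seed=0)


@pytest.fixture(scope="session")
def small_mask() -> KidneyMask:
    """Small disk (~250 px) for cheap per-voxel fits."""
    yy, xx = np.mgrid[0:24, 0:24]
    return KidneyMask(grid=(yy - 12.0) ** 2 + (xx - 12.0) ** 2 < 9.0**2)


def uniform_map(mask: KidneyMask, value: float, kind: str = "RBF") -> ParametricMap:
    return ParametricMap(values=np.where(mask.grid, float(value), 0.0),
                         mask=mask, kind=kind)


@pytest.fixture(scope="session")
def make_map():
    return uniform_map
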