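import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from concord import GridSpec, StructureMask

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_grid(dims=(12, 12, 12), spacing=(1.0, 1.0, 1.0), origin=(0.0, 0.0, 0.0)):
    return GridSpec(dims=dims, spacing=spacing, origin=origin)


def box_mask(grid, lo, hi, **meta):
    """Solid axis-aligned box over half-open index ranges [lo, hi)."""
    occ = np.zeros(grid.dims, dtype=bool)
    occ[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]] = True
    return StructureMask(grid=grid, occupancy=occ, **meta)


def sphere_mask(grid, center_mm, radius_mm, **meta):
    X, Y, Z = grid.coordinate_grids()
    occ = (
        (X - center_mm[0]) ** 2 + (Y - center_mm[1]) ** 2 + (Z - center_mm[2]) ** 2
        <= radius_mm**2
    )
    return StructureMask(grid=grid, occupancy=occ, **meta)


def random_blob_mask(grid, rng, **meta):
    """Non-empty random smooth-ish blob: thresholded smoothed noise."""
    from scipy import ndimage

    field = ndimage.gaussian_filter(rng.standard_normal(grid.dims), sigma=1.5)
    occ = field > np.quantile(field, rng.uniform(0.6, 0.95))
    if not occ.any():
        occ[tuple(rng.integers(0, d) for d in grid.dims)] = True
    return StructureMask(grid=grid, occupancy=occ, **meta)


@pytest.fixture
def grid12():
    return make_grid()


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)
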