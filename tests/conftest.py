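import numpy as np
import pytest

from atriashape import BinaryMask
from atriashape.synthetic import CohortSpec, generate_member


def rasterize_sphere(radius_mm: float = 10.0, spacing: float = 1.0) -> BinaryMask:
    """Sphere of given radius centred on the grid, with a 3-voxel margin."""
    n_half = int(np.ceil(radius_mm / spacing)) + 3
    coords = spacing * (np.arange(2 * n_half + 1) - n_half)
    X, Y, Z = np.meshgrid(coords, coords, coords, indexing="ij")
    data = (X**2 + Y**2 + Z**2 <= radius_mm**2).astype(np.uint8)
    origin = -n_half * spacing
    return BinaryMask(data, (spacing,) * 3, (origin,) * 3)


def rasterize_cube(side_mm: float = 10.0, spacing: float = 1.0) -> BinaryMask:
    half = side_mm / 2
    n_half = int(np.ceil(half / spacing)) + 3
    coords = spacing * (np.arange(2 * n_half + 1) - n_half)
    X, Y, Z = np.meshgrid(coords, coords, coords, indexing="ij")
    data = (
        (np.abs(X) <= half) & (np.abs(Y) <= half) & (np.abs(Z) <= half)
    ).astype(np.uint8)
    origin = -n_half * spacing
    return BinaryMask(data, (spacing,) * 3, (origin,) * 3)


@pytest.fixture(scope="session")
def sphere10():
    return rasterize_sphere(10.0, 1.0)


@pytest.fixture(scope="session")
def cube10():
    return rasterize_cube(10.0, 1.0)


#: Coarse generator settings for fast unit tests (~35^3 grids).
FAST_SPEC = dict(spacing_mm=3.0, seed=9)


@pytest.fixture(scope="session")
def fast_member():
    """One negative-group synthetic member at coarse resolution."""
    return generate_member(CohortSpec(**FAST_SPEC), group=0, member_seed=42)


@pytest.fixture(scope="session")
def fast_member_b():
    """A second, anatomically distinct negative-group member."""
    return generate_member(CohortSpec(**FAST_SPEC), group=0, member_seed=43)


@pytest.fixture(scope="session")
def fast_member_bumped():
    """The first member with the planted 3 mm cap switched on."""
    return generate_member(CohortSpec(**FAST_SPEC), group=1, member_seed=42)
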