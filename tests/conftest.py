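import numpy as np
import pytest

from datspect.phantom import (
    SyntheticHeadParams,
    extract_segments,
    generate_synthetic_head,
)


@pytest.fixture(scope="session")
def head_params():
    """Half-resolution study head: same physical anatomy, 2.2 mm voxels."""
    return SyntheticHeadParams().scaled(2.0)


@pytest.fixture(scope="session")
def head(head_params):
    return generate_synthetic_head(head_params)


@pytest.fixture(scope="session")
def segments(head):
    return extract_segments(head)


@pytest.fixture(scope="session")
def coarse_head():
    """Very coarse head for smoke tests (4.4 mm voxels)."""
    return generate_synthetic_head(SyntheticHeadParams().scaled(4.0))


def ball_mask(radius_mm, voxel_mm, pad=2):
    """Digitised sphere: centre of the grid, ||x|| <= radius."""
    n = int(2 * (radius_mm / voxel_mm + pad)) + 1
    ax = (np.arange(n) - (n - 1) / 2) * voxel_mm
    x, y, z = np.meshgrid(ax, ax, ax, indexing="ij", sparse=True)
    return np.sqrt(x**2 + y**2 + z**2) <= radius_mm
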