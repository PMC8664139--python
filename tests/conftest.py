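import numpy as np
import pytest

from arcplan.phantom import Phantom, StructureMask, VoxelGrid, generate_phantom


@pytest.fixture(scope="session")
def default_phantom():
    return generate_phantom(1)


def box_mask(grid, name, lo, hi):
    """Axis-aligned box of voxel indices [lo, hi) as a StructureMask."""
    m = np.zeros(grid.shape, dtype=bool)
    m[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]] = True
    return StructureMask(name, m, grid)


@pytest.fixture()
def toy_phantom():
    """Small box-anatomy phantom for cost-function and optimizer tests."""
    grid = VoxelGrid.centered((10, 10, 6), 4.0)
    body = box_mask(grid, "body", (0, 0, 0), (10, 10, 6))
    primaries = {
        "body": body,
        "CTV": box_mask(grid, "CTV", (3, 4, 2), (7, 8, 4)),
        "rectum": box_mask(grid, "rectum", (3, 0, 0), (7, 3, 6)),
        "bladder": box_mask(grid, "bladder", (3, 8, 2), (7, 10, 6)),
        "urethra": box_mask(grid, "urethra", (4, 5, 2), (6, 7, 4)),
        "femoral_head_L": box_mask(grid, "femoral_head_L", (8, 3, 1), (10, 7, 5)),
        "femoral_head_R": box_mask(grid, "femoral_head_R", (0, 3, 1), (2, 7, 5)),
    }
    return Phantom(grid=grid, primaries=primaries)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
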