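import numpy as np
import pytest

from spectpareto import (
    AttenuationMap,
    Grid,
    Projector,
    SystemModel,
)


@pytest.fixture(scope="session")
def tiny_grid():
    return Grid((8, 8, 8), voxel_size=4.42)


@pytest.fixture(scope="session")
def tiny_system():
    return SystemModel(pixel_size_mm=4.42, num_pixels=8, sensitivity_cps_per_MBq=3.0)


@pytest.fixture(scope="session")
def tiny_attenuation(tiny_grid):
    rng = np.random.default_rng(7)
    return AttenuationMap(tiny_grid, rng.uniform(0.0, 0.15, tiny_grid.shape))


@pytest.fixture(scope="session")
def tiny_projector(tiny_grid, tiny_system, tiny_attenuation):
    return Projector(tiny_grid, tiny_system, [0.0, 40.0, 135.0], tiny_attenuation)


def dense_matrix(projector, grid):
    """Dense system matrix oracle, built column by column."""
    nvox = int(np.prod(grid.shape))
    nproj = len(projector.angles_deg) * grid.shape[0] * grid.shape[2]
    a = np.empty((nproj, nvox))
    for j in range(nvox):
        e = np.zeros(nvox)
        e[j] = 1.0
        a[:, j] = projector.forward(e.reshape(grid.shape)).ravel()
    return a
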