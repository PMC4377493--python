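import numpy as np
import pytest

from connfeed.grids import VolumeGrid
from connfeed.roi import synthetic_registry


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_grid():
    """A 1-mm isotropic grid for voxelization oracles."""
    affine = np.eye(4)
    affine[:3, 3] = -10.0
    return VolumeGrid(shape=(21, 21, 21), affine=affine)


@pytest.fixture(scope="session")
def sim_registry():
    return synthetic_registry()


def make_exact_corr_volume(shape, pairs, n_volumes=48, seed=0):
    """4D volume in which listed voxel pairs have exactly prescribed r.

    ``pairs`` maps ((i, j, k), (i2, j2, k2)) -> r.  Every other voxel gets
    its own orthogonal basis vector, so all remaining correlations are 0.
    """
    from connfeed.synthetic import orthonormal_timecourses

    n_vox = int(np.prod(shape))
    basis = orthonormal_timecourses(n_volumes, n_vox + len(pairs), seed=seed)
    data = np.zeros((*shape, n_volumes))
    flat_index = {}
    for idx, voxel in enumerate(np.ndindex(*shape)):
        flat_index[voxel] = idx
        data[voxel] = basis[:, idx]
    for extra, ((va, vb), r) in enumerate(pairs.items()):
        shared = basis[:, n_vox + extra]
        data[tuple(vb)] = r * data[tuple(va)] + np.sqrt(1 - r * r) * shared
    return data
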