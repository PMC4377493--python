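"""Voxel grids and voxel<->world (MNI mm) coordinate mapping.

A :class:`VolumeGrid` is a 3D sampling lattice described by its shape and a
4x4 affine mapping 0-based voxel indices to millimetre coordinates, following
the NIfTI-1 convention (``world = affine @ [i, j, k, 1]``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["VolumeGrid", "default_synthetic_grid"]


@dataclass(frozen=True)
class VolumeGrid:
    """A 3D voxel lattice with a NIfTI-style affine.

    Parameters
    ----------
    shape
        Number of voxels along each axis, ``(nx, ny, nz)``.
    affine
        4x4 voxel-to-world (mm) affine.
    """

    shape: tuple[int, int, int]
    affine: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        affine = np.asarray(self.affine, dtype=float)
        if affine.shape != (4, 4):
            raise ValueError(f"affine must be 4x4, got {affine.shape}")
        if len(self.shape) != 3 or any(int(s) <= 0 for s in self.shape):
            raise ValueError(f"shape must be three positive ints, got {self.shape}")
        object.__setattr__(self, "shape", tuple(int(s) for s in self.shape))
        object.__setattr__(self, "affine", affine)

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.shape))

    @property
    def voxel_sizes(self) -> np.ndarray:
        """Edge lengths of a voxel in mm along each axis."""
        return np.sqrt((self.affine[:3, :3] ** 2).sum(axis=0))

    def voxel_to_world(self, ijk: np.ndarray) -> np.ndarray:
        """Map 0-based voxel indices (..., 3) to mm coordinates."""
        ijk = np.asarray(ijk, dtype=float)
        return ijk @ self.affine[:3, :3].T + self.affine[:3, 3]

    def world_to_voxel(self, xyz: np.ndarray) -> np.ndarray:
        """Map mm coordinates (..., 3) to fractional 0-based voxel indices."""
        xyz = np.asarray(xyz, dtype=float)
        inv = np.linalg.inv(self.affine)
        return xyz @ inv[:3, :3].T + inv[:3, 3]

    def contains_voxel(self, ijk: np.ndarray) -> np.ndarray:
        ijk = np.asarray(ijk)
        return np.all((ijk >= 0) & (ijk < np.asarray(self.shape)), axis=-1)

    def voxel_centers_world(self) -> np.ndarray:
        """World (mm) coordinates of every voxel centre, shape (n_voxels, 3)."""
        ijk = np.indices(self.shape).reshape(3, -1).T
        return self.voxel_to_world(ijk)


def default_synthetic_grid() -> VolumeGrid:
    """The small EPI-like grid used for simulated acquisitions.

    24 x 24 x 18 voxels of 3 x 3 x 3.5 mm, centred on the origin so that MNI-like
    coordinates of a few centimetres fall inside the volume.
    """
    shape = (24, 24, 18)
    voxel = np.array([3.0, 3.0, 3.5])
    affine = np.diag(np.r_[voxel, 1.0])
    # centre the grid on (0, 0, 0)
    affine[:3, 3] = -voxel * (np.asarray(shape) - 1) / 2.0
    return VolumeGrid(shape=shape, affine=affine)
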