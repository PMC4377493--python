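"""Regions of interest: specification, registry, voxelization, network pairing.

The default registry holds the sixteen regions used for the resting-state
network analysis: eight in the motor/visuospatial network group (MVN), four in
the default mode network (DMN) and four control regions in the visual and
auditory networks.  Regions are defined either as spheres around an MNI
millimetre coordinate or as user-supplied binary mask volumes (used for the
anatomically defined regions, e.g. Brodmann areas, for which no atlas is
shipped).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .grids import VolumeGrid, default_synthetic_grid

__all__ = [
    "NETWORKS",
    "RoiSpec",
    "RoiRegistry",
    "NetworkPairType",
    "load_roi_registry",
    "default_registry",
    "synthetic_registry",
    "voxelize_roi",
    "partition_network_pairs",
]

NETWORKS = ("MVN", "DMN", "control")

#: default sphere radius in mm where a region is given only by its centre
DEFAULT_SPHERE_RADIUS_MM = 7.5


class RegistryError(ValueError):
    """Raised for malformed or inconsistent ROI registries."""


@dataclass(frozen=True)
class RoiSpec:
    """One named region of interest.

    Exactly one of the following definitions applies:

    * sphere — ``center`` (MNI mm triple) and ``radius`` (mm);
    * mask — ``mask_path`` pointing to a binary NIfTI volume;
    * anatomical — neither; the region is named after an anatomical label
      (``anatomical_note``) and cannot be voxelized until a mask is supplied.
    """

    name: str
    network: str
    center: tuple[float, float, float] | None = None
    radius: float | None = None
    mask_path: str | None = None
    anatomical_note: str = ""

    def __post_init__(self) -> None:
        if self.network not in NETWORKS:
            raise RegistryError(
                f"ROI {self.name!r}: unknown network {self.network!r}; "
                f"expected one of {NETWORKS}"
            )
        if self.center is not None:
            if len(self.center) != 3:
                raise RegistryError(f"ROI {self.name!r}: center must be an (x, y, z) mm triple")
            object.__setattr__(self, "center", tuple(float(c) for c in self.center))
            radius = DEFAULT_SPHERE_RADIUS_MM if self.radius is None else float(self.radius)
            if radius <= 0:
                raise RegistryError(f"ROI {self.name!r}: sphere radius must be > 0, got {radius}")
            object.__setattr__(self, "radius", radius)
        if self.center is not None and self.mask_path is not None:
            raise RegistryError(f"ROI {self.name!r}: give a sphere or a mask, not both")

    @property
    def kind(self) -> str:
        if self.center is not None:
            return "sphere"
        if self.mask_path is not None:
            return "mask"
        return "anatomical"


@dataclass(frozen=True)
class RoiRegistry:
    """Ordered collection of ROIs sharing a target voxel grid."""

    rois: tuple[RoiSpec, ...]
    grid: VolumeGrid = field(default_factory=default_synthetic_grid)

    def __post_init__(self) -> None:
        names = [r.name for r in self.rois]
        dupes = {n for n in names if names.count(n) > 1}
        if dupes:
            raise RegistryError(f"duplicate ROI names: {sorted(dupes)}")
        object.__setattr__(self, "rois", tuple(self.rois))

    def __len__(self) -> int:
        return len(self.rois)

    def __iter__(self):
        return iter(self.rois)

    def __getitem__(self, name: str) -> RoiSpec:
        for roi in self.rois:
            if roi.name == name:
                return roi
        raise KeyError(name)

    @property
    def names(self) -> list[str]:
        return [r.name for r in self.rois]

    def network_counts(self) -> dict[str, int]:
        counts = {net: 0 for net in NETWORKS}
        for roi in self.rois:
            counts[roi.network] += 1
        return counts

    def networks_of(self) -> dict[str, str]:
        return {r.name: r.network for r in self.rois}

    def voxel_sets(self) -> dict[str, np.ndarray]:
        """Voxelize every ROI on the registry grid."""
        return {r.name: voxelize_roi(r, self.grid) for r in self.rois}

    # -- serialization -------------------------------------------------

    def to_file(self, path: str | Path) -> None:
        rows = []
        for r in self.rois:
            rows.append(
                {
                    "name": r.name,
                    "network": r.network,
                    "center_x": "" if r.center is None else r.center[0],
                    "center_y": "" if r.center is None else r.center[1],
                    "center_z": "" if r.center is None else r.center[2],
                    "radius_mm": "" if r.center is None else r.radius,
                    "mask_path": "" if r.mask_path is None else r.mask_path,
                    "anatomical_note": r.anatomical_note,
                }
            )
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_file(cls, path: str | Path, grid: VolumeGrid | None = None) -> "RoiRegistry":
        table = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
        required = {"name", "network"}
        missing = required - set(table.columns)
        if missing:
            raise RegistryError(f"registry file missing columns: {sorted(missing)}")
        rois = []
        for _, row in table.iterrows():
            has_center = all(str(row.get(c, "")).strip() != "" for c in ("center_x", "center_y", "center_z"))
            center = None
            radius = None
            if has_center:
                try:
                    center = tuple(float(row[c]) for c in ("center_x", "center_y", "center_z"))
                except ValueError as exc:
                    raise RegistryError(f"ROI {row['name']!r}: malformed coordinates") from exc
                raw_radius = str(row.get("radius_mm", "")).strip()
                radius = float(raw_radius) if raw_radius else None
            mask_path = str(row.get("mask_path", "")).strip() or None
            rois.append(
                RoiSpec(
                    name=str(row["name"]),
                    network=str(row["network"]),
                    center=center,
                    radius=radius,
                    mask_path=mask_path,
                    anatomical_note=str(row.get("anatomical_note", "")),
                )
            )
        return cls(rois=tuple(rois), grid=grid or default_synthetic_grid())


# -- the packaged 16-ROI registry --------------------------------------

# name, network, (center mm or None), anatomical note
_DEFAULT_ROIS: tuple[tuple[str, str, tuple[float, float, float] | None, str], ...] = (
    ("lM1", "MVN", None, "Left primary motor cortex (Brodmann area 4)"),
    ("rM1", "MVN", None, "Right primary motor cortex (Brodmann area 4)"),
    ("lSMA", "MVN", None, "Left supplementary motor area (Brodmann area 6)"),
    ("rSMA", "MVN", None, "Right supplementary motor area (Brodmann area 6)"),
    ("lIPS", "MVN", (-25.0, -57.0, 46.0), "Left intra-parietal sulcus"),
    ("rIPS", "MVN", (25.0, -57.0, 46.0), "Right intra-parietal sulcus"),
    ("lFEF", "MVN", (-25.0, -13.0, 50.0), "Left frontal eye field"),
    ("rFEF", "MVN", (25.0, -13.0, 50.0), "Right frontal eye field"),
    ("lLP", "DMN", (-45.0, -67.0, 36.0), "Left lateral parietal region"),
    ("rLP", "DMN", (45.0, -67.0, 36.0), "Right lateral parietal region"),
    ("PCC", "DMN", (-5.0, -49.0, 40.0), "Posterior cingulate cortex"),
    ("MPF", "DMN", (-1.0, 47.0, -4.0), "Medial prefrontal cortex"),
    ("lV1", "control", None, "Left primary visual cortex (Brodmann area 17)"),
    ("rV1", "control", None, "Right primary visual cortex (Brodmann area 17)"),
    ("lA1", "control", None, "Left auditory cortex (Brodmann areas 41/42)"),
    ("rA1", "control", None, "Right auditory cortex (Brodmann areas 41/42)"),
)


def default_registry(grid: VolumeGrid | None = None) -> RoiRegistry:
    """The packaged 16-ROI registry (8 MVN, 4 DMN, 4 control).

    Coordinate-defined regions carry their MNI sphere centres (default
    7.5 mm radius); anatomically defined regions (M1, SMA, V1, A1) require a
    user-supplied mask before they can be voxelized.
    """
    rois = tuple(
        RoiSpec(name=name, network=net, center=center, anatomical_note=note)
        for name, net, center, note in _DEFAULT_ROIS
    )
    return RoiRegistry(rois=rois, grid=grid or default_synthetic_grid())


def synthetic_registry(grid: VolumeGrid | None = None, radius: float = 6.0) -> RoiRegistry:
    """A fully sphere-defined 16-ROI registry on the synthetic grid.

    Same names and network labels as :func:`default_registry`, but every
    region — including the anatomically defined ones — is given a synthetic
    sphere centre laid out on the small simulation grid so that all sixteen
    regions voxelize to disjoint, nonempty voxel sets.  Intended for simulated
    studies only; the centres of the anatomical regions are stand-ins, not
    MNI coordinates.
    """
    grid = grid or default_synthetic_grid()
    # lay the 16 ROIs out on a 4x4 lattice in the central axial plane,
    # alternating two z levels to use the volume
    extent = grid.voxel_sizes * np.asarray(grid.shape)
    xs = np.linspace(-0.33, 0.33, 4) * extent[0]
    ys = np.linspace(-0.33, 0.33, 4) * extent[1]
    zs = (-0.15 * extent[2], 0.15 * extent[2])
    rois = []
    for idx, (name, net, _center, note) in enumerate(_DEFAULT_ROIS):
        center = (float(xs[idx % 4]), float(ys[idx // 4]), float(zs[idx % 2]))
        rois.append(
            RoiSpec(name=name, network=net, center=center, radius=radius,
                    anatomical_note=f"synthetic stand-in placement; {note}")
        )
    return RoiRegistry(rois=tuple(rois), grid=grid)


def load_roi_registry(source: str | Path, grid: VolumeGrid | None = None) -> RoiRegistry:
    """Load a registry from a TSV file, or the packaged one for ``"default"``."""
    if str(source) == "default":
        return default_registry(grid)
    if str(source) == "synthetic":
        return synthetic_registry(grid)
    return RoiRegistry.from_file(source, grid=grid)


# -- voxelization ------------------------------------------------------


def voxelize_roi(roi: RoiSpec, grid: VolumeGrid) -> np.ndarray:
    """Voxel indices (n, 3), 0-based, belonging to an ROI on ``grid``.

    Sphere ROIs include every voxel whose *centre* lies within ``radius`` mm
    (Euclidean) of the MNI centre.  Mask ROIs include the nonzero voxels of
    the mask volume, which must share the grid shape.
    """
    if roi.kind == "sphere":
        center = np.asarray(roi.center, dtype=float)
        frac = grid.world_to_voxel(center)
        if not grid.contains_voxel(np.round(frac)):
            raise RegistryError(
                f"ROI {roi.name!r}: sphere centre {roi.center} maps outside the grid"
            )
        # search only the bounding box of the sphere
        half = roi.radius / grid.voxel_sizes
        lo = np.maximum(np.floor(frac - half).astype(int), 0)
        hi = np.minimum(np.ceil(frac + half).astype(int), np.asarray(grid.shape) - 1)
        ranges = [np.arange(lo[a], hi[a] + 1) for a in range(3)]
        box = np.stack(np.meshgrid(*ranges, indexing="ij"), axis=-1).reshape(-1, 3)
        dist = np.linalg.norm(grid.voxel_to_world(box) - center, axis=1)
        voxels = box[dist <= roi.radius]
    elif roi.kind == "mask":
        img = nib.load(roi.mask_path)
        data = np.asarray(img.dataobj)
        if data.shape != tuple(grid.shape):
            raise RegistryError(
                f"ROI {roi.name!r}: mask shape {data.shape} != grid shape {grid.shape}"
            )
        voxels = np.argwhere(data != 0)
    else:
        raise RegistryError(
            f"ROI {roi.name!r} is anatomically defined; supply a mask volume to voxelize it"
        )
    if len(voxels) == 0:
        raise RegistryError(f"ROI {roi.name!r} voxelizes to an empty set on this grid")
    return np.asarray(voxels, dtype=int)


# -- network-pair partition --------------------------------------------


@dataclass(frozen=True)
class NetworkPairType:
    """One of the six types of network pairs (e.g. MVN-DMN)."""

    label: str
    networks: tuple[str, str]
    pairs: tuple[tuple[str, str], ...]

    @property
    def cell_count(self) -> int:
        return len(self.pairs)


def pair_type_label(net_a: str, net_b: str) -> str:
    order = {net: i for i, net in enumerate(NETWORKS)}
    a, b = sorted((net_a, net_b), key=order.__getitem__)
    return f"{a}-{b}"


def partition_network_pairs(registry: RoiRegistry) -> list[NetworkPairType]:
    """Partition all unordered off-diagonal ROI pairs by network-pair type.

    For the three network groups this yields six types (MVN-MVN, MVN-DMN,
    DMN-DMN, MVN-control, DMN-control, control-control); types with no member
    pairs are returned with empty pair lists.  The partition is exhaustive and
    disjoint: cell counts sum to n(n-1)/2.
    """
    networks = registry.networks_of()
    buckets: dict[str, list[tuple[str, str]]] = {}
    for i, net_a in enumerate(NETWORKS):
        for net_b in NETWORKS[i:]:
            buckets[pair_type_label(net_a, net_b)] = []
    for a, b in itertools.combinations(registry.names, 2):
        buckets[pair_type_label(networks[a], networks[b])].append((a, b))
    return [
        NetworkPairType(label=label, networks=tuple(label.split("-")), pairs=tuple(pairs))
        for label, pairs in buckets.items()
    ]
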