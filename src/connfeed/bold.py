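"""4D BOLD runs: in-memory container, NIfTI-1 and confound-table I/O."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .grids import VolumeGrid

__all__ = ["BoldRun", "read_bold", "write_bold", "read_confounds", "write_confounds",
           "CONFOUND_COLUMNS"]

#: six rigid-body motion parameters plus three tissue-mean signals
CONFOUND_COLUMNS = (
    "trans_x", "trans_y", "trans_z", "rot_x", "rot_y", "rot_z",
    "gray_matter", "white_matter", "csf",
)


@dataclass
class BoldRun:
    """A 4D voxel time series with grid geometry and provenance.

    ``data`` has shape (nx, ny, nz, n_volumes); ``tr_s`` is the volume
    repetition time in seconds.
    """

    data: np.ndarray
    tr_s: float
    affine: np.ndarray
    subject: str = ""
    group: str = ""
    session: str = ""
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 4:
            raise ValueError(f"BOLD data must be 4D, got shape {self.data.shape}")
        if self.tr_s <= 0:
            raise ValueError(f"tr_s must be positive, got {self.tr_s}")
        self.affine = np.asarray(self.affine, dtype=float)

    @property
    def n_volumes(self) -> int:
        return self.data.shape[3]

    @property
    def grid(self) -> VolumeGrid:
        return VolumeGrid(shape=self.data.shape[:3], affine=self.affine)

    def roi_means(self, voxel_sets: dict[str, np.ndarray]) -> pd.DataFrame:
        """Mean time course per ROI, columns ordered as ``voxel_sets``."""
        out = {}
        for name, vox in voxel_sets.items():
            out[name] = self.data[vox[:, 0], vox[:, 1], vox[:, 2], :].mean(axis=0)
        return pd.DataFrame(out)


def read_bold(path: str | Path, tr_override: float | None = None) -> BoldRun:
    """Load a 4D NIfTI-1 file as a :class:`BoldRun`.

    The TR is taken from the header's time axis unless ``tr_override`` is
    given; a missing/zero header TR with no override is an error.
    """
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 4:
        raise ValueError(f"{path}: expected a 4D volume, got {data.ndim}D")
    tr = tr_override
    if tr is None:
        header_tr = float(img.header.get_zooms()[3]) if len(img.header.get_zooms()) > 3 else 0.0
        if header_tr <= 0:
            raise ValueError(f"{path}: no TR in header; pass tr_override")
        tr = header_tr
    sidecar = Path(str(path)).with_suffix("").with_suffix("")  # strip .nii.gz
    prov_path = Path(str(sidecar) + ".provenance.json")
    provenance = {}
    if prov_path.exists():
        provenance = json.loads(prov_path.read_text())
    return BoldRun(data=data, tr_s=tr, affine=img.affine,
                   subject=provenance.get("subject", ""),
                   group=provenance.get("group", ""),
                   session=provenance.get("session", ""),
                   provenance=provenance)


def write_bold(run: BoldRun, path: str | Path) -> None:
    """Write a run as 4D NIfTI-1 plus a JSON provenance sidecar."""
    img = nib.Nifti1Image(run.data, run.affine)
    img.header.set_zooms((*img.header.get_zooms()[:3], run.tr_s))
    img.header.set_xyzt_units("mm", "sec")
    nib.save(img, str(path))
    prov = dict(run.provenance)
    prov.update({"subject": run.subject, "group": run.group,
                 "session": run.session, "tr_s": run.tr_s})
    sidecar = Path(str(path).removesuffix(".gz").removesuffix(".nii") + ".provenance.json")
    sidecar.write_text(json.dumps(prov, indent=1, default=str))


def read_confounds(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t")
    missing = set(CONFOUND_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"{path}: confound table missing columns {sorted(missing)}")
    return table


def write_confounds(confounds: pd.DataFrame, path: str | Path) -> None:
    confounds.to_csv(path, sep="\t", index=False)
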