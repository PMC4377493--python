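"""Voxelwise degree-of-connectivity maps and cluster-size correction.

The degree of connectivity of a voxel is the number of other in-mask voxels
whose time-course correlation with it satisfies a signed threshold relation
— here, by default, r < -0.25, so the map counts strong *negative*
connections and a post-training decrease in degree means anticorrelations
moved toward zero or positive values.  Pre/post changes are tested with a
voxelwise paired t-test and corrected at cluster level against a Monte-Carlo
null of smooth Gaussian fields (the minimum significant cluster size is
always derived for the current mask and smoothness, never hard-coded).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .bold import BoldRun
from .roi import RoiRegistry

__all__ = [
    "FWHM_TO_SIGMA",
    "DegreeParams",
    "DegreeMap",
    "ClusterResult",
    "smooth_volume",
    "degree_map",
    "degree_change_test",
    "cluster_threshold_mc",
    "find_clusters",
    "threshold_sweep",
    "roi_significance_ratio",
]

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))  # 1/2.3548


def _connectivity_structure(connectivity: int) -> np.ndarray:
    codes = {6: 1, 18: 2, 26: 3}
    if connectivity not in codes:
        raise ValueError(f"connectivity must be one of {sorted(codes)}, got {connectivity}")
    return ndimage.generate_binary_structure(3, codes[connectivity])


def _smooth_data(data: np.ndarray, fwhm_mm: float, voxel_sizes: np.ndarray) -> np.ndarray:
    if fwhm_mm < 0:
        raise ValueError(f"fwhm must be >= 0, got {fwhm_mm}")
    if fwhm_mm == 0:
        return data.copy()
    sigma_vox = fwhm_mm * FWHM_TO_SIGMA / np.asarray(voxel_sizes, dtype=float)
    # wide truncation so the discrete kernel matches the closed-form Gaussian
    return ndimage.gaussian_filter(data, sigma=tuple(sigma_vox), mode="constant",
                                   truncate=6.0)


def smooth_volume(run: BoldRun, fwhm_mm: float) -> BoldRun:
    """Per-volume 3D Gaussian smoothing with sigma = FWHM / 2.3548 per axis (mm)."""
    if fwhm_mm < 0:
        raise ValueError(f"fwhm must be >= 0, got {fwhm_mm}")
    voxel_sizes = run.grid.voxel_sizes
    out = np.empty_like(run.data)
    for t in range(run.n_volumes):
        out[..., t] = _smooth_data(run.data[..., t], fwhm_mm, voxel_sizes)
    return BoldRun(data=out, tr_s=run.tr_s, affine=run.affine,
                   subject=run.subject, group=run.group, session=run.session,
                   provenance={**run.provenance, "smoothing_fwhm": fwhm_mm})


@dataclass(frozen=True)
class DegreeParams:
    """Counting rule for the degree map."""

    threshold: float = -0.25
    direction: str = "less"       # count r < threshold ("less") or r > threshold
    smoothing_fwhm: float = 10.0  # mm, applied in the pipeline before counting
    block_size: int = 512         # voxels per block in the streamed computation

    def __post_init__(self) -> None:
        if not -1.0 < self.threshold < 1.0:
            raise ValueError(f"|threshold| must be < 1, got {self.threshold}")
        if self.direction not in ("less", "greater"):
            raise ValueError("direction must be 'less' or 'greater'")


@dataclass
class DegreeMap:
    """Per-voxel connection counts (NaN outside the mask)."""

    counts: np.ndarray
    mask: np.ndarray
    params: DegreeParams
    provenance: dict = field(default_factory=dict)

    @property
    def n_mask_voxels(self) -> int:
        return int(self.mask.sum())


def degree_map(run: BoldRun | np.ndarray, params: DegreeParams | None = None,
               mask: np.ndarray | None = None) -> DegreeMap:
    """Count, for each mask voxel, the other mask voxels it is connected to.

    ``direction="less"`` counts voxels u != v with r(v, u) < threshold.
    Computation is streamed in voxel blocks over standardised series, so
    memory stays bounded by the block size and the result is independent of
    the block partition.  Zero-variance voxels are dropped from the mask
    with a warning.
    """
    params = params or DegreeParams()
    data = run.data if isinstance(run, BoldRun) else np.asarray(run, dtype=float)
    if data.ndim != 4:
        raise ValueError("expected 4D data (x, y, z, t)")
    n_t = data.shape[3]
    if n_t < 3:
        raise ValueError("need at least 3 time points")
    if mask is None:
        mask = np.ones(data.shape[:3], dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != data.shape[:3]:
        raise ValueError("mask shape does not match the volume")

    series = data[mask].astype(float)           # (v, t)
    sd = series.std(axis=1)
    valid = sd > 1e-12 * max(np.abs(series).max(initial=0.0), 1.0)
    if not valid.all():
        warnings.warn(f"{int((~valid).sum())} zero-variance voxels removed from mask",
                      RuntimeWarning, stacklevel=2)
        new_mask = mask.copy()
        new_mask[tuple(np.argwhere(mask)[~valid].T)] = False
        mask = new_mask
        series = series[valid]
        sd = sd[valid]
    n_vox = series.shape[0]
    if n_vox == 0:
        raise ValueError("mask is empty after removing zero-variance voxels")

    centered = series - series.mean(axis=1, keepdims=True)
    z = centered / np.linalg.norm(centered, axis=1, keepdims=True)  # unit norm

    degrees = np.zeros(n_vox, dtype=np.int64)
    for start in range(0, n_vox, params.block_size):
        stop = min(start + params.block_size, n_vox)
        corr = z[start:stop] @ z.T                      # (b, v)
        if params.direction == "less":
            hits = corr < params.threshold
        else:
            hits = corr > params.threshold
        # remove self-correlation (r = 1) where it satisfies the relation
        self_cols = np.arange(start, stop)
        self_hits = hits[np.arange(stop - start), self_cols]
        degrees[start:stop] = hits.sum(axis=1) - self_hits

    counts = np.full(data.shape[:3], np.nan)
    counts[mask] = degrees
    return DegreeMap(counts=counts, mask=mask, params=params,
                     provenance={"n_volumes": n_t})


def degree_change_test(pre_maps: list[DegreeMap] | np.ndarray,
                       post_maps: list[DegreeMap] | np.ndarray) -> np.ndarray:
    """Voxelwise paired t statistic of (post - pre) degree across subjects.

    Returns the raw t map (negative where degree decreased); the direction of
    interest is applied by the caller when thresholding.
    """
    def _stack(maps):
        if isinstance(maps, np.ndarray):
            return np.asarray(maps, dtype=float)
        return np.stack([m.counts for m in maps]).astype(float)

    pre = _stack(pre_maps)
    post = _stack(post_maps)
    if pre.shape != post.shape:
        raise ValueError("pre/post grids or subject counts differ")
    n = pre.shape[0]
    if n < 2:
        raise ValueError("need >= 2 subjects for a paired t-test")
    d = post - pre
    mean = d.mean(axis=0)
    sd = d.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    t[(sd == 0) & (mean == 0)] = 0.0
    return t


def cluster_threshold_mc(mask: np.ndarray, voxel_sizes: np.ndarray,
                         fwhm_mm: float, voxel_p: float = 0.005,
                         corrected_p: float = 0.05, n_iter: int = 1000,
                         seed: int | np.random.Generator = 0,
                         connectivity: int = 18) -> int:
    """Monte-Carlo minimum cluster size controlling familywise error.

    Simulates smooth Gaussian noise fields on the mask, thresholds each at
    the one-sided ``voxel_p`` quantile of the standardised field, records the
    largest suprathreshold cluster per iteration, and returns the smallest
    size k with P(max cluster >= k) <= corrected_p.  The smoothness of the
    null fields is the nominal applied FWHM, not an estimate of residual
    smoothness.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("mask is empty")
    if n_iter < 100:
        raise ValueError("n_iter must be >= 100")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    structure = _connectivity_structure(connectivity)
    z_thresh = stats.norm.isf(voxel_p)
    max_sizes = np.zeros(n_iter, dtype=int)
    for it in range(n_iter):
        noise = rng.standard_normal(mask.shape)
        field_ = _smooth_data(noise, fwhm_mm, voxel_sizes)
        vals = field_[mask]
        field_std = vals.std()
        binary = np.zeros(mask.shape, dtype=bool)
        binary[mask] = (vals - vals.mean()) / field_std > z_thresh
        labels, n_labels = ndimage.label(binary, structure=structure)
        if n_labels:
            sizes = np.bincount(labels.ravel())[1:]
            max_sizes[it] = sizes.max()
    # smallest k with P(max >= k) <= corrected_p
    for k in range(0, max_sizes.max() + 2):
        if np.mean(max_sizes >= k) <= corrected_p:
            return int(k)
    return int(max_sizes.max() + 1)


@dataclass
class ClusterResult:
    clusters: pd.DataFrame           # size, peak voxel, peak value, peak mm
    labels: np.ndarray = field(repr=False, default=None)
    min_size: int = 1
    forming_threshold: float = 0.0
    connectivity: int = 18

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)


def find_clusters(stat_map: np.ndarray, forming_threshold: float,
                  connectivity: int = 18, min_size: int = 1,
                  mask: np.ndarray | None = None,
                  affine: np.ndarray | None = None,
                  direction: str = "greater") -> ClusterResult:
    """Connected components of suprathreshold voxels, filtered by size.

    ``direction="greater"`` keeps voxels with stat > threshold;
    ``direction="less"`` keeps stat < threshold (e.g. negative t values for
    a decrease).  Peak locations are reported in voxel indices and, when an
    affine is given, in mm.
    """
    stat_map = np.asarray(stat_map, dtype=float)
    structure = _connectivity_structure(connectivity)
    if direction == "greater":
        supra = stat_map > forming_threshold
    elif direction == "less":
        supra = stat_map < forming_threshold
    else:
        raise ValueError("direction must be 'greater' or 'less'")
    supra &= np.isfinite(stat_map)
    if mask is not None:
        supra &= np.asarray(mask, dtype=bool)
    labels, n_labels = ndimage.label(supra, structure=structure)
    rows = []
    keep = np.zeros_like(labels)
    next_id = 0
    for lab in range(1, n_labels + 1):
        voxels = np.argwhere(labels == lab)
        if len(voxels) < min_size:
            continue
        next_id += 1
        keep[labels == lab] = next_id
        values = stat_map[tuple(voxels.T)]
        peak_idx = voxels[np.argmax(values if direction == "greater" else -values)]
        row = {"cluster": next_id, "size": len(voxels),
               "peak_i": int(peak_idx[0]), "peak_j": int(peak_idx[1]),
               "peak_k": int(peak_idx[2]),
               "peak_stat": float(stat_map[tuple(peak_idx)])}
        if affine is not None:
            mm = np.asarray(affine)[:3, :3] @ peak_idx + np.asarray(affine)[:3, 3]
            row.update({"peak_x_mm": float(mm[0]), "peak_y_mm": float(mm[1]),
                        "peak_z_mm": float(mm[2])})
        rows.append(row)
    frame = pd.DataFrame(rows, columns=["cluster", "size", "peak_i", "peak_j",
                                        "peak_k", "peak_stat"]
                         + (["peak_x_mm", "peak_y_mm", "peak_z_mm"]
                            if affine is not None else []))
    return ClusterResult(clusters=frame, labels=keep, min_size=min_size,
                         forming_threshold=forming_threshold,
                         connectivity=connectivity)


# -- study-level pipeline ----------------------------------------------


def _study_degree_maps(study, theta: float, direction: str, fwhm_mm: float,
                       mask: np.ndarray | None, discard_initial: int = 2
                       ) -> dict[str, dict[str, list[DegreeMap]]]:
    """Degree maps per group and session for a voxel-rendered study."""
    from .network import preprocess_rest_run

    params = DegreeParams(threshold=theta, direction=direction,
                          smoothing_fwhm=fwhm_mm)
    out: dict[str, dict[str, list[DegreeMap]]] = {}
    for subj in study.subjects:
        for session, rest in subj.sessions.items():
            if rest.bold is None:
                raise ValueError(
                    "degree analysis needs voxel data; simulate with render_voxels=True")
            cleaned = preprocess_rest_run(rest.bold, rest.confounds,
                                          smoothing_fwhm=fwhm_mm,
                                          discard_initial=discard_initial)
            dmap = degree_map(cleaned, params, mask=mask)
            out.setdefault(subj.group, {}).setdefault(session, []).append(dmap)
    return out


def threshold_sweep(study, thetas, direction: str = "less",
                    fwhm_mm: float = 10.0, voxel_p: float = 0.005,
                    corrected_p: float = 0.05, n_iter: int = 500,
                    mask: np.ndarray | None = None,
                    connectivity: int = 18,
                    seed: int | np.random.Generator = 0,
                    sessions: tuple[str, str] = ("pre", "post")) -> pd.DataFrame:
    """Re-run the degree pipeline per correlation threshold; tabulate clusters.

    For each theta: per-subject pre/post degree maps -> paired t of the
    decrease -> clusters larger than the Monte-Carlo minimum size (computed
    once for the mask/smoothness, independent of theta).
    """
    thetas = list(thetas)
    if any(not -1.0 < th < 1.0 for th in thetas):
        raise ValueError("thresholds must lie in (-1, 1)")
    if mask is None:
        mask = np.ones(study.registry.grid.shape, dtype=bool)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    min_size = cluster_threshold_mc(mask, study.registry.grid.voxel_sizes,
                                    fwhm_mm, voxel_p=voxel_p,
                                    corrected_p=corrected_p, n_iter=n_iter,
                                    seed=rng, connectivity=connectivity)
    rows = []
    for theta in thetas:
        maps = _study_degree_maps(study, theta, direction, fwhm_mm, mask)
        for group, by_session in maps.items():
            pre, post = by_session[sessions[0]], by_session[sessions[1]]
            t_map = degree_change_test(pre, post)
            df = len(pre) - 1
            t_crit = stats.t.isf(voxel_p, df)
            result = find_clusters(t_map, -t_crit, connectivity=connectivity,
                                   min_size=min_size, mask=mask,
                                   affine=study.registry.grid.affine,
                                   direction="less")
            rows.append({"group": group, "theta": theta,
                         "min_cluster_size": min_size,
                         "n_clusters": result.n_clusters,
                         "largest": int(result.clusters["size"].max())
                         if result.n_clusters else 0})
    return pd.DataFrame(rows)


def roi_significance_ratio(significance_mask: np.ndarray,
                           registry: RoiRegistry,
                           voxel_sets: dict[str, np.ndarray] | None = None
                           ) -> pd.DataFrame:
    """Percentage of significantly changed voxels within each ROI."""
    significance_mask = np.asarray(significance_mask, dtype=bool)
    if significance_mask.shape != tuple(registry.grid.shape):
        raise ValueError("significance map shape does not match the registry grid")
    voxel_sets = voxel_sets or registry.voxel_sets()
    rows = []
    for name, vox in voxel_sets.items():
        if len(vox) == 0:
            raise ValueError(f"ROI {name!r} is empty")
        hits = significance_mask[vox[:, 0], vox[:, 1], vox[:, 2]]
        rows.append({"roi": name, "n_voxels": len(vox),
                     "n_significant": int(hits.sum()),
                     "percent": 100.0 * float(hits.mean())})
    return pd.DataFrame(rows)
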