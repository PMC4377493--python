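"""ROI-based resting-state network analysis.

Pipeline: nuisance regression of six motion parameters and three tissue-mean
signals (after discarding the first two volumes and 6-mm spatial smoothing,
when working on voxel data) -> ROI-mean time courses -> Fisher-z transformed
Pearson correlation matrices per subject and session -> post-minus-pre
difference matrices averaged within group -> "colored cell" rule (a region
pair whose increase exceeds the pooled mean + SD across all pairs and
groups) -> bootstrap confidence intervals on the number of colored cells per
network-pair type, Bonferroni-corrected across the six pair types and three
groups.  Group-level statistics (one-way ANOVA across groups of per-day mean
scores, one-sample negativity t-tests) and a Welch spectral check round out
the module.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal, stats

from .bold import CONFOUND_COLUMNS, BoldRun
from .roi import NetworkPairType, RoiRegistry, partition_network_pairs

__all__ = [
    "Z_CAP",
    "CorrelationMatrix",
    "DifferenceMatrix",
    "ColoredCellResult",
    "BootstrapPairResult",
    "preprocess_rest_run",
    "regress_confounds",
    "roi_matrix",
    "roi_matrix_from_series",
    "difference_matrices",
    "colored_cells",
    "bootstrap_pair_test",
    "negativity_tests",
    "score_group_comparison",
    "psd_check",
    "study_matrices",
    "analyze_study",
]

#: Fisher-z cap so degenerate |r| = 1 never produces infinities
Z_CAP = float(np.arctanh(1.0 - 1e-6))


def fisher_z(r: np.ndarray) -> np.ndarray:
    """Variance-stabilising z = atanh(r), capped at |z| <= Z_CAP."""
    r = np.asarray(r, dtype=float)
    r_max = np.tanh(Z_CAP)
    if np.any(np.abs(r) > r_max):
        warnings.warn("|r| at or near 1 capped before Fisher transform",
                      RuntimeWarning, stacklevel=2)
    return np.arctanh(np.clip(r, -r_max, r_max))


@dataclass
class CorrelationMatrix:
    """Symmetric ROI x ROI Fisher-z matrix for one subject and session."""

    z: pd.DataFrame
    subject: str = ""
    group: str = ""
    session: str = ""

    @property
    def roi_names(self) -> list[str]:
        return list(self.z.index)


@dataclass
class DifferenceMatrix:
    """Elementwise z difference between two sessions (or its group mean)."""

    dz: pd.DataFrame
    contrast: str = "post-pre"
    group: str = ""
    subject: str = ""

    @property
    def roi_names(self) -> list[str]:
        return list(self.dz.index)

    def upper_cells(self) -> pd.Series:
        """Off-diagonal upper-triangle cells as a Series keyed by ROI pair."""
        names = self.roi_names
        idx, vals = [], []
        for i, j in itertools.combinations(range(len(names)), 2):
            idx.append((names[i], names[j]))
            vals.append(self.dz.iat[i, j])
        return pd.Series(vals, index=pd.MultiIndex.from_tuples(idx))


# -- preprocessing -----------------------------------------------------


def regress_confounds(data: np.ndarray, confounds: pd.DataFrame | np.ndarray
                      ) -> np.ndarray:
    """Least-squares removal of confound time courses (plus an intercept).

    ``data`` is (n_volumes, n_series).  Rank-deficient confound sets are
    handled through the pseudo-inverse; residuals are orthogonal to every
    confound column.
    """
    data = np.asarray(data, dtype=float)
    conf = np.asarray(confounds, dtype=float)
    if conf.ndim == 1:
        conf = conf[:, None]
    if conf.shape[0] != data.shape[0]:
        raise ValueError(
            f"confound rows ({conf.shape[0]}) != volumes ({data.shape[0]})")
    design = np.column_stack([conf, np.ones(conf.shape[0])])
    beta = np.linalg.pinv(design) @ data
    return data - design @ beta


def preprocess_rest_run(run: BoldRun, confounds: pd.DataFrame,
                        smoothing_fwhm: float = 6.0,
                        discard_initial: int = 2) -> BoldRun:
    """Standard rest preprocessing on a voxel run.

    Discards the first ``discard_initial`` volumes (T1 equilibration),
    smooths each volume with a Gaussian kernel of ``smoothing_fwhm`` mm, and
    regresses out the nine confounds.  The confound table may cover either
    the full run or only the retained volumes.
    """
    from .degree import smooth_volume  # local import to avoid a cycle

    n_total = run.n_volumes
    retained = n_total - discard_initial
    conf = confounds[list(CONFOUND_COLUMNS)].to_numpy(dtype=float)
    if conf.shape[0] == n_total:
        conf = conf[discard_initial:]
    elif conf.shape[0] != retained:
        raise ValueError(
            f"confound table has {conf.shape[0]} rows; expected {n_total} or {retained}")
    smoothed = smooth_volume(run, smoothing_fwhm) if smoothing_fwhm > 0 else run
    data = smoothed.data[..., discard_initial:]
    flat = data.reshape(-1, retained).T  # (t, v)
    resid = regress_confounds(flat, conf)
    cleaned = resid.T.reshape(data.shape)
    return BoldRun(data=cleaned, tr_s=run.tr_s, affine=run.affine,
                   subject=run.subject, group=run.group, session=run.session,
                   provenance={**run.provenance, "preprocessed": True,
                               "smoothing_fwhm": smoothing_fwhm,
                               "discarded_volumes": discard_initial})


def preprocess_roi_series(series: pd.DataFrame, confounds: pd.DataFrame,
                          discard_initial: int = 2) -> pd.DataFrame:
    """ROI-level analogue of :func:`preprocess_rest_run` (no smoothing)."""
    data = series.to_numpy(dtype=float)[discard_initial:]
    conf = confounds[list(CONFOUND_COLUMNS)].to_numpy(dtype=float)
    if conf.shape[0] == len(series):
        conf = conf[discard_initial:]
    elif conf.shape[0] != len(data):
        raise ValueError("confound/volume count mismatch")
    resid = regress_confounds(data, conf)
    return pd.DataFrame(resid, columns=series.columns)


# -- correlation matrices ----------------------------------------------


def roi_matrix_from_series(series: pd.DataFrame, subject: str = "",
                           group: str = "", session: str = "") -> CorrelationMatrix:
    """Fisher-z correlation matrix from ROI-mean time courses."""
    data = series.to_numpy(dtype=float)
    sd = data.std(axis=0)
    if np.any(sd <= 1e-12 * max(np.abs(data).max(), 1.0)):
        bad = [c for c, s in zip(series.columns, sd) if s <= 1e-12]
        raise ValueError(f"zero-variance ROI series: {bad}")
    r = np.corrcoef(data.T)
    np.fill_diagonal(r, 0.0)  # diagonal excluded from all statistics
    z = fisher_z(r)
    frame = pd.DataFrame(z, index=series.columns, columns=series.columns)
    return CorrelationMatrix(z=frame, subject=subject, group=group, session=session)


def roi_matrix(cleaned: BoldRun, registry: RoiRegistry,
               voxel_sets: dict[str, np.ndarray] | None = None,
               **labels) -> CorrelationMatrix:
    """ROI-mean series from a preprocessed run, then the Fisher-z matrix."""
    voxel_sets = voxel_sets or registry.voxel_sets()
    series = cleaned.roi_means(voxel_sets)
    return roi_matrix_from_series(series, **labels)


def difference_matrices(matrices: dict[str, CorrelationMatrix],
                        contrast: str = "post-pre") -> DifferenceMatrix:
    """Session_b minus session_a Fisher-z matrix for one subject.

    ``contrast`` is "<session_b>-<session_a>", e.g. "post-pre" or
    "followup-pre".
    """
    later, earlier = contrast.split("-", 1)
    if later not in matrices or earlier not in matrices:
        raise KeyError(f"contrast {contrast!r} needs sessions {later!r} and {earlier!r}")
    mat_b, mat_a = matrices[later], matrices[earlier]
    if mat_b.roi_names != mat_a.roi_names:
        raise ValueError("ROI order differs between sessions")
    dz = mat_b.z - mat_a.z
    return DifferenceMatrix(dz=dz, contrast=contrast,
                            group=mat_b.group, subject=mat_b.subject)


def group_mean_difference(diffs: list[DifferenceMatrix]) -> DifferenceMatrix:
    if not diffs:
        raise ValueError("no difference matrices to average")
    names = diffs[0].roi_names
    for d in diffs:
        if d.roi_names != names:
            raise ValueError("ROI order differs across subjects")
    mean = sum(d.dz for d in diffs) / len(diffs)
    return DifferenceMatrix(dz=mean, contrast=diffs[0].contrast,
                            group=diffs[0].group, subject="")


# -- colored cells and the bootstrap test ------------------------------


@dataclass
class ColoredCellResult:
    threshold: float
    pooled_mean: float
    pooled_sd: float
    masks: dict[str, pd.DataFrame]            # group -> boolean ROI x ROI mask
    counts: pd.DataFrame                      # rows pair type, columns group

    def count(self, group: str, pair_type: str) -> int:
        return int(self.counts.loc[pair_type, group])


def colored_cells(group_diffs: dict[str, DifferenceMatrix],
                  partition: list[NetworkPairType]) -> ColoredCellResult:
    """Mark region pairs whose increase exceeds the pooled mean + SD.

    The threshold is the mean plus one standard deviation of the
    upper-triangle cells pooled across *all* groups; a cell is colored iff
    its increase is strictly greater than the threshold.
    """
    cells = {g: d.upper_cells() for g, d in group_diffs.items()}
    pooled = np.concatenate([c.to_numpy() for c in cells.values()])
    if pooled.size < 2:
        raise ValueError("need at least 2 pooled cells")
    mean, sd = float(pooled.mean()), float(pooled.std(ddof=0))
    threshold = mean + sd
    masks = {}
    counts = pd.DataFrame(index=[t.label for t in partition],
                          columns=list(group_diffs), dtype=int)
    for group, diff in group_diffs.items():
        mask = (diff.dz > threshold) & ~np.eye(len(diff.roi_names), dtype=bool)
        masks[group] = pd.DataFrame(mask, index=diff.roi_names, columns=diff.roi_names)
        colored = cells[group] > threshold
        for ptype in partition:
            n = sum(bool(colored.get(pair, False)) for pair in ptype.pairs)
            counts.loc[ptype.label, group] = n
    return ColoredCellResult(threshold=threshold, pooled_mean=mean, pooled_sd=sd,
                             masks=masks, counts=counts)


@dataclass
class BootstrapPairResult:
    table: pd.DataFrame  # per (group, pair_type): observed, ci_upper, p, significant
    threshold: float
    n_boot: int
    alpha: float
    bonferroni_factor: int
    seed: int | None
    colored: ColoredCellResult = field(repr=False, default=None)

    def significant_pairs(self) -> list[tuple[str, str]]:
        hits = self.table[self.table["significant"]]
        return list(zip(hits["group"], hits["pair_type"]))

    def summary(self) -> str:
        lines = [
            "Bootstrap colored-cell test "
            f"(n_boot={self.n_boot}, alpha={self.alpha}, "
            f"Bonferroni x{self.bonferroni_factor}, threshold={self.threshold:+.4f})",
            self.table.to_string(index=False, float_format=lambda v: f"{v:.4f}"),
        ]
        return "\n".join(lines)


def bootstrap_pair_test(group_diffs: dict[str, DifferenceMatrix],
                        partition: list[NetworkPairType],
                        n_boot: int = 3000, alpha: float = 0.05,
                        seed: int | np.random.Generator = 0,
                        pooling: str = "pooled") -> BootstrapPairResult:
    """Bootstrap CI on the number of colored cells per network-pair type.

    For each pair type of ``m`` cells, draw ``m`` cells with replacement from
    the cell population (pooled across the three group-averaged difference
    matrices by default, or per group with ``pooling="per-group"``), count how
    many exceed the colored-cell threshold, and repeat ``n_boot`` times.  The
    upper CI bound is taken at the ``100 * (1 - alpha / (types * groups))``
    percentile (Bonferroni across the six pair types and three groups); an
    observed count strictly above the bound is significant.
    """
    if pooling not in ("pooled", "per-group"):
        raise ValueError("pooling must be 'pooled' or 'per-group'")
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    colored = colored_cells(group_diffs, partition)
    groups = list(group_diffs)
    bonferroni = len(partition) * len(groups)
    tail = alpha / bonferroni
    if n_boot * tail < 1.0:
        raise ValueError(
            f"n_boot={n_boot} too small to resolve the {100 * (1 - tail):.3f} percentile")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    seed_val = None if isinstance(seed, np.random.Generator) else int(seed)

    pooled_cells = np.concatenate(
        [group_diffs[g].upper_cells().to_numpy() for g in groups])
    per_group_cells = {g: group_diffs[g].upper_cells().to_numpy() for g in groups}

    rows = []
    for group in groups:
        population = pooled_cells if pooling == "pooled" else per_group_cells[group]
        colored_pop = population > colored.threshold
        for ptype in partition:
            m = ptype.cell_count
            if m == 0:
                continue
            draws = rng.integers(0, len(population), size=(n_boot, m))
            boot_counts = colored_pop[draws].sum(axis=1)
            upper = float(np.percentile(boot_counts, 100.0 * (1.0 - tail),
                                        method="higher"))
            observed = colored.count(group, ptype.label)
            p = float((1 + np.sum(boot_counts >= observed)) / (n_boot + 1))
            rows.append({"group": group, "pair_type": ptype.label,
                         "n_cells": m, "observed": observed,
                         "ci_upper": upper, "p": p,
                         "significant": observed > upper})
    table = pd.DataFrame(rows)
    return BootstrapPairResult(table=table, threshold=colored.threshold,
                               n_boot=n_boot, alpha=alpha,
                               bonferroni_factor=bonferroni, seed=seed_val,
                               colored=colored)


# -- group statistics --------------------------------------------------


def negativity_tests(pair_set_values: dict[str, np.ndarray],
                     alternative: str = "two-sided",
                     alpha: float = 0.05) -> pd.DataFrame:
    """One-sample t-tests of Fisher-z values against zero, per pair set.

    Used to ask whether a connection (e.g. lM1-lLP) is significantly negative
    in a given session.  P-values are Bonferroni-corrected by the number of
    pair sets (capped at 1).  ``alternative="less"`` gives the one-sided
    version of the test.
    """
    n_sets = len(pair_set_values)
    rows = []
    for name, values in pair_set_values.items():
        values = np.asarray(values, dtype=float)
        if len(values) < 2:
            raise ValueError(f"{name}: need >= 2 subjects")
        if values.std(ddof=1) <= 1e-15:
            raise ValueError(f"{name}: degenerate (zero-variance) sample")
        res = stats.ttest_1samp(values, 0.0, alternative=alternative)
        p_corr = min(res.pvalue * n_sets, 1.0)
        rows.append({"pair_set": name, "n": len(values),
                     "mean_z": float(values.mean()),
                     "t": float(res.statistic), "p": float(res.pvalue),
                     "p_bonferroni": float(p_corr),
                     "significant": bool(p_corr < alpha and res.statistic < 0)})
    return pd.DataFrame(rows)


@dataclass
class GroupComparisonResult:
    f_stat: float
    p_value: float
    posthoc: pd.DataFrame

    def summary(self) -> str:
        lines = [f"One-way ANOVA: F = {self.f_stat:.3f}, p = {self.p_value:.4g}",
                 self.posthoc.to_string(index=False,
                                        float_format=lambda v: f"{v:.4f}")]
        return "\n".join(lines)


def score_group_comparison(group_values: dict[str, np.ndarray],
                           reference: str | None = None) -> GroupComparisonResult:
    """One-way ANOVA across groups plus Bonferroni-corrected post-hoc t-tests.

    ``group_values`` maps each group to its observations (e.g. per-day mean
    scores).  Post-hoc two-sample t-tests compare the reference group
    (default: the first) against each other group, with p-values multiplied
    by the number of comparisons.
    """
    if len(group_values) < 2:
        raise ValueError("need >= 2 groups")
    arrays = {g: np.asarray(v, dtype=float) for g, v in group_values.items()}
    for g, v in arrays.items():
        if len(v) < 2:
            raise ValueError(f"group {g!r}: need >= 2 observations")
    anova = stats.f_oneway(*arrays.values())
    reference = reference or next(iter(arrays))
    others = [g for g in arrays if g != reference]
    rows = []
    for other in others:
        res = stats.ttest_ind(arrays[reference], arrays[other])
        rows.append({"comparison": f"{reference} vs {other}",
                     "t": float(res.statistic), "df": len(arrays[reference]) + len(arrays[other]) - 2,
                     "p": float(res.pvalue),
                     "p_bonferroni": float(min(res.pvalue * len(others), 1.0))})
    return GroupComparisonResult(f_stat=float(anova.statistic),
                                 p_value=float(anova.pvalue),
                                 posthoc=pd.DataFrame(rows))


def psd_check(series: np.ndarray, tr_s: float,
              nperseg: int | None = None) -> tuple[np.ndarray, np.ndarray, float]:
    """Welch spectral density on [0, Nyquist] and the dominant frequency.

    Returns (frequencies, density, peak_frequency); the DC bin is excluded
    from the peak search.  Used to confirm that resting-state power is
    concentrated below 0.05 Hz, under the 0.06-Hz cutoff of the online
    training filter.
    """
    series = np.asarray(series, dtype=float)
    if len(series) < 16:
        raise ValueError("series too short for a spectral estimate (need >= 16)")
    nperseg = nperseg or min(len(series), 256)
    freqs, density = signal.welch(series, fs=1.0 / tr_s, nperseg=nperseg)
    peak = float(freqs[1:][np.argmax(density[1:])])
    return freqs, density, peak


# -- study-level drivers -----------------------------------------------


def study_matrices(study, discard_initial: int = 2) -> list[CorrelationMatrix]:
    """Per-subject, per-session Fisher-z matrices from a simulated study.

    Runs the ROI-level nuisance regression (motion + tissue means) after
    discarding the first two volumes, then correlates the residual ROI-mean
    series.
    """
    out = []
    for subj in study.subjects:
        for session, rest in subj.sessions.items():
            cleaned = preprocess_roi_series(rest.roi_series, rest.confounds,
                                            discard_initial=discard_initial)
            out.append(roi_matrix_from_series(cleaned, subject=subj.subject_id,
                                              group=subj.group, session=session))
    return out


@dataclass
class StudyAnalysisResult:
    contrast: str
    group_diffs: dict[str, DifferenceMatrix]
    bootstrap: BootstrapPairResult
    matrices: list[CorrelationMatrix] = field(repr=False, default_factory=list)

    def summary(self) -> str:
        return self.bootstrap.summary()


def analyze_study(study, contrast: str = "post-pre", n_boot: int = 3000,
                  alpha: float = 0.05, seed: int | np.random.Generator = 0,
                  pooling: str = "pooled") -> StudyAnalysisResult:
    """Difference matrices, colored cells and the bootstrap test for a study."""
    matrices = study_matrices(study)
    by_subject: dict[str, dict[str, CorrelationMatrix]] = {}
    groups_of: dict[str, str] = {}
    for mat in matrices:
        by_subject.setdefault(mat.subject, {})[mat.session] = mat
        groups_of[mat.subject] = mat.group
    diffs_by_group: dict[str, list[DifferenceMatrix]] = {}
    for subject, sessions in by_subject.items():
        diff = difference_matrices(sessions, contrast=contrast)
        diffs_by_group.setdefault(groups_of[subject], []).append(diff)
    group_diffs = {g: group_mean_difference(d) for g, d in diffs_by_group.items()}
    partition = partition_network_pairs(study.registry)
    boot = bootstrap_pair_test(group_diffs, partition, n_boot=n_boot,
                               alpha=alpha, seed=seed, pooling=pooling)
    return StudyAnalysisResult(contrast=contrast, group_diffs=group_diffs,
                               bootstrap=boot, matrices=matrices)
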