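"""Online connectivity-neurofeedback computation.

The engine ingests a stream of per-volume BOLD samples for two target ROIs,
high-pass filters the accumulated ROI-mean time courses (0.06 Hz cutoff),
windows each imagery period (drop the first imagery volume, append the first
feedback-period volume to partly compensate the hemodynamic delay), computes
the Pearson correlation of the two windowed courses, and converts it to a
feedback score relative to the subject's own baseline:

    score_i = (r_i - r_initial) / (1 + |r_initial|) * 100

where ``r_initial`` is the correlation averaged over the trials of the
initial block of the first training day.  The added 1 in the denominator
keeps the score within [-100, +100].  During the initial block no score is
delivered; the block only establishes the baseline.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Protocol, Sequence

import numpy as np
from scipy import signal

__all__ = [
    "TrialSchedule",
    "BaselineState",
    "FeedbackTrialResult",
    "SessionResult",
    "DegenerateTrialError",
    "highpass_filter",
    "assemble_trial_window",
    "trial_correlation",
    "feedback_score",
    "compute_baseline",
    "run_session",
    "replay_session",
    "yoke_sham_scores",
    "BoldStreamSource",
]

logger = logging.getLogger(__name__)


class DegenerateTrialError(ValueError):
    """A trial window had zero variance; its correlation is undefined."""


@dataclass(frozen=True)
class TrialSchedule:
    """Timing of one training trial and its blocking.

    Defaults: 14 s rest, 14 s imagery, intermittent feedback, TR 2 s,
    10 trials per block.
    """

    rest_s: float = 14.0
    imagery_s: float = 14.0
    feedback_s: float = 6.0
    trials_per_block: int = 10
    blocks_per_day: int = 5
    tr_s: float = 2.0

    def __post_init__(self) -> None:
        for name in ("rest_s", "imagery_s", "feedback_s", "tr_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.trials_per_block < 1:
            raise ValueError("trials_per_block must be >= 1")
        if abs(self.imagery_s / self.tr_s - round(self.imagery_s / self.tr_s)) > 1e-9:
            raise ValueError("imagery_s must be an integer multiple of tr_s")

    @property
    def rest_volumes(self) -> int:
        return int(round(self.rest_s / self.tr_s))

    @property
    def imagery_volumes(self) -> int:
        return int(round(self.imagery_s / self.tr_s))

    @property
    def feedback_volumes(self) -> int:
        return max(int(round(self.feedback_s / self.tr_s)), 1)

    @property
    def volumes_per_trial(self) -> int:
        return self.rest_volumes + self.imagery_volumes + self.feedback_volumes

    @property
    def window_length(self) -> int:
        """Samples entering the trial correlation (imagery minus one, plus one)."""
        return self.imagery_volumes


@dataclass
class BaselineState:
    """Per-subject baseline correlation from the day-1 initial block."""

    correlation_initial: float
    n_trials: int = 0

    def __post_init__(self) -> None:
        if not -1.0 <= self.correlation_initial <= 1.0:
            raise ValueError("baseline correlation must lie in [-1, 1]")


@dataclass
class FeedbackTrialResult:
    trial_index: int
    block: int
    day: int
    correlation: float | None
    score: float | None
    window_volume_indices: tuple[int, ...]
    degenerate: bool = False


@dataclass
class SessionResult:
    trials: list[FeedbackTrialResult]
    block_means: list[float | None]
    baseline: BaselineState
    roi_a_series: np.ndarray
    roi_b_series: np.ndarray
    reward_total: float = 0.0
    provenance: dict = field(default_factory=dict)

    def scores(self) -> np.ndarray:
        return np.array([t.score for t in self.trials if t.score is not None], dtype=float)


# -- primitive operations ----------------------------------------------


def _design_highpass(cutoff_hz: float, tr_s: float, order: int = 5) -> np.ndarray:
    nyquist = 0.5 / tr_s
    if cutoff_hz >= nyquist:
        raise ValueError(f"cutoff {cutoff_hz} Hz must be below Nyquist {nyquist} Hz")
    if cutoff_hz <= 0:
        raise ValueError("cutoff must be positive")
    return signal.butter(order, cutoff_hz, btype="highpass", fs=1.0 / tr_s, output="sos")


def highpass_filter(series: np.ndarray, cutoff_hz: float = 0.06, tr_s: float = 2.0,
                    mode: str = "online", order: int = 5) -> np.ndarray:
    """High-pass filter a time series (Butterworth, default 5th order).

    ``mode="online"`` applies the filter causally (no future samples), as a
    real-time system must; ``mode="offline"`` applies it forward and backward
    for zero phase distortion.
    """
    series = np.asarray(series, dtype=float)
    if series.ndim != 1:
        raise ValueError("series must be 1D")
    sos = _design_highpass(cutoff_hz, tr_s, order)
    if mode == "online":
        if len(series) < order + 1:
            raise ValueError(f"series too short for order-{order} filter: {len(series)}")
        return signal.sosfilt(sos, series)
    if mode == "offline":
        padlen = 3 * (2 * sos.shape[0] + 1)
        if len(series) <= padlen:
            raise ValueError(f"series too short for zero-phase filtering: {len(series)}")
        return signal.sosfiltfilt(sos, series)
    raise ValueError(f"mode must be 'online' or 'offline', got {mode!r}")


def assemble_trial_window(imagery_volumes: Sequence[float],
                          feedback_first_volume: float,
                          expected_imagery: int = 7) -> np.ndarray:
    """Drop the first imagery sample and append the first feedback sample.

    With 7 imagery volumes (14 s at TR 2 s) the window is
    ``[v2..v7, f1]`` — length 7.  The one-volume shift partly compensates the
    hemodynamic delay while keeping the feedback prompt.
    """
    imagery = np.asarray(imagery_volumes, dtype=float)
    if imagery.ndim != 1 or len(imagery) != expected_imagery:
        raise ValueError(
            f"expected exactly {expected_imagery} imagery samples, got {imagery.shape}"
        )
    return np.concatenate([imagery[1:], [float(feedback_first_volume)]])


def trial_correlation(window_a: Sequence[float], window_b: Sequence[float]) -> float:
    """Pearson correlation of two trial windows.

    Raises :class:`DegenerateTrialError` if either window has (numerically)
    zero variance — a degenerate trial must be skipped and logged, never
    silently scored as zero.
    """
    a = np.asarray(window_a, dtype=float)
    b = np.asarray(window_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("windows must be 1D and of equal length")
    if len(a) < 3:
        raise ValueError("windows must contain at least 3 samples")
    sd_a, sd_b = a.std(), b.std()
    scale = max(np.abs(a).max(), np.abs(b).max(), 1.0)
    if sd_a <= 1e-12 * scale or sd_b <= 1e-12 * scale:
        raise DegenerateTrialError("zero-variance trial window")
    r = float(np.corrcoef(a, b)[0, 1])
    return float(np.clip(r, -1.0, 1.0))


def feedback_score(correlation_i: float, correlation_initial: float) -> float:
    """The intermittent feedback score.

    ``(r_i - r_init) / (1 + |r_init|) * 100``; bounded in [-100, 100], with
    a positive score whenever the trial correlation exceeds the baseline —
    including when a negative correlation merely becomes less negative.
    """
    for name, value in (("correlation_i", correlation_i),
                        ("correlation_initial", correlation_initial)):
        if not -1.0 <= value <= 1.0:
            raise ValueError(f"{name} must lie in [-1, 1], got {value}")
    return (correlation_i - correlation_initial) / (1.0 + abs(correlation_initial)) * 100.0


def compute_baseline(initial_block_correlations: Sequence[float]) -> BaselineState:
    """Arithmetic mean of the raw trial correlations of the initial block."""
    values = [v for v in initial_block_correlations if v is not None and np.isfinite(v)]
    if not values:
        raise ValueError("cannot compute a baseline from zero valid trials")
    return BaselineState(correlation_initial=float(np.mean(values)), n_trials=len(values))


# -- session sources ---------------------------------------------------


class SessionSource(Protocol):
    """Anything that can feed the engine one ROI-pair sample per volume."""

    def begin_trial(self, rng: np.random.Generator) -> None: ...

    def sample_volume(self, phase: str, rng: np.random.Generator) -> tuple[float, float]: ...

    def receive_score(self, score: float, rng: np.random.Generator) -> None: ...


class BoldStreamSource:
    """Replay a recorded :class:`~connfeed.bold.BoldRun` as a session source.

    ROI-mean samples are taken volume-by-volume in acquisition order from the
    two target ROI voxel sets, which must be nonempty and disjoint.
    """

    def __init__(self, run, roi_a_voxels: np.ndarray, roi_b_voxels: np.ndarray):
        if len(roi_a_voxels) == 0 or len(roi_b_voxels) == 0:
            raise ValueError("target ROI voxel sets must be nonempty")
        set_a = {tuple(v) for v in np.asarray(roi_a_voxels)}
        set_b = {tuple(v) for v in np.asarray(roi_b_voxels)}
        if set_a & set_b:
            raise ValueError("target ROI voxel sets must be disjoint")
        va, vb = np.asarray(roi_a_voxels), np.asarray(roi_b_voxels)
        self._a = run.data[va[:, 0], va[:, 1], va[:, 2], :].mean(axis=0)
        self._b = run.data[vb[:, 0], vb[:, 1], vb[:, 2], :].mean(axis=0)
        self._cursor = 0

    def begin_trial(self, rng: np.random.Generator) -> None:
        pass

    def sample_volume(self, phase: str, rng: np.random.Generator) -> tuple[float, float]:
        if self._cursor >= len(self._a):
            raise RuntimeError("BOLD stream underrun: run shorter than the schedule")
        a, b = self._a[self._cursor], self._b[self._cursor]
        self._cursor += 1
        return float(a), float(b)

    def receive_score(self, score: float, rng: np.random.Generator) -> None:
        pass


# -- the session loop --------------------------------------------------


def _window_correlation(a_hist: np.ndarray, b_hist: np.ndarray,
                        imagery_idx: np.ndarray, feedback_idx: int,
                        cutoff_hz: float, tr_s: float) -> tuple[float, tuple[int, ...]]:
    """Causally filter the history up to the first feedback volume and
    correlate the assembled windows.  Used identically online and in replay,
    so offline recomputation is bit-exact."""
    upto = feedback_idx + 1
    fa = highpass_filter(a_hist[:upto], cutoff_hz=cutoff_hz, tr_s=tr_s, mode="online")
    fb = highpass_filter(b_hist[:upto], cutoff_hz=cutoff_hz, tr_s=tr_s, mode="online")
    n_im = len(imagery_idx)
    win_idx = tuple(int(i) for i in imagery_idx[1:]) + (int(feedback_idx),)
    wa = assemble_trial_window(fa[imagery_idx], fa[feedback_idx], expected_imagery=n_im)
    wb = assemble_trial_window(fb[imagery_idx], fb[feedback_idx], expected_imagery=n_im)
    return trial_correlation(wa, wb), win_idx


def run_session(source: SessionSource, schedule: TrialSchedule,
                n_blocks: int | None = None, baseline: BaselineState | None = None,
                day: int = 1, seed: int | np.random.Generator = 0,
                cutoff_hz: float = 0.06,
                max_degenerate_fraction: float = 0.5) -> SessionResult:
    """Run one training session (day) through the online engine.

    If ``baseline`` is None the first block is the day-1 initial block: its
    trial correlations are collected with scores suppressed, and their mean
    becomes the baseline for every subsequent trial.  Block summaries are the
    mean trial score within each block; the reward ledger accumulates block
    means floored at zero (negative scores are shown but never charged).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_blocks = schedule.blocks_per_day if n_blocks is None else int(n_blocks)
    a_hist: list[float] = []
    b_hist: list[float] = []
    trials: list[FeedbackTrialResult] = []
    block_means: list[float | None] = []
    reward_total = 0.0
    baseline_pending = baseline is None
    pending_correlations: list[float] = []
    n_degenerate = 0
    trial_counter = 0

    for block in range(n_blocks):
        block_scores: list[float] = []
        for _trial in range(schedule.trials_per_block):
            source.begin_trial(rng)
            for _ in range(schedule.rest_volumes):
                a, b = source.sample_volume("rest", rng)
                a_hist.append(a)
                b_hist.append(b)
            imagery_idx = []
            for _ in range(schedule.imagery_volumes):
                a, b = source.sample_volume("imagery", rng)
                imagery_idx.append(len(a_hist))
                a_hist.append(a)
                b_hist.append(b)
            feedback_idx = None
            for k in range(schedule.feedback_volumes):
                a, b = source.sample_volume("feedback", rng)
                if k == 0:
                    feedback_idx = len(a_hist)
                a_hist.append(a)
                b_hist.append(b)
            try:
                r_i, win_idx = _window_correlation(
                    np.asarray(a_hist), np.asarray(b_hist),
                    np.asarray(imagery_idx), feedback_idx, cutoff_hz, schedule.tr_s)
            except DegenerateTrialError:
                n_degenerate += 1
                logger.warning("degenerate trial %d skipped (zero-variance window)",
                               trial_counter)
                trials.append(FeedbackTrialResult(
                    trial_index=trial_counter, block=block, day=day,
                    correlation=None, score=None,
                    window_volume_indices=(), degenerate=True))
                trial_counter += 1
                continue
            if baseline_pending and block == 0:
                pending_correlations.append(r_i)
                score = None  # no score in the day-1 initial block
            else:
                score = feedback_score(r_i, baseline.correlation_initial)
                block_scores.append(score)
                source.receive_score(score, rng)
            trials.append(FeedbackTrialResult(
                trial_index=trial_counter, block=block, day=day,
                correlation=r_i, score=score,
                window_volume_indices=win_idx))
            trial_counter += 1
        if baseline_pending and block == 0:
            baseline = compute_baseline(pending_correlations)
            baseline_pending = False
            block_means.append(None)
        else:
            mean = float(np.mean(block_scores)) if block_scores else None
            block_means.append(mean)
            if mean is not None:
                reward_total += max(mean, 0.0)

    if n_degenerate > max_degenerate_fraction * max(trial_counter, 1):
        raise DegenerateTrialError(
            f"{n_degenerate}/{trial_counter} trials degenerate "
            f"(> {max_degenerate_fraction:.0%} allowed)")
    return SessionResult(trials=trials, block_means=block_means, baseline=baseline,
                         roi_a_series=np.asarray(a_hist), roi_b_series=np.asarray(b_hist),
                         reward_total=reward_total,
                         provenance={"day": day, "n_blocks": n_blocks,
                                     "cutoff_hz": cutoff_hz})


def replay_session(roi_a_series: np.ndarray, roi_b_series: np.ndarray,
                   schedule: TrialSchedule, n_blocks: int,
                   baseline: BaselineState | None = None, day: int = 1,
                   cutoff_hz: float = 0.06) -> SessionResult:
    """Offline recomputation of a session from its logged ROI-mean volumes.

    Uses the same causal filtering and windowing as the online loop, so
    scores reproduce bit-exactly.
    """

    class _Replay:
        def __init__(self, a, b):
            self._a, self._b = np.asarray(a, float), np.asarray(b, float)
            self._cursor = 0

        def begin_trial(self, rng):
            pass

        def sample_volume(self, phase, rng):
            if self._cursor >= len(self._a):
                raise RuntimeError("logged series shorter than the schedule")
            pair = (float(self._a[self._cursor]), float(self._b[self._cursor]))
            self._cursor += 1
            return pair

        def receive_score(self, score, rng):
            pass

    return run_session(_Replay(roi_a_series, roi_b_series), schedule,
                       n_blocks=n_blocks, baseline=baseline, day=day,
                       cutoff_hz=cutoff_hz)


# -- sham yoking -------------------------------------------------------


def yoke_sham_scores(donor_series: dict[str, Sequence[float]],
                     recipients: Sequence[str],
                     seed: int | np.random.Generator = 0
                     ) -> dict[str, tuple[str, np.ndarray]]:
    """Assign each sham recipient one donor's full score time series.

    No donor is assigned twice, and when the donor and recipient pools
    overlap nobody receives their own series.  With equal pool sizes the
    assignment is a bijection.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    donors = list(donor_series)
    if len(donors) < 2:
        raise ValueError("need at least 2 donors for sham yoking")
    if len(donors) < len(recipients):
        raise ValueError(
            f"fewer donors ({len(donors)}) than recipients ({len(recipients)})")
    for _attempt in range(1000):
        order = list(rng.permutation(donors))
        assignment = dict(zip(recipients, order))
        if all(d != r for r, d in assignment.items()):
            return {r: (d, np.asarray(donor_series[d], dtype=float))
                    for r, d in assignment.items()}
    raise RuntimeError("could not find a self-avoiding yoking assignment")
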