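"""Synthetic multi-subject BOLD generation and a reward-driven virtual subject.

The generator is a latent-signal model: each ROI carries a unit-variance
latent time course drawn from a multivariate normal with a prescribed
ROI-by-ROI correlation matrix; voxels within an ROI share that latent signal
plus independent Gaussian noise, and every series receives a shared
low-frequency drift that also loads onto the synthetic tissue-mean confound
channels (so the nuisance-regression stage of the analysis is exercised
honestly).  The prescribed matrix is built from a three-network factor model
(MVN, DMN, control): within-network correlation ``lambda2`` and
between-network correlation ``lambda2 * c(net_a, net_b)``, reproducing the
characteristic pre-training MVN-DMN anticorrelation (about -0.3).

The virtual subject is a deliberately simple scalar learner: it holds a
latent coupling (the correlation its two target ROIs express during imagery),
explores it with per-trial Gaussian jitter, and reinforces exploration that
earned a higher feedback score.  With veridical feedback this climbs; with
yoked sham scores, which carry no information about the subject's own
exploration, there is no systematic drift.  No cognitive realism is claimed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .bold import CONFOUND_COLUMNS, BoldRun
from .feedback import (BaselineState, SessionResult, TrialSchedule, run_session,
                       yoke_sham_scores)
from .roi import NETWORKS, RoiRegistry, pair_type_label, synthetic_registry

__all__ = [
    "NetworkCovarianceSpec",
    "default_covariance_spec",
    "nearest_psd",
    "orthonormal_timecourses",
    "simulate_rest_run",
    "simulate_roi_rest",
    "RewardAgent",
    "simulate_training_trial",
    "run_training_course",
    "TrainingCourse",
    "StudyConfig",
    "SimulatedStudy",
    "simulate_study",
]

PSD_TOLERANCE = 1e-6

#: default within-network correlation (factor loading squared)
DEFAULT_LAMBDA2 = 0.4
#: default between-network factor correlations, keyed by pair-type label;
#: chosen so that MVN-DMN region pairs correlate at about -0.3 before training
DEFAULT_FACTOR_CORR = {"MVN-DMN": -0.75, "MVN-control": 0.25, "DMN-control": 0.0}


def nearest_psd(matrix: np.ndarray, tol: float = PSD_TOLERANCE) -> np.ndarray:
    """Repair a slightly non-PSD symmetric matrix by eigenvalue clipping.

    Eigenvalues above ``-tol`` are clipped to zero; anything more negative is
    an error (the matrix is not a small perturbation of a valid one).
    """
    matrix = np.asarray(matrix, dtype=float)
    sym = 0.5 * (matrix + matrix.T)
    vals, vecs = np.linalg.eigh(sym)
    if vals.min() < -tol:
        raise ValueError(
            f"matrix is not positive semidefinite (min eigenvalue {vals.min():.3g})")
    vals = np.clip(vals, 0.0, None)
    return (vecs * vals) @ vecs.T


@dataclass(frozen=True)
class NetworkCovarianceSpec:
    """Target correlation structure and confound levels for one rest run."""

    roi_names: tuple[str, ...]
    target_corr: np.ndarray = field(repr=False)
    voxel_noise_sd: float = 1.0
    roi_noise_sd: float = 0.316  # ROI-mean measurement noise (~voxel noise / sqrt(10))
    drift_amplitude: float = 0.5
    drift_period_s: float = 100.0
    hrf_smoothing: float = 0.0  # AR(1)-style temporal smoothing constant in [0, 1)

    def __post_init__(self) -> None:
        corr = np.asarray(self.target_corr, dtype=float)
        n = len(self.roi_names)
        if corr.shape != (n, n):
            raise ValueError(f"target_corr must be {n}x{n}, got {corr.shape}")
        if not np.allclose(corr, corr.T, atol=1e-12):
            raise ValueError("target_corr must be symmetric")
        if not np.allclose(np.diag(corr), 1.0, atol=1e-12):
            raise ValueError("target_corr must have a unit diagonal")
        if np.abs(corr).max() > 1.0 + 1e-12:
            raise ValueError("correlations must satisfy |r| <= 1")
        repaired = nearest_psd(corr)  # raises if non-PSD beyond tolerance
        np.fill_diagonal(repaired, 1.0)
        object.__setattr__(self, "target_corr", repaired)
        object.__setattr__(self, "roi_names", tuple(self.roi_names))
        if not 0.0 <= self.hrf_smoothing < 1.0:
            raise ValueError("hrf_smoothing must lie in [0, 1)")


def _factor_target_corr(networks: dict[str, str], lambda2: float,
                        factor_corr: dict[str, float]) -> np.ndarray:
    names = list(networks)
    n = len(names)
    corr = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            net_i, net_j = networks[names[i]], networks[names[j]]
            if net_i == net_j:
                r = lambda2
            else:
                r = lambda2 * factor_corr[pair_type_label(net_i, net_j)]
            corr[i, j] = corr[j, i] = r
    return corr


def default_covariance_spec(registry: RoiRegistry | None = None,
                            lambda2: float = DEFAULT_LAMBDA2,
                            factor_corr: dict[str, float] | None = None,
                            **kwargs) -> NetworkCovarianceSpec:
    """Pre-training network structure on the 16-ROI registry."""
    registry = registry or synthetic_registry()
    fc = dict(DEFAULT_FACTOR_CORR)
    if factor_corr:
        fc.update(factor_corr)
    corr = _factor_target_corr(registry.networks_of(), lambda2, fc)
    return NetworkCovarianceSpec(roi_names=tuple(registry.names),
                                 target_corr=nearest_psd(corr, tol=np.inf), **kwargs)


def orthonormal_timecourses(n_volumes: int, k: int,
                            seed: int | np.random.Generator = 0) -> np.ndarray:
    """(n_volumes, k) zero-mean, mutually orthogonal, unit-norm time courses.

    Building blocks for series with *exactly* prescribed pairwise Pearson
    correlations: for unit vectors orthogonal to the constant vector,
    corr(a e1 + b e2, e1) = a / sqrt(a^2 + b^2) exactly.
    """
    if k >= n_volumes:
        raise ValueError("need n_volumes > k for zero-mean orthonormal courses")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    mat = rng.standard_normal((n_volumes, k))
    mat -= mat.mean(axis=0)  # orthogonal to the constant vector
    q, _ = np.linalg.qr(mat)
    return q[:, :k]


# -- rest-run simulation -----------------------------------------------


def _draw_latents(spec: NetworkCovarianceSpec, n_volumes: int,
                  rng: np.random.Generator) -> np.ndarray:
    vals, vecs = np.linalg.eigh(spec.target_corr)
    root = vecs * np.sqrt(np.clip(vals, 0.0, None))
    latents = rng.standard_normal((n_volumes, len(spec.roi_names))) @ root.T
    if spec.hrf_smoothing > 0.0:
        # identical AR(1) smoothing on every channel leaves the lag-0
        # cross-correlation structure unchanged
        a = spec.hrf_smoothing
        for t in range(1, n_volumes):
            latents[t] = a * latents[t - 1] + np.sqrt(1 - a * a) * latents[t]
    return latents


def _drift(spec: NetworkCovarianceSpec, n_volumes: int, tr_s: float,
           rng: np.random.Generator) -> np.ndarray:
    phase = rng.uniform(0.0, 2.0 * np.pi)
    t = np.arange(n_volumes) * tr_s
    return spec.drift_amplitude * np.sin(2.0 * np.pi * t / spec.drift_period_s + phase)


def _confounds(drift: np.ndarray, rng: np.random.Generator) -> pd.DataFrame:
    n = len(drift)
    motion = np.cumsum(rng.normal(0.0, 0.02, size=(n, 6)), axis=0)
    tissue_load = np.array([1.0, 0.8, 0.6])
    tissue = drift[:, None] * tissue_load + rng.normal(0.0, 0.02, size=(n, 3))
    table = np.c_[motion, tissue]
    return pd.DataFrame(table, columns=list(CONFOUND_COLUMNS))


def simulate_roi_rest(spec: NetworkCovarianceSpec, n_volumes: int, tr_s: float = 2.0,
                      seed: int | np.random.Generator = 0
                      ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate ROI-mean time courses directly (no voxel rendering).

    Returns the ROI-mean table (n_volumes x n_rois) and the matching
    confound table.  The observed series are latent + measurement noise +
    shared drift; their correlations converge to the target attenuated by
    the measurement-noise factor ``1 / (1 + roi_noise_sd**2)``.
    """
    if n_volumes < 3:
        raise ValueError(f"n_volumes must be >= 3, got {n_volumes}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    latents = _draw_latents(spec, n_volumes, rng)
    drift = _drift(spec, n_volumes, tr_s, rng)
    noise = rng.normal(0.0, spec.roi_noise_sd, size=latents.shape)
    series = latents + noise + drift[:, None]
    return (pd.DataFrame(series, columns=list(spec.roi_names)),
            _confounds(drift, rng))


def simulate_rest_run(spec: NetworkCovarianceSpec, n_volumes: int, tr_s: float = 2.0,
                      seed: int | np.random.Generator = 0,
                      registry: RoiRegistry | None = None
                      ) -> tuple[BoldRun, dict[str, np.ndarray], pd.DataFrame]:
    """Render a full 4D rest run on the registry grid.

    Voxels inside an ROI share the ROI latent signal plus independent
    voxel noise; background voxels carry noise and drift only.  Returns the
    run, the ground-truth ROI voxel assignment, and the confound table.
    """
    if n_volumes < 3:
        raise ValueError(f"n_volumes must be >= 3, got {n_volumes}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    registry = registry or synthetic_registry()
    if tuple(registry.names) != tuple(spec.roi_names):
        raise ValueError("registry ROI names must match the covariance spec")
    latents = _draw_latents(spec, n_volumes, rng)
    drift = _drift(spec, n_volumes, tr_s, rng)
    voxel_sets = registry.voxel_sets()

    shape = registry.grid.shape
    data = rng.normal(0.0, spec.voxel_noise_sd, size=(*shape, n_volumes))
    data += drift  # shared drift everywhere
    for idx, name in enumerate(registry.names):
        vox = voxel_sets[name]
        data[vox[:, 0], vox[:, 1], vox[:, 2], :] += latents[:, idx]
    run = BoldRun(data=data, tr_s=tr_s, affine=registry.grid.affine,
                  provenance={"generator": "simulate_rest_run",
                              "n_volumes": n_volumes})
    return run, voxel_sets, _confounds(drift, rng)


# -- the virtual subject -----------------------------------------------


@dataclass
class RewardAgent:
    """Scalar reward-following learner closing the neurofeedback loop.

    ``coupling`` is the correlation the agent's two target ROIs express
    during imagery; it always lies in [-1, 1].  Internally the agent works
    on the unbounded Fisher-z scale (coupling = tanh(latent)), so updates
    never need a hard clip and a reward stream that carries no information
    about the agent's own exploration produces no systematic drift.  Each
    trial the agent explores the latent coupling with Gaussian jitter and,
    on receiving a score, reinforces the exploration direction in proportion
    to the baseline-subtracted reward (a normalised REINFORCE step).  With
    exploration switched off it degenerates to plain score-following
    (coupling += learning_rate * score / 100, clipped).
    """

    coupling: float = -0.3
    learning_rate: float = 0.05
    exploration_sd: float = 0.1
    rest_coupling: float | None = None  # correlation expressed at rest; defaults to coupling
    _latent: float = field(default=0.0, repr=False)
    _expressed: float = field(default=0.0, repr=False)
    _last_exploration: float = field(default=0.0, repr=False)
    _reward_baseline: float = field(default=0.0, repr=False)
    _n_rewards: int = field(default=0, repr=False)

    def __post_init__(self) -> None:
        self.coupling = float(np.clip(self.coupling, -1.0, 1.0))
        self._latent = float(np.arctanh(np.clip(self.coupling, -0.999999, 0.999999)))
        self._expressed = self.coupling

    # SessionSource protocol ------------------------------------------

    def begin_trial(self, rng: np.random.Generator) -> None:
        self._last_exploration = (rng.normal(0.0, self.exploration_sd)
                                  if self.exploration_sd > 0 else 0.0)
        self._expressed = float(np.tanh(self._latent + self._last_exploration))

    def sample_volume(self, phase: str, rng: np.random.Generator) -> tuple[float, float]:
        rho = self._expressed if phase in ("imagery", "feedback") else (
            self.coupling if self.rest_coupling is None else self.rest_coupling)
        z1, z2 = rng.standard_normal(2)
        return float(z1), float(rho * z1 + np.sqrt(max(1.0 - rho * rho, 0.0)) * z2)

    def receive_score(self, score: float, rng: np.random.Generator) -> None:
        simulate_training_trial(self, score)


def simulate_training_trial(agent: RewardAgent, score: float,
                            seed: int | np.random.Generator | None = None) -> RewardAgent:
    """Update the agent's coupling from one trial's feedback score.

    With exploration on, the step is reward times the normalised exploration
    the agent just produced, so only feedback correlated with the agent's own
    behaviour produces systematic learning (yoked sham scores do not).  With
    ``exploration_sd == 0`` the update is plain score-following.  The
    coupling is clipped to [-1, 1] after every update.
    """
    if not -100.0 - 1e-9 <= score <= 100.0 + 1e-9:
        raise ValueError(f"score must lie in [-100, 100], got {score}")
    if agent.exploration_sd > 0:
        # baseline-subtracted reward: only reward co-varying with the agent's
        # own exploration produces a systematic step
        advantage = score - agent._reward_baseline
        step = agent.learning_rate * (advantage / 100.0) * (
            agent._last_exploration / agent.exploration_sd)
        agent._n_rewards += 1
        agent._reward_baseline += (score - agent._reward_baseline) / agent._n_rewards
        agent._latent += step
        agent.coupling = float(np.tanh(agent._latent))
    else:
        step = agent.learning_rate * score / 100.0
        agent.coupling = float(np.clip(agent.coupling + step, -1.0, 1.0))
        agent._latent = float(np.arctanh(np.clip(agent.coupling, -0.999999, 0.999999)))
    return agent


class _ShamRewarded:
    """Wrap an agent so its learning signal is a yoked donor score series."""

    def __init__(self, agent: RewardAgent, donor_scores: np.ndarray):
        self.agent = agent
        self._donor = np.asarray(donor_scores, dtype=float)
        self._cursor = 0

    def begin_trial(self, rng):
        self.agent.begin_trial(rng)

    def sample_volume(self, phase, rng):
        return self.agent.sample_volume(phase, rng)

    def receive_score(self, score, rng):
        # the subject's own score is computed and logged, but the reward the
        # learner sees comes from the donor
        if self._cursor < len(self._donor):
            simulate_training_trial(self.agent, float(np.clip(
                self._donor[self._cursor], -100.0, 100.0)))
            self._cursor += 1


@dataclass
class TrainingCourse:
    day_results: list[SessionResult]
    baseline: BaselineState
    coupling_by_day: list[float]

    def day_mean_scores(self) -> np.ndarray:
        means = []
        for res in self.day_results:
            s = res.scores()
            means.append(float(s.mean()) if len(s) else np.nan)
        return np.asarray(means)

    def all_scores(self) -> np.ndarray:
        return np.concatenate([res.scores() for res in self.day_results])


def run_training_course(agent: RewardAgent, schedule: TrialSchedule | None = None,
                        days: int = 4, seed: int | np.random.Generator = 0,
                        sham_scores: np.ndarray | None = None) -> TrainingCourse:
    """Run a multi-day closed-loop training course for one virtual subject.

    Day 1 starts with the no-feedback initial block that sets the baseline.
    If ``sham_scores`` is given, the agent's reward is taken from that series
    (yoked sham) while the subject's own scores are still computed and
    logged, mirroring the control-group bookkeeping.
    """
    schedule = schedule or TrialSchedule()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    source = agent if sham_scores is None else _ShamRewarded(agent, sham_scores)
    day_results: list[SessionResult] = []
    coupling_by_day = []
    baseline: BaselineState | None = None
    for day in range(1, days + 1):
        res = run_session(source, schedule, baseline=baseline, day=day, seed=rng)
        baseline = res.baseline
        day_results.append(res)
        coupling_by_day.append(agent.coupling)
    return TrainingCourse(day_results=day_results, baseline=baseline,
                          coupling_by_day=coupling_by_day)


# -- whole-study simulation --------------------------------------------

GROUPS = ("neurofeedback", "sham", "imagery")
SESSIONS = ("pre", "post", "followup")


#: baseline target correlation per network-pair type (within = lambda2;
#: between = lambda2 * factor correlation of the two networks)
DEFAULT_PAIR_R = {
    "MVN-MVN": DEFAULT_LAMBDA2,
    "DMN-DMN": DEFAULT_LAMBDA2,
    "control-control": DEFAULT_LAMBDA2,
    "MVN-DMN": DEFAULT_LAMBDA2 * DEFAULT_FACTOR_CORR["MVN-DMN"],
    "MVN-control": DEFAULT_LAMBDA2 * DEFAULT_FACTOR_CORR["MVN-control"],
    "DMN-control": DEFAULT_LAMBDA2 * DEFAULT_FACTOR_CORR["DMN-control"],
}


@dataclass(frozen=True)
class StudyConfig:
    """Study-level knobs; defaults mirror the three-group, 33-subject design.

    Between-subject heterogeneity is a stable per-subject offset of each
    network-pair coupling, drawn on the Fisher-z scale (``trait_sd``) so the
    trait distribution is symmetric on the scale the group statistics use;
    ``session_sd`` adds smaller day-to-day state noise on the same scale.
    """

    group_sizes: dict = field(default_factory=lambda: {
        "neurofeedback": 12, "sham": 12, "imagery": 9})
    sessions: tuple[str, ...] = SESSIONS
    n_volumes: int = 152
    tr_s: float = 2.0
    delta: float = 0.2  # injected post-training MVN-DMN correlation shift (nf group)
    pair_r: dict = field(default_factory=lambda: dict(DEFAULT_PAIR_R))
    trait_sd: float = 0.165     # per-subject network-coupling trait, Fisher-z scale
    session_sd: float = 0.05    # per-session jitter (day-to-day state), same scale
    roi_noise_sd: float = 0.316
    voxel_noise_sd: float = 1.0   # used when runs are rendered to voxels
    drift_amplitude: float = 0.5
    drift_period_s: float = 100.0
    include_training: bool = False
    training_days: int = 4

    def __post_init__(self) -> None:
        unknown = set(self.group_sizes) - set(GROUPS)
        if unknown:
            raise ValueError(f"unknown groups {sorted(unknown)}; expected {GROUPS}")
        if any(n < 0 for n in self.group_sizes.values()):
            raise ValueError("group sizes must be nonnegative")


@dataclass
class RestSession:
    roi_series: pd.DataFrame
    confounds: pd.DataFrame
    target_corr: np.ndarray
    bold: BoldRun | None = None
    roi_voxels: dict | None = None


@dataclass
class SimulatedSubject:
    subject_id: str
    group: str
    sessions: dict[str, RestSession]
    training: TrainingCourse | None = None


@dataclass
class SimulatedStudy:
    config: StudyConfig
    registry: RoiRegistry
    subjects: list[SimulatedSubject]
    ground_truth: pd.DataFrame
    seed: int

    def by_group(self) -> dict[str, list[SimulatedSubject]]:
        out: dict[str, list[SimulatedSubject]] = {g: [] for g in self.config.group_sizes}
        for s in self.subjects:
            out[s.group].append(s)
        return out


def _subject_spec(config: StudyConfig, registry: RoiRegistry,
                  trait: dict[str, float], rng: np.random.Generator,
                  shifted: bool) -> NetworkCovarianceSpec:
    networks = registry.networks_of()
    names = registry.names
    corr = np.eye(len(names))
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            label = pair_type_label(networks[names[i]], networks[names[j]])
            # session state varies cell by cell; the trait is shared per type
            r = np.tanh(np.arctanh(config.pair_r[label]) + trait[label]
                        + rng.normal(0.0, config.session_sd))
            if shifted and label == "MVN-DMN":
                r = r + config.delta
            corr[i, j] = corr[j, i] = float(np.clip(r, -0.99, 0.99))
    corr = nearest_psd(corr, tol=np.inf)  # trait jitter may need repair
    scale = 1.0 / np.sqrt(np.diag(corr))  # renormalise to a correlation matrix
    corr = corr * scale[:, None] * scale[None, :]
    np.fill_diagonal(corr, 1.0)
    return NetworkCovarianceSpec(
        roi_names=tuple(names), target_corr=corr,
        roi_noise_sd=config.roi_noise_sd,
        voxel_noise_sd=config.voxel_noise_sd,
        drift_amplitude=config.drift_amplitude,
        drift_period_s=config.drift_period_s)


def simulate_study(config: StudyConfig | None = None,
                   seed: int = 0,
                   registry: RoiRegistry | None = None,
                   render_voxels: bool = False) -> SimulatedStudy:
    """Simulate the full three-group study.

    The neurofeedback group's post-training rest sessions (post and 2-month
    follow-up) have their target MVN-DMN correlations raised by
    ``config.delta`` (default +0.2); control groups get no shift.  Per-subject
    trait jitter on the network couplings is drawn once and shared across
    sessions, so pre/post differences reflect the injected shift plus
    sampling noise.  Everything is reproducible from ``seed``.
    """
    config = config or StudyConfig()
    registry = registry or synthetic_registry()
    rng = np.random.default_rng(seed)
    subjects: list[SimulatedSubject] = []
    labels = list(config.pair_r)

    for group in GROUPS:
        size = config.group_sizes.get(group, 0)
        for k in range(size):
            sid = f"{group}-{k + 1:02d}"
            trait = {lab: float(rng.normal(0.0, config.trait_sd)) for lab in labels}
            sessions: dict[str, RestSession] = {}
            for session in config.sessions:
                shifted = group == "neurofeedback" and session in ("post", "followup")
                spec = _subject_spec(config, registry, trait, rng, shifted)
                if render_voxels:
                    run, voxels, confounds = simulate_rest_run(
                        spec, config.n_volumes, config.tr_s, seed=rng,
                        registry=registry)
                    run.subject, run.group, run.session = sid, group, session
                    series = run.roi_means(voxels)
                    sessions[session] = RestSession(
                        roi_series=series, confounds=confounds,
                        target_corr=spec.target_corr, bold=run, roi_voxels=voxels)
                else:
                    series, confounds = simulate_roi_rest(
                        spec, config.n_volumes, config.tr_s, seed=rng)
                    sessions[session] = RestSession(
                        roi_series=series, confounds=confounds,
                        target_corr=spec.target_corr)
            subjects.append(SimulatedSubject(subject_id=sid, group=group,
                                             sessions=sessions))

    if config.include_training:
        _attach_training(subjects, config, rng)

    pair_types = sorted({pair_type_label(a, b)
                         for i, a in enumerate(NETWORKS) for b in NETWORKS[i:]})
    rows = []
    for group in config.group_sizes:
        for label in pair_types:
            shift = config.delta if (group == "neurofeedback" and label == "MVN-DMN") else 0.0
            rows.append({"group": group, "pair_type": label, "delta": shift})
    ground_truth = pd.DataFrame(rows)
    return SimulatedStudy(config=config, registry=registry, subjects=subjects,
                          ground_truth=ground_truth, seed=seed)


def _attach_training(subjects: list[SimulatedSubject], config: StudyConfig,
                     rng: np.random.Generator) -> None:
    schedule = TrialSchedule()
    nf = [s for s in subjects if s.group == "neurofeedback"]
    sham = [s for s in subjects if s.group == "sham"]
    imagery = [s for s in subjects if s.group == "imagery"]
    donor_scores: dict[str, np.ndarray] = {}
    for subj in nf:
        agent = RewardAgent()
        subj.training = run_training_course(agent, schedule,
                                            days=config.training_days, seed=rng)
        donor_scores[subj.subject_id] = subj.training.all_scores()
    if sham:
        assignment = yoke_sham_scores(donor_scores, [s.subject_id for s in sham],
                                      seed=rng)
        for subj in sham:
            _donor, series = assignment[subj.subject_id]
            agent = RewardAgent()
            subj.training = run_training_course(agent, schedule,
                                                days=config.training_days,
                                                seed=rng, sham_scores=series)
    for subj in imagery:
        agent = RewardAgent(learning_rate=0.0)  # imagery only, no reward to follow
        subj.training = run_training_course(agent, schedule,
                                            days=config.training_days, seed=rng)
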