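# Methods

This note documents the models and procedures implemented in `connfeed`, the
assumptions behind them, the defaults that matter, and what the synthetic
data can and cannot show.

## The online feedback computation

Each training trial is 14 s rest, 14 s motor-imagery, then a feedback
display. At TR = 2 s the imagery period yields 7 volumes. The engine keeps
the full ROI-mean history of the session and, at scoring time:

1. applies a high-pass Butterworth filter (5th order, cutoff 0.06 Hz)
   **causally** to the history up to the first feedback-period volume —
   a real-time system cannot use future samples. An `offline` zero-phase
   mode (`sosfiltfilt`) exists for verification analyses. The filter family
   and order are implementation choices; the cutoff is the method's.
2. assembles the trial window: imagery volumes 2–7 plus the first
   feedback-period volume (7 samples). The one-volume shift is the method's
   entire treatment of hemodynamic delay — deliberately minimal so feedback
   arrives within ~4 s of imagery offset.
3. computes the Pearson correlation r_i of the two windowed ROI courses, and
   the score `(r_i − r_init)/(1 + |r_init|) × 100`, bounded in ±100. The
   baseline r_init is the arithmetic mean of raw (not Fisher-z) trial
   correlations of the day-1 initial block, during which no score is shown.

Degenerate trials (zero-variance window — possible with synthetic inputs)
raise and are skipped with a logged warning, excluded from block means, and
capped at a configurable fraction of the session. Filtering is applied to
the ROI-mean series rather than per voxel (equivalent for a linear filter up
to the ordering of voxel-noise averaging); a per-voxel path can be had by
streaming voxel data through the same engine. The reward ledger accumulates
block-mean scores floored at zero: negative scores are displayed but never
charged.

Offline replay of a logged session reuses the identical causal computation,
so recomputed scores are bit-exact — this is tested.

Sham yoking assigns each control recipient the full score series of a
distinct donor (a bijection when pools are equal-sized, never
self-assigning), reproducing the control condition in which the displayed
score carries no information about the subject's own brain.

## The virtual subject

The learner is a deliberately minimal scalar model, with no claim of
cognitive realism: a latent coupling u (the Fisher-z of the correlation its
two target ROIs express during imagery, starting at atanh(−0.3)), per-trial
Gaussian exploration ε with sd 0.1, and a REINFORCE-style update

    u ← u + η · (score − reward_baseline)/100 · ε/sd(ε),   η = 0.05,

where `reward_baseline` is the running mean of received scores. Working on
the unbounded latent scale (expressed correlation = tanh(u)) avoids hard
clipping; baseline subtraction means only reward that *covaries with the
agent's own exploration* drives systematic learning. This is what makes the
sham control behave correctly: a yoked score series, however rewarding on
average, is uncorrelated with the recipient's exploration and produces a
near-zero-mean random walk (residual drift ≈ +0.07 over a full course,
versus ≈ +0.7 for veridical feedback), matching the empirical finding that
sham feedback does not train connectivity. With exploration disabled the
update degenerates to plain clipped score-following, which is monotone under
repeated positive scores.

## The synthetic study

`simulate_study` emulates the three-group design: 12 neurofeedback, 12
sham, 9 imagery-only subjects; rest sessions before training, immediately
after, and at a 2-month follow-up; 152 volumes per rest run at TR 2 s (the
first two are discarded in analysis).

BOLD generation is a latent-signal model. Each ROI has a unit-variance
latent course drawn from a multivariate normal whose correlation matrix is
built per network-pair type: within-network r = 0.4; MVN–DMN r = −0.3
(the resting anticorrelation of the two networks); MVN–control 0.1;
DMN–control 0. Voxels inside an ROI share the latent signal plus independent
noise (sd 1.0); ROI-level runs add measurement noise equivalent to averaging
~10 voxels (sd 0.316, attenuating observed correlations by ≈ 0.91). A
shared sinusoidal drift (amplitude 0.5, period 100 s, random phase) loads on
all series *and* on the three synthetic tissue-mean confound channels, so
nuisance regression genuinely has work to do; six random-walk motion traces
complete the confound table.

Between-subject heterogeneity is a stable per-subject offset of each
network-pair coupling drawn on the Fisher-z scale (sd 0.165) — the scale on
which the group t-statistics operate, so the trait distribution stays
symmetric; per-cell session noise (sd 0.05) adds day-to-day state. The
trait sd was set so that simulated one-sample t-values for the lM1–lLP
connection fall in the empirically reported regime (pre ≈ −5, post ≈ −2
with n = 12). Session noise is independent across matrix cells; this keeps
the cells of a difference matrix exchangeable, which the bootstrap test
assumes — a correlated session state shared across a whole pair type would
invalidate its null, and real data may well violate exchangeability in just
that way (a known caveat of the cell-resampling design, not of this
implementation).

The training effect is injected directly: neurofeedback-group post and
follow-up sessions have every MVN–DMN pair's target correlation raised by
Δ = +0.2; control groups get Δ = 0. Ground truth is recorded with the study.

What the generator does **not** emulate: hemodynamic response shapes,
realistic motion/physiological artifacts, spatial autocorrelation beyond the
applied smoothing, regional signal heterogeneity, or any coupling between
training success and the injected rest-state shift. Passing tests therefore
show the *analysis machinery* is correct and calibrated under the stated
model, not that the biological effect would be detected in real data.

## Offline network analysis

Per subject and session: discard two volumes, (for voxel data) smooth with a
6-mm FWHM Gaussian, regress out the nine confounds (six motion + gray
/white/CSF means; gray-matter mean kept deliberately, mirroring the original
regressor list, despite the global-signal debate — configurable), average
residuals within ROIs, and Fisher-z the pairwise Pearson correlations with a
cap |z| ≤ atanh(1 − 1e-6) so degenerate |r| = 1 cannot produce infinities.
Post − pre differences are averaged within group.

The colored-cell rule marks cells whose increase strictly exceeds the
mean + SD of the 120 upper-triangle cells pooled across all three groups.
The bootstrap test draws, for a pair type of m cells, m cells with
replacement from the pooled 360-cell population, counts colored cells, and
repeats 3000 times; the upper bound is the 100·(1 − α/18) percentile
(Bonferroni across 6 pair types × 3 groups, α = 0.05) and a type is
significant when its observed count strictly exceeds the bound. Pooling
across groups is the default reading of the resampling population; a
per-group pool is available via `pooling="per-group"`. The reported p is
the fraction of bootstrap counts ≥ observed (add-one estimate).

One-sample "negativity" t-tests (is a connection's z significantly below
zero?) default to two-sided p-values with a ×3 Bonferroni factor for the
three nested pair sets (lM1–lLP, SMN–DMN, MVN–DMN): the stated direction of
the question is one-sided, but the reported statistics in the literature
this mirrors are two-sided, and we follow the computation; a one-sided
alternative is a parameter. Group score comparisons use a one-way ANOVA on
per-day group means with Bonferroni-corrected post-hoc two-sample t-tests.
A Welch spectral check confirms resting-state power is dominated by
frequencies below 0.05 Hz — under the 0.06-Hz online filter cutoff, so the
rest measurements are not contaminated by whatever the training filter
passed.

## Degree of connectivity

The degree of a voxel is the number of other in-mask voxels whose
correlation with it satisfies a signed threshold relation — by default
r < −0.25, counting strong *negative* connections, so a training-induced
weakening of anticorrelation shows as a degree *decrease*. Series are
standardised once and counted blockwise (default 512 voxels per block):
memory is bounded by block size and the result is independent of the
partition, which is tested against an O(V²) brute-force oracle.
Zero-variance voxels are dropped from the mask with a warning.

Pre/post change is a voxelwise paired t across subjects. Cluster-level
correction simulates smooth Gaussian null fields on the mask (at the
*nominal* applied smoothness — residual smoothness estimation is out of
scope), thresholds each standardised field at the one-sided voxel p
(default 0.005), and takes the smallest cluster size k with
P(max cluster ≥ k) ≤ 0.05. The minimum size is always derived for the
current mask and smoothness, never hard-coded; cluster connectivity defaults
to 18 (faces + edges). `threshold_sweep` re-runs the pipeline across a range
of correlation thresholds to check that detected clusters are not an
artifact of one threshold choice, and `roi_significance_ratio` reports the
percentage of significantly changed voxels per ROI.

## Problem sizes and numerical choices

Defaults are sized for a single CPU: ROI-level study generation for the
bootstrap analyses (the 33-subject study simulates and analyses in well
under a second; voxel rendering is opt-in via `render_voxels=True` and used
by the degree pipeline and its tests on reduced grids such as 10×10×6 and
12×12×8 voxels of 3×3×3.5 mm). The Monte-Carlo cluster null uses 200–1000
iterations in tests and 500 by default in the CLI. Gaussian smoothing uses
a 6σ kernel truncation so the discrete kernel matches the closed-form
Gaussian to ~1e-8. Slightly non-PSD user correlation matrices are repaired
by eigenvalue clipping within a 1e-6 tolerance (anything worse is an error);
internally generated matrices may need larger repairs after per-subject
jitter and are renormalised to unit diagonal afterwards. All randomness
flows from `numpy.random.default_rng` seeds recorded in provenance; every
entry point is bit-reproducible given its seed.

## Known limitations

- The virtual subject is a one-parameter learner; learning curves are not
  meant to fit human data quantitatively.
- The bootstrap test inherits the cell-exchangeability assumption discussed
  above; its null calibration is demonstrated under the generator, not for
  arbitrary dependence structures.
- Anatomically defined ROIs (Brodmann areas) are accepted only as
  user-supplied mask volumes; no atlas ships with the package.
- Spatial normalisation, realignment, slice-timing and other scanner-side
  preprocessing are out of scope: inputs are assumed aligned to a common
  grid.
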