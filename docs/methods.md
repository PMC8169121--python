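# Methods

This note records the models, conventions and numerical choices behind
`sniffsearch`, and what the synthetic-data tests do and do not establish
about real recordings.

## Coordinate frame and units

Arena coordinates are centimetres with the origin at the initiation-port
wall corner: the longitudinal axis runs 0 → 25 cm toward the odor ports,
the lateral axis 0 → 15 cm, and the (virtual) decision line sits at 15 cm.
Frames are 0-based at 80 Hz (12.5 ms), times are seconds on the session
clock, and intervals are half-open `[start, end)`.  Trajectories are
stored in cm; a `px_per_cm` scale (default 20) travels with each session
so pixel-based criteria — notably the 100 px/frame tracking-glitch
threshold — remain applicable.  The transition zone is the 5–10 cm
longitudinal band.

## AR-HMM

**Likelihood.**  Per trial, the joint log-likelihood sums, from the second
frame on, a transition term `log π[z_{t-1}, z_t]` and a Gaussian AR term
`log N(x_t | A_z x_{t-1} + b_z, Q_z)`.  The first frame is conditioned on,
never modelled, and the initial state distribution is uniform.

**Priors.**  Rows of π are Dirichlet with uniform mean and total
concentration α = 4, i.e. Dirichlet(α/S, …, α/S); interpreting α as a
per-cell concentration is available as a configuration switch
(`alpha_mode="per_cell"`).  Each state's `[A_z b_z]` is matrix-normal with
mean `[I 0]`, row covariance `Q_z` and identity column covariance
`I_{d+1}`; `Q_z` is inverse-Wishart with identity scale and `d + 2`
degrees of freedom.  These are loose priors: with no assigned frames a
state's conditional posterior reduces to the prior, so empty states are
always proper.

**Gibbs sweep.**  Labels are initialized iid uniform (seeded).  Each
iteration draws θ from the conjugate conditionals given the labels, then
redraws every trial's label sequence by exact forward-filter
backward-sample (scaled forward messages; numba-compiled inner loops).
The literature this model family comes from specifies Gibbs sampling but
not the state-sampling kernel; the exact blocked sampler was chosen over
single-site updates for correctness and mixing, and its exactness is
verified against exhaustive enumeration on an S=2, T=8 toy.  Defaults: 300
iterations, 200 burned, 100 retained.  Posterior marginals are label
frequencies over retained draws; MAP sequences are their per-frame argmax
(ties break toward the lower state id); expected parameters are averages
over retained draws with transition rows renormalized against rounding.

**Numerical guards.**  Inverse-Wishart draws that fail a Cholesky get a
1e-10·I jitter; forward messages are rescaled per frame, so underflow
cannot occur for proper covariances.

**Free parameters.**  `S(S−1)` transition entries plus, per state,
`d² + d + d(d+1)/2` for A, b and symmetric Q — i.e. `S(S−1) + 3Sd(d+1)/2`.

**Model selection.**  Held-out log-likelihood marginalizes states by the
forward algorithm (uniform initial distribution) on trials excluded from
fitting, at trial granularity.  Motifs occupying fewer than 5 % of
assigned frames are excluded from downstream motif analyses
(`usage_filter`); on real datasets this is how a large fitted S narrows to
the motifs actually used.

## Sniff processing

Inhalation onsets are troughs and exhalation onsets peaks of the
thermistor signal (cooling on inhale); a polarity flag covers the opposite
hardware convention.  Detection runs on a 25 ms boxcar-smoothed trace
(edges shrink the window) via peak finding with a prominence floor
(default 0.3 of the normalized waveform amplitude — the threshold is not
specified by the upstream analyses, so it is exposed as configuration) and
a minimum separation (default 50 ms), followed by a local parabolic
refinement (±4 ms) that suppresses noise-induced one-sample jitter of the
discrete argmin.

A sniff is one cycle, inhalation onset to next inhalation onset.  Cycles
with durations strictly below the 5th or strictly above the 95th
percentile (linear-interpolation quantiles; boundary ties kept) are
excluded.  Instantaneous rate at time t is 1/duration of the enclosing
kept sniff; sniff phase is elapsed time since inhalation onset divided by
cycle duration.  Within-trial sniffs run from initiation poke to
decision-line crossing; inter-trial-interval sniffs from reward-port entry
to the next initiation-port entry.

**Resolution limit.**  With the fixed 25 ms smoothing window, trough
localization acquires a deterministic ≈1 ms bias once cycles are faster
than ~8 Hz (the window becomes comparable to the inhalation half-cycle).
Sample-exact onset recovery on synthetic traces is therefore validated in
the 4–7 Hz band; durations, rates and phases are unaffected at all rates
because the constant shift cancels in onset differences.

## Kinematics and sniff synchrony

Nose speed is the frame-to-frame Euclidean displacement of the snout tip;
Z-velocity the change of snout-to-head distance (a 2-D proxy for pitch);
yaw velocity the change of the unsigned angle between the snout–head and
head–body segments, so centrifugal motion (nose swinging away from the
body axis) is positive regardless of side.  First frames and frames with
missing keypoints are NaN; gaps are never interpolated across more than
3 frames.  Tracking and motif streams are advanced two frames (25 ms)
relative to the sniff clock — the camera/thermistor offset — once,
centrally, at session assembly.

Sniff-triggered analysis extracts a 400 ms window centered on each kept
inhalation; events whose window leaves the record are dropped.  The
modulation index of the grand-mean curve is (max − min)/(max + min)
(NaN for an all-zero curve).  Cross-correlation is Pearson-normalized
(mean-removed, unit variance); coherence is Welch-averaged with 1 s
windows and 50 % overlap — the windowing is not dictated by the upstream
description, so both are configurable.

**Trial-shuffle significance.**  The null re-pairs trials' kinematics with
other trials' sniff times, taken relative to trial start and truncated to
the paired record, and recomputes the statistic; one-sided
p = (1 + #{null ≥ observed}) / (1 + n).  The default null draws uniform
random permutations of trial indices — the classical randomization test,
whose validity follows from exchangeability of the identity with the null
draws.  A derangement-only null (every trial re-paired with a different
trial) is available via `exclude_self=True`, but it is measurably
anticonservative at small trial counts (type-I ≈ 0.075 at α = 0.05 with
6 trials in 200 null simulations) because the identity is not exchangeable
with draws from the derangement set; the uniform-permutation default
measures 0.05.  The same convention applies to the motif-onset modulation
test.

## Motif-level analysis

Motif onsets are the first frame of a trial plus every frame whose MAP
label differs from the previous frame's.  Onset-triggered inhalation
PSTHs use 12.5 ms bins over a 400 ms window, normalized to rate; phase
histograms place onsets on the normalized sniff cycle (inhalation onset =
phase 0), excluding onsets outside kept sniffs, and report the mean
end-of-inhalation phase alongside.  Both per-mouse rate-normalized and raw
averages can be exported.

Two behavioral states come from clustering the rows of the retained-motif
transition matrix — raw probabilities, Euclidean metric — with Ward
agglomerative linkage cut at k = 2 by default and k-means (100 restarts)
as an alternative; tests require both to recover planted two-block
structure up to cross-block probability 0.15.  The slower cluster (by
mean nose speed) is named *investigation*, the faster *approach*; state
summaries z-score per-motif mean speed and sniff rate within mouse.

## Spatial statistics

Occupancy maps are 2-D histograms of nose position on grids that tile the
arena exactly: 50 × 30 at 0.5 cm for occupancy/sniff-rate maps, 25 × 15 at
1 cm for state-occupancy maps, anchored at the initiation-port corner.
Out-of-arena points are clipped into edge bins and counted.  Sniff-rate
maps divide per-bin sniff counts by occupancy (NaN where unvisited).
I.A.I. is (inv − app)/(inv + app) per bin, NaN where both are zero; axis
profiles project the maps (sum over the orthogonal axis, optionally
restricted to a zone) *before* taking the ratio.  Gaussian smoothing
(σ = 1 bin) is display-only and recorded in the map object; statistics run
on unsmoothed grids.  Choice reorientation flips the lateral axis of
right-choice trials (y → width − y).

Correct/incorrect comparisons scramble outcome labels within mice
(1000 times by default) before re-taking grand means, so the null carries
both within- and across-mouse variability; p-values are pointwise
two-sided exceedance, with a max-statistic family-wise option.

## Decoding

Single-trial features are flattened empirical transition matrices of the
MAP sequence; rows with no outgoing transitions are imputed uniform and
flagged, keeping the feature dimension fixed.  The decoder is LDA with
pooled-covariance shrinkage (`lsqr` solver, `shrinkage="auto"`), since S²
features can exceed trial counts, under stratified 5-fold cross-validation
(shuffled, seeded).  Significance shuffles the *training* labels 100 times
per fold, scores the unshuffled test set, z-scores the real per-class
accuracy against the shuffle distribution, and averages z across folds;
the overall p applies the standard-normal tail to the fold-averaged z
scaled by √(#folds) (the null standard error of a mean of fold-wise
z-scores).  A zero-variance null falls back to count exceedance.

## Plume maps

2 s PID traces from a 7 × 5 sampling grid are reduced to 25 ms chunk means
(about one inhalation of odor sampling; the PID sample rate is a free
parameter, default 1 kHz).  Absolute-concentration discriminability runs
ROC analysis per location between left-trial and right-trial chunk-mean
distributions and reports |2·AUC − 1|.  Gradient discriminability
assembles pseudosamples — the j-th chunk mean from every location paired
in order (random pairing available) — takes the spatial gradient by
central differences (one-sided at edges), and applies the same ROC to the
per-bin angle distributions, linearized by default as the sine of the
deviation from the longitudinal axis (exactly the component that separates
mirrored plumes; raw-angle mode available).  Maps can be quantized to
eight equal-width grayscale levels for display (idempotent); no display
threshold is applied by default.

## Synthetic data: what it emulates, what it does not

The generators define the study conditions the tests run under:

- **AR-HMM ground truth** — stable rotation-plus-drift dynamics with
  state-specific fixed points (`separation` = 3, spectral radius 0.9,
  persistence 0.9, noise 8 % of separation): well-separated motifs, the
  regime where label recovery is meaningful.
- **Thermistor traces** — one −cos cycle per sniff under a monotone
  quintic phase warp with unit slope and zero curvature at the extrema, so
  the trough/peak neighborhoods are locally symmetric (boxcar smoothing
  then cannot bias their location) while inhalation (40 % of the cycle)
  and exhalation differ in duration.  Durations are log-normally jittered
  (σ = 3 %), event times live on the sample grid, sensor noise is white
  (σ = 0.01 of amplitude), and a configurable fraction of cycles gets
  extreme durations (×0.25 or ×3) as known targets for the percentile
  filter.
- **Sniff-locked kinematics** — baseline × (1 + depth·cos 2π·phase) plus
  white noise, so the triggered-mean MI equals the planted depth.
- **Sessions** — alternating investigation bouts (slow
  Ornstein–Uhlenbeck wandering around anchors near the port or at
  approach-abort points, ~3 cm/s, 9 Hz sniffing) and approach bouts
  (heading-persistent runs at the chosen port, ~18 cm/s, 5 Hz sniffing);
  choices follow a logistic read-out of the left–right concentration
  ratio (gain 6), so correct and incorrect trials are both populated
  (~75–85 % correct); a `correct_midline_bias` knob concentrates
  investigation anchors at the lateral midline on correct trials to plant
  a detectable outcome effect.  Trial counts default to 40 per session;
  tests use 10–50.
- **Plume grids** — exponential decay from the active port (length scale
  8 cm, mirrored across the midline) plus AR(1) "turbulence"
  (coefficient 0.95, σ = 0.05), ~15 two-second trials per location/side.

None of this reproduces the heavy tails of real tracking error, real
turbulent intermittency, postural artifacts of the thermistor, or
behavioral non-stationarity across a session.  Passing tests therefore
establish that the estimators are *correct and calibrated* — they recover
planted structure and hold their nominal error rates — not that any
specific biological effect size will be observed in real recordings.

## Problem sizes in the test-suite

Validation runs use deliberately modest sizes chosen to exercise each
property at useful statistical resolution: the Gibbs-exactness toy (T = 8,
5000 draws), parameter recovery at 50 trials × 200 frames with the full
300-iteration schedule, model selection on 10 replicates of 20 × 100
frames with a shortened 60/40 schedule (the preference for the true state
count is insensitive to the schedule), shuffle-test calibration on 200
small simulations with 1000 permutations each, and a 10-trial end-to-end
demo session.
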