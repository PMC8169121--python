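# sniffsearch

Analysis toolkit for **sniff-synchronized olfactory search behavior** in
freely moving mice.  In a two-choice odor-localization task a mouse samples
a turbulent odor landscape while running between an initiation port and two
odor/reward ports in a 15 × 25 cm arena.  The package turns the raw
measurements of such an experiment — three-point pose tracks (nose, head,
center of mass at 80 Hz), intranasal-thermistor sniff signals, trial
metadata, and gridded photoionization-detector (PID) plume recordings —
into the quantities that describe the search strategy:

- **Movement motifs** from a Bayesian auto-regressive hidden Markov model
  (AR-HMM) fit to the 6-D keypoint trajectory,
- **Sniff events** (inhalation/exhalation times, rates, phases) and the
  synchrony of nose/head kinematics with the sniff cycle,
- **Investigation vs. approach states** from clustering the motif
  transition matrix, with allocentric occupancy and index maps,
- **Decoding** of trial labels from single-trial motif transition
  statistics, and
- **Plume discriminability maps** (ROC analysis of concentration and
  gradient-direction distributions).

Every input the pipeline consumes can be generated synthetically with known
ground truth (`sniffsearch.synthetic`), so the whole analysis is testable
end to end without animal data.

## The model at the core

The trajectory `x_t` (the 6-vector of nose/head/body coordinates) follows
switching linear dynamics governed by a discrete motif sequence `z_t ∈
{1,…,S}`:

    z_t | z_{t-1}  ~  Categorical(π_{z_{t-1}, ·})
    x_t | x_{t-1}, z_t  =  A_{z_t} x_{t-1} + b_{z_t} + ε_t,   ε_t ~ N(0, Q_{z_t})

with the first frame of each trial conditioned on and a uniform initial
state distribution.  Inference is fully Bayesian with conjugate priors —
Dirichlet(α/S, …, α/S) rows for π (α = 4) and matrix-normal-inverse-Wishart
priors on (A_z, b_z, Q_z) with identity inverse-Wishart scale, d + 2
degrees of freedom, prior mean [I, 0] and identity column covariance — and
runs by Gibbs sampling: exact forward-filter backward-sample draws of each
trial's state sequence alternate with closed-form conjugate draws of θ =
(π, {A_z}, {b_z}, {Q_z}).  The default schedule runs 300 iterations, burns
200 and retains 100 draws; per-frame posterior marginals are state
frequencies over retained draws, the MAP sequence their argmax, and the
"fit model" the posterior-mean parameters.

Downstream statistics follow the conventions of the field: modulation
index MI = (max − min)/(max + min) of an event-aligned mean curve;
investigation–approach index I.A.I. = (inv − app)/(inv + app) per spatial
bin; single-trial transition features π̂_ab = n_ab / Σ_c n_ac decoded by
linear discriminant analysis under stratified 5-fold cross-validation with
100-shuffle significance; plume discriminability as |2·AUC − 1| per grid
location.

## Worked example

Fit an AR-HMM to trajectories simulated from a known 3-state model, and
recover planted sniff events from a synthetic thermistor trace:

```python
import numpy as np
from sniffsearch.synthetic import gen_arhmm_params, simulate_trials, gen_sniff_trace
from sniffsearch.arhmm import gibbs_fit, GibbsConfig, match_states
from sniffsearch.sniff import smooth_trace, detect_sniffs, filter_sniff_durations

truth = gen_arhmm_params(S=3, d=2, seed=0)
trajs, labels = simulate_trials(truth, n_trials=20, length_range=(150, 150), seed=1)
fit = gibbs_fit(trajs, S=3, cfg=GibbsConfig(n_iter=120, n_burn=80, seed=2))
perm = match_states(labels, fit.map_sequences, 3)
acc = np.mean(np.concatenate(
    [perm[np.asarray(e)] == t for e, t in zip(fit.map_sequences, labels)]))
print(f"MAP frame accuracy vs ground truth: {acc:.3f}")
inv = np.argsort(perm)
print("fitted transition matrix (aligned):")
print(np.round(fit.expected_params.pi[np.ix_(inv, inv)], 3))

trace, planted = gen_sniff_trace(rate_profile=6.0, duration=20.0, seed=3)
events = filter_sniff_durations(detect_sniffs(smooth_trace(trace)))
d = np.abs(events.inhalation_onsets[:, None]
           - planted.inhalation_onsets[None, :]).min(axis=0)
print(f"sniffs detected: {events.n_sniffs}, "
      f"kept after 5th-95th pct filter: {events.kept_mask.sum()}")
print(f"onsets within one sample of planted truth: {np.mean(d <= 1.5e-3) * 100:.1f}%")
```

Output:

```
MAP frame accuracy vs ground truth: 0.995
fitted transition matrix (aligned):
[[0.887 0.07  0.043]
 [0.057 0.893 0.051]
 [0.046 0.055 0.899]]
sniffs detected: 119, kept after 5th-95th pct filter: 107
onsets within one sample of planted truth: 100.0%
```

99.5 % of frames receive the generating motif label (after Hungarian
alignment of the arbitrary state order), the fitted transition matrix
matches the generator's 0.9-persistence rows to ~0.01, and every planted
inhalation onset is recovered to within one sample; the percentile filter
excludes the 10 % of cycles in the duration-distribution tails.

## Command line

`sniffsearch run --config configs/demo.yaml --out artifacts/` executes the
full chain (simulate → sniff → kinematics → fit → states → spatial →
decode → plume) and writes per-stage artifacts plus a provenance manifest;
re-running with the same config and seed reproduces every file bit for
bit.  Individual stage subcommands (`sniffsearch fit ...`, etc.) run the
chain up to that stage.  Exit codes: 0 success, 2 config error, 3 data
error.

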