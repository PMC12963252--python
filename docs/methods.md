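# Methods

`neurostate` implements a pre-decoder gate for intracortical brain-computer
interfaces: every millisecond of multi-unit activity is classified as
*stationary* or *movement*, so that a downstream movement decoder can be
driven only during intended movement. This note documents the models, the
numerical choices, and what the synthetic benchmark does and does not show.

## Signal model and preprocessing

Spike trains are binned on a 1 kHz grid and convolved with a discrete
Gaussian kernel (SD 3 ms, zero mean, truncated at ±5 SD and renormalized).
The kernel is normalized to **unit sum** on the grid, so each spike
contributes exactly one spike of integrated rate and the rate matrix is in
spikes/ms. Unit-sum normalization is also what makes the labeling cutoff
(below) numerically interpretable: an isolated change point smoothed with an
SD-10 ms kernel peaks at 1/(10·√(2π)) ≈ 0.0399, two coincident change points
at ≈ 0.0798, and a dense train of change points at ≈ the change-point rate
per ms.

Cursor velocity is the central finite difference of position scaled to
device units per second (one-sided at the endpoints); files that already
carry velocities are passed through unchanged.

## Reference labels

Ground truth is behavioral: movement is the interval from cursor-motion
onset to target acquisition. Labels are generated from cursor position only:

1. A sliding two-window mean-difference detector (window 10 ms per side,
   default) marks every sample where |mean(next window) − mean(previous
   window)| exceeds 6× the noise SD of that statistic. The noise level is a
   robust estimate (MAD of first differences), so on noiseless traces any
   sustained change is marked. Sustained cursor motion therefore produces a
   dense train of marks, isolated artifacts a single mark.
2. The x- and y-axis impulse vectors are **added** (a simultaneous change on
   both axes counts twice — it is stronger evidence of movement than a
   change on one axis).
3. The summed impulses are smoothed with a unit-sum Gaussian (SD 10 ms) and
   thresholded at the cutoff (0.05); ties label movement.

With these defaults an isolated single-axis impulse (peak 0.0399) never
labels movement, while sustained motion (marks at ≥ 1 per 20 ms) does. The
labeled boundary leads/lags the true kinematic boundary by at most roughly
(window − 1) + 16.4 ms — the 16.4 ms being the distance at which a unit-rate
smoothed edge decays to 0.05 — which motivates the 10 ms default window
(≈ ±26 ms worst case, inside ±3 kernel SDs). All labeling parameters accept
per-trial overrides; hand-curated labels can be supplied via `labels.csv`
instead.

## cPCA: correlation-informed component selection

PCA is fit (mean-centered, full SVD) on the pooled time samples of the
training trials. Each component's projection is correlated with the binary
labels (product-moment r; identical to the point-biserial coefficient for
0/1 coding) and components with |r| ≥ 0.2 are retained, preserving PC
order. The retention rule is non-strict at the boundary; 0.2 is the
conventional floor below which a correlation is considered weak. If no
component qualifies, the error names the largest |r| observed rather than
silently returning an empty model.

Two supporting analyses characterize the selection: a per-trial survey
(PCA fit to each trial independently; |r| pooled across trials; the summary
median is computed after discarding |r| < 0.1 as noise) and an OLS
regression of per-channel mean |loading| on per-channel mean |rate
difference| between states, reported as slope, Θ = atan(slope) in degrees,
and R². Mean loadings are means of absolute values per channel — signs of
PC loadings are arbitrary, so averaging signed loadings across components
would cancel structure.

## Classifier

The selected projections are z-scored (moments from training data only) and
fed to a linear soft-margin SVM: hinge loss, box constraint C = 1, no class
weighting. The contract is the optimum of

    0.5·(‖w‖² + (b/s)²) + C·Σ max(0, 1 − yᵢ(w·zᵢ + b)),   s = 10,

i.e. the standard augmented-constant-feature formulation in which the
intercept carries a light penalty b²/200 — numerically negligible for the
standardized features used here. The exposed tolerance `eps` (default 1e-3)
bounds the objective suboptimality; the dual coordinate-descent backend is
run an order of magnitude tighter. A decision value of exactly zero is
classified movement, consistent with the ≥ conventions elsewhere. The
solver is seeded, so refitting on identical data is bit-reproducible.

Evaluation uses k-fold cross-validation (default k = 10) partitioned **at
the trial level**: trials are shuffled once with the given seed and split
into folds balanced to within one trial. PCA, selection, standardization
and the SVM are all fit per fold on the training trials only. Fold metrics
pool all samples of the fold's test trials; per-trial predictions are also
retained so per-trial summaries remain available.

## Threshold-crossing baseline

The comparison method needs no training: a sample is movement when |vx| ≥
threshold_x **or** |vy| ≥ threshold_y (thresholds default 25 units/s); the
boundary case is movement, matching the output gate that zeroes decoder
outputs below threshold. Velocities are compared by absolute value — the
thresholds are positive speed limits, and signed comparison would
misclassify leftward or downward movement. Thresholds are calibrated by an
exhaustive integer sweep (10–40, both axes independently) maximizing mean
per-trial accuracy; ties resolve to the smallest thresholds, x before y.

## Evaluation battery

- Confusion metrics (accuracy, sensitivity, specificity, precision,
  F-score) are computed per declared positive class; zero-denominator
  metrics are flagged undefined and excluded from means with a count, never
  silently zeroed. Swapping the positive class exchanges sensitivity and
  specificity.
- A transition is any label change; transition counts measure output
  continuity (each spurious flicker adds two).
- Responsiveness: each reference transition is matched with the nearest
  same-direction decoded transition (ties resolve to the earlier
  candidate); reactivity = decoded − reference time (negative means the
  decoder led behavior), sensitivity = |reactivity|. When a reference
  carries more than the nominal two transitions, the per-trial summary uses
  the first start and the last end. The nearest-match rule is a design
  choice — the alternative "first decoded transition after the reference"
  is biased positive for high-flicker outputs — and the pooled
  (all-transition) results are also emitted.
- State rate comparisons pair mean rates per (channel, trial, state); the
  paired comparison delegates to the Wilcoxon signed-rank test (normality
  screened with Shapiro–Wilk, subsampled deterministically above its n=5000
  domain); Cohen's d and the pairing logic are computed in-package
  (paired d = mean(diff)/SD(diff), one-sample d = mean/SD, df = n − 1).

## Synthetic sessions

The simulator emulates a delayed center-out task: central hold (≥ 700 ms),
uniform 0–1 s preparatory delay ending at the go cue, a minimum-jerk reach
(600 ms, amplitude 120 units — peak speed 375 units/s, so the default
velocity threshold of 25 is crossed ≈ 40 ms into a noiseless reach) to one
of nine equally spaced targets, and a 500 ms target hold. Truth labels
equal the kinematic movement interval exactly, giving exactly two
transitions per trial.

Channels fire as inhomogeneous Poisson processes (thinning sampler).
Baseline rates are drawn per channel from a lognormal with median 80 Hz
(σ = 0.4), typical of unsorted multi-unit threshold crossings in motor
cortex; half the channels (default) multiply their baseline by the movement
gain (default 2.0) during movement. The modulation begins a configurable
neural lead (default 50 ms) before kinematic onset and ends at kinematic
offset, with 20 ms linear ramps — an instantaneous step would make the
classification problem unrealistically easy. Trial-to-trial multiplicative
rate jitter (CV 0.1) and optional sub-threshold preparatory modulation are
available. All randomness derives from one session seed through a
`SeedSequence`; each trial consumes one spawned child, so sessions are
byte-reproducible.

For stress-testing the velocity baseline, white Gaussian jitter (default SD
= threshold/2) is added to the velocity traces, standing in for decoder
output noise. With that noise the threshold rule flickers on the order of a
hundred times per trial while the neural classifier's transition count
stays near the reference, and the threshold rule's movement-start onset is
at/after the reference while the neural classifier's precedes it by roughly
the programmed lead — the qualitative contrast the package is built to
measure.

**What the simulator does not capture:** latent cortical dynamics and
cross-channel noise correlations (channels are conditionally independent
Poisson), realistic heterogeneous tuning (all modulated channels share one
gain), behavioral variability in reach kinematics (every reach is an ideal
minimum-jerk trajectory), and non-stationarity across a session. Passing
the synthetic battery therefore demonstrates correctness of the pipeline's
mechanics and its qualitative contrasts, not performance on real
recordings.

## Problem sizes and numerical choices

The benchmark battery uses 100-trial sessions: 64 channels with gain 2.0 on
half the channels for the accuracy benchmark, and the full 192-channel
default for the transition/responsiveness contrasts; the chance-level
control uses 50 unmodulated trials. The control is run with benchmark 0
(all components retained): with no state modulation, no component can pass
the correlation criterion, and the selection stage correctly refuses to
return an empty model — the control instead verifies that the rest of the
pipeline cannot manufacture accuracy above the majority-class share.

Other conventions: kernels truncate at ±5 SD and renormalize; smoothing at
array edges loses the out-of-range kernel mass (rate conservation holds for
kernels fully inside the window); CSV output uses shortest-round-trip float
formatting and reads with round-trip parsing, so write→read is bit-exact;
NWB times (seconds) are converted to ms on load.

## Known limitations

- The change detector is a two-window mean-difference scan, not a
  replication of any proprietary routine; with per-trial manual curation
  out of scope, generated labels are not claimed to match hand-tuned ones.
- The velocity units of real sessions (and hence the physical meaning of
  threshold 25) must be established by the user; the sweep exists for that
  calibration.
- Per-sample classification carries no temporal prior; a hidden-state
  smoother would trade reactivity for continuity and is deliberately out of
  scope.
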