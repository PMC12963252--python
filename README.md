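# neurostate

Pre-decoder classification of **stationary vs. movement neural states** for
intracortical brain-computer interfaces (BCIs).

Movement decoders work well while the user intends to move, but cortical
activity never stops: during intended stillness (idle periods, and
especially preparatory activity before a go cue) the decoder keeps emitting
spurious commands. `neurostate` implements a gating classifier — **cpSVM**
(correlation-PCA SVM) — that labels every millisecond of multi-unit
activity as stationary (0) or movement (1) so the decoder can be enabled
only during intended movement. It is written for BCI/motor-systems
researchers working with center-out cursor tasks sampled at 1 kHz.

## The model

Given per-channel firing rates `X(t) ∈ R^C` (Gaussian-smoothed spike
counts, SD 3 ms) and behavioral reference labels `y(t) ∈ {0, 1}`:

1. **PCA** — fit mean-centered PCA on the pooled training samples.
2. **Correlation selection (cPCA)** — keep the components whose projections
   satisfy `|r(PCᵢ, y)| ≥ 0.2`; PCA alone cannot say which components carry
   task information, the label correlation can.
3. **Linear SVM** — z-score the selected projections and fit a linear
   soft-margin SVM (hinge loss, `C = 1`, no class weighting). Decision
   rule: `movement ⇔ w·z + b ≥ 0`.

Reference labels come from cursor kinematics alone: change points detected
on the x/y position traces, smoothed with a Gaussian (SD 10 ms) and
thresholded at a cutoff (0.05). The comparison baseline is the classical
**threshold-crossing (TC)** rule — movement whenever `|vx| ≥ θx` or
`|vy| ≥ θy` — the same gate used to zero decoder outputs below a speed
threshold. Evaluation covers confusion metrics, transition counts (output
continuity) and responsiveness (signed onset timing of decoded vs.
reference transitions), with trial-level 10-fold cross-validation.

A full synthetic center-out session generator (inhomogeneous-Poisson
spiking, minimum-jerk reaches, configurable neural lead before kinematic
onset) makes every stage runnable and testable without any recordings.

## Worked example

```python
import numpy as np
import neurostate as ns

# simulate a 20-trial, 192-channel center-out session; neural modulation
# leads kinematic movement onset by 50 ms
cfg = ns.SessionConfig(n_trials=20, n_channels=192)
tune = ns.NeuralTuningParams(neural_lead_ms=50.0)
trials = ns.simulate_session(cfg, tune, seed=42)

data = [(ns.estimate_firing_rates(t.spikes), t.truth) for t in trials]
cv = ns.run_trialwise_cv(data, k=5, seed=42)
print(f"cpSVM 5-fold mean accuracy: {cv.mean_accuracy:.3f}")

sel = cv.models[0].selection
print(f"components retained in fold 1: {sel.selected} "
      f"(|r| = {np.round(np.abs(sel.r[sel.selected]), 3).tolist()})")

from neurostate.evaluate import count_transitions, summarize_trial_responsiveness
starts = [summarize_trial_responsiveness(p, t.truth)["start_ms"]
          for p, t in zip(cv.predictions, trials)]
print(f"median movement-start reactivity: {np.median(starts):+.1f} ms")
```

Output:

```
cpSVM 5-fold mean accuracy: 0.978
components retained in fold 1: [0] (|r| = [0.914])
median movement-start reactivity: -39.5 ms
```

Reading the numbers: out of 192 principal components a single one carries
the state signal (its projection correlates with the labels at |r| = 0.91;
everything else is discarded by the 0.2 benchmark), and per-millisecond
state decoding is 97.8% correct on held-out trials. The *negative*
reactivity says the decoded movement onset precedes the behavioral one —
the classifier reads the neural lead programmed into the simulation, which
is exactly the predictive behavior wanted from a gate. Running the TC
baseline on the same session with noisy velocity
(`ns.tc_classify(...)` after `ns.jitter_velocity(..., 12.5, rng)`) prints
`accuracy 0.900, transitions/trial 295.2` against 2.30 for the cpSVM and
2.00 for the reference — the velocity threshold flickers two orders of
magnitude more than the neural gate.

## Command line

```sh
neurostate simulate --trials 100 --channels 192 --lead 50 --seed 7 --out data/
neurostate label    --in data/ --sd 10 --cutoff 0.05 --out labels.csv
neurostate cv       --in data/ --k 10 --benchmark 0.2 --seed 42 --out cv.json
neurostate tc-sweep --in data/ --range 10:40 --out sweep.json
neurostate run      --in data/ --out report/        # full pipeline
```

Sessions are read either from the CSV dialect written by `simulate`
(spikes.csv / kinematics.csv / events.csv / labels.csv) or from NWB-layout
HDF5 files (units table, cursor position series, trial intervals).

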