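"""Synthetic center-out sessions: spikes, cursor kinematics, ground truth.

Each simulated trial follows the delayed center-out structure: a central hold
(>= 700 ms), a variable preparatory delay (uniform 0-1 s) ending at the go
cue, a minimum-jerk reach to one of nine equally spaced targets, and a
target hold. Multi-unit channels fire as inhomogeneous Poisson processes; a
configurable fraction of channels multiplies its baseline rate during
movement, with the rate modulation beginning a configurable neural lead
(tens of ms) BEFORE kinematic onset, emulating the lag between cortical
activity and behavior. Ground-truth state labels equal the kinematic
movement interval exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InputError, ParameterError
from .preprocess import KinematicsTrace, SpikeTrainSet, StateLabels

__all__ = [
    "SessionConfig",
    "NeuralTuningParams",
    "SimulatedTrial",
    "minimum_jerk_reach",
    "sample_inhomogeneous_poisson",
    "simulate_session",
    "jitter_velocity",
]


@dataclass
class SessionConfig:
    """Trial-structure parameters (durations in ms, amplitudes in device units)."""

    n_trials: int = 100
    n_channels: int = 192
    sample_rate: float = 1000.0
    hold_ms: float = 700.0
    delay_range_ms: tuple[float, float] = (0.0, 1000.0)
    n_targets: int = 9
    reach_duration_ms: float = 600.0
    target_hold_ms: float = 500.0
    reach_amplitude: float = 120.0

    def __post_init__(self):
        if self.n_trials < 1 or self.n_channels < 1 or self.n_targets < 1:
            raise ParameterError("counts must be >= 1")
        if self.hold_ms < 700.0:
            raise ParameterError("central hold must be at least 700 ms")
        if min(self.reach_duration_ms, self.target_hold_ms, self.sample_rate) <= 0:
            raise ParameterError("durations and sample rate must be positive")
        lo, hi = self.delay_range_ms
        if lo < 0 or hi < lo:
            raise ParameterError("invalid delay range")


@dataclass
class NeuralTuningParams:
    """State-dependent firing-rate model.

    ``baseline_rate_hz`` may be a per-channel array; when None, baselines are
    drawn per channel from a lognormal with median 80 Hz (sigma 0.4), typical
    of unsorted multi-unit threshold crossings in motor cortex. Modulated
    channels multiply their baseline by ``movement_gain`` during movement,
    ramping over ``ramp_ms`` and leading kinematic onset by
    ``neural_lead_ms``. ``rate_noise_cv`` is multiplicative trial-to-trial
    rate jitter; ``prep_gain`` adds optional sub-threshold modulation during
    the preparatory delay (1.0 = off).
    """

    baseline_rate_hz: np.ndarray | None = None
    movement_gain: float = 2.0
    modulated_fraction: float = 0.5
    neural_lead_ms: float = 50.0
    rate_noise_cv: float = 0.1
    ramp_ms: float = 20.0
    prep_gain: float = 1.0

    def __post_init__(self):
        if self.neural_lead_ms < 0:
            raise ParameterError("neural_lead_ms must be >= 0")
        if not 0.0 <= self.modulated_fraction <= 1.0:
            raise ParameterError("modulated_fraction must lie in [0, 1]")
        if self.movement_gain < 0 or self.prep_gain < 0:
            raise ParameterError("gains must be non-negative")
        if self.baseline_rate_hz is not None:
            b = np.asarray(self.baseline_rate_hz, dtype=float)
            if np.any(b < 0):
                raise ParameterError("baseline rates must be non-negative")
            self.baseline_rate_hz = b


@dataclass
class SimulatedTrial:
    spikes: SpikeTrainSet
    kin: KinematicsTrace
    truth: StateLabels
    target_direction: int
    seed: int
    movement_onset_ms: float = 0.0
    movement_offset_ms: float = 0.0


def minimum_jerk_reach(
    start: np.ndarray, target: np.ndarray, duration_ms: float,
    sample_rate: float = 1000.0,
) -> np.ndarray:
    """Minimum-jerk 2-D trajectory sampled on the grid, zero endpoint velocity.

    Position follows start + (target-start) * (10 tau^3 - 15 tau^4 + 6 tau^5)
    with tau = t/duration; the profile is time-symmetric about its midpoint.
    """
    if duration_ms <= 0:
        raise ParameterError("duration must be positive")
    start = np.asarray(start, dtype=float)
    target = np.asarray(target, dtype=float)
    n = int(round(duration_ms * sample_rate / 1000.0))
    tau = np.arange(n) / max(n - 1, 1)
    s = 10 * tau**3 - 15 * tau**4 + 6 * tau**5
    return start[None, :] + (target - start)[None, :] * s[:, None]


def sample_inhomogeneous_poisson(
    rate_hz: np.ndarray, rng: np.random.Generator, sample_rate: float = 1000.0
) -> np.ndarray:
    """Thinning-based sampling of an inhomogeneous Poisson spike train.

    ``rate_hz`` is the intensity (spikes/s) at each grid sample. Candidate
    events are drawn homogeneously at the peak rate and accepted with
    probability rate(t)/peak. Deterministic given the generator state.
    """
    rate = np.asarray(rate_hz, dtype=float)
    if np.any(rate < 0):
        raise InputError("rates must be non-negative")
    lam_max = rate.max() if rate.size else 0.0
    duration_s = rate.shape[0] / sample_rate
    if lam_max == 0 or duration_s == 0:
        return np.array([])
    n_cand = rng.poisson(lam_max * duration_s)
    t_s = np.sort(rng.uniform(0.0, duration_s, size=n_cand))
    idx = np.minimum((t_s * sample_rate).astype(int), rate.shape[0] - 1)
    keep = rng.uniform(0.0, 1.0, size=n_cand) < rate[idx] / lam_max
    return t_s[keep] * 1000.0  # ms


def _modulation_profile(n: int, on: int, off: int, lead: int, ramp: int) -> np.ndarray:
    """0..1 profile: ramps up starting lead ms before `on`, down ending at `off`."""
    m = np.zeros(n)
    rise0 = max(on - lead, 0)
    rise1 = min(rise0 + ramp, n)
    fall1 = min(off, n)
    fall0 = max(fall1 - ramp, rise1)
    if rise1 > rise0:
        m[rise0:rise1] = np.linspace(0.0, 1.0, rise1 - rise0, endpoint=False)
    m[rise1:fall0] = 1.0
    if fall1 > fall0:
        m[fall0:fall1] = np.linspace(1.0, 0.0, fall1 - fall0, endpoint=False)
    return m


def simulate_session(
    cfg: SessionConfig | None = None,
    tune: NeuralTuningParams | None = None,
    seed: int = 0,
) -> list[SimulatedTrial]:
    """Generate a full center-out session.

    All randomness flows from ``seed`` through a SeedSequence: session-level
    draws (baselines, modulated channel set) use the root, and each trial
    uses one spawned child, so trials are reproducible independently of each
    other.
    """
    cfg = cfg or SessionConfig()
    tune = tune or NeuralTuningParams()
    root = np.random.SeedSequence(seed)
    session_rng = np.random.default_rng(root)
    trial_seeds = root.spawn(cfg.n_trials)

    if tune.baseline_rate_hz is None:
        baselines = 80.0 * np.exp(session_rng.normal(0.0, 0.4, cfg.n_channels))
    else:
        baselines = np.broadcast_to(tune.baseline_rate_hz, (cfg.n_channels,)).copy()
    n_mod = int(round(tune.modulated_fraction * cfg.n_channels))
    modulated = np.zeros(cfg.n_channels, dtype=bool)
    modulated[session_rng.permutation(cfg.n_channels)[:n_mod]] = True

    fs = cfg.sample_rate
    ramp = int(round(tune.ramp_ms))
    lead = int(round(tune.neural_lead_ms))
    trials: list[SimulatedTrial] = []
    for t_idx, child in enumerate(trial_seeds):
        rng = np.random.default_rng(child)
        delay = rng.uniform(*cfg.delay_range_ms)
        hold_n = int(round(cfg.hold_ms * fs / 1000.0))
        delay_n = int(round(delay * fs / 1000.0))
        reach_n = int(round(cfg.reach_duration_ms * fs / 1000.0))
        tgt_n = int(round(cfg.target_hold_ms * fs / 1000.0))
        n = hold_n + delay_n + reach_n + tgt_n
        on, off = hold_n + delay_n, hold_n + delay_n + reach_n

        direction = int(rng.integers(cfg.n_targets))
        angle = 2.0 * np.pi * direction / cfg.n_targets
        target = cfg.reach_amplitude * np.array([np.cos(angle), np.sin(angle)])
        pos = np.zeros((n, 2))
        pos[on:off] = minimum_jerk_reach(np.zeros(2), target, cfg.reach_duration_ms, fs)
        pos[off:] = target

        truth = np.zeros(n, dtype=np.int8)
        truth[on:off] = 1

        mod = _modulation_profile(n, on, off, lead, ramp)
        prep = np.zeros(n)
        if tune.prep_gain != 1.0 and delay_n > 0:
            prep[hold_n:on] = 1.0
        jitter = np.clip(rng.normal(1.0, tune.rate_noise_cv, cfg.n_channels), 0.1, None)
        channel_spikes = []
        for c in range(cfg.n_channels):
            rate = np.full(n, baselines[c] * jitter[c])
            if modulated[c]:
                rate = rate * (1.0 + (tune.movement_gain - 1.0) * mod)
                rate = rate * (1.0 + (tune.prep_gain - 1.0) * prep)
            channel_spikes.append(sample_inhomogeneous_poisson(rate, rng, fs))
        time_grid = np.arange(n) * (1000.0 / fs)
        trials.append(
            SimulatedTrial(
                spikes=SpikeTrainSet(channel_spikes, duration_ms=n * 1000.0 / fs,
                                     sample_rate=fs),
                kin=KinematicsTrace(time_grid=time_grid, x=pos[:, 0], y=pos[:, 1],
                                    go_cue_ms=float(on * 1000.0 / fs)),
                truth=StateLabels(labels=truth, time_grid=time_grid),
                target_direction=direction,
                seed=int(child.generate_state(1)[0] & 0x7FFFFFFF),
                movement_onset_ms=float(on * 1000.0 / fs),
                movement_offset_ms=float(off * 1000.0 / fs),
            )
        )
    return trials


def jitter_velocity(
    v: np.ndarray, sd: float, rng: np.random.Generator
) -> np.ndarray:
    """Additive white Gaussian velocity jitter (TC stress-test noise model)."""
    if sd < 0:
        raise ParameterError("jitter SD must be >= 0")
    v = np.asarray(v, dtype=float)
    return v + rng.normal(0.0, sd, v.shape)
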