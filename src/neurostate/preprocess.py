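"""Spike-rate estimation, cursor velocities, and behavioral reference labels.

Everything in this module lives on a shared 1 kHz time grid: spike trains are
binned to 1 ms and convolved with a unit-sum Gaussian kernel to give
instantaneous firing rates (spikes/ms); cursor position traces are scanned for
abrupt changes, and the resulting change-point impulses are smoothed and
thresholded to produce the binary stationary(0)/movement(1) reference labels
that supervise the state classifier.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InputError, ParameterError

__all__ = [
    "SpikeTrainSet",
    "RateMatrix",
    "KinematicsTrace",
    "LabelingParams",
    "StateLabels",
    "gaussian_kernel",
    "estimate_firing_rates",
    "detect_change_points",
    "labels_from_impulses",
    "generate_reference_labels",
    "compute_velocity",
]


@dataclass
class SpikeTrainSet:
    """Per-channel spike times for one trial or session.

    Parameters
    ----------
    channel_spikes:
        One array of spike times (ms, ascending) per channel.
    duration_ms:
        Length of the recording window; all spike times lie in
        ``[0, duration_ms]``.
    sample_rate:
        Sampling rate of the analysis grid in Hz (default 1000).
    """

    channel_spikes: list[np.ndarray]
    duration_ms: float
    sample_rate: float = 1000.0

    def __post_init__(self):
        if len(self.channel_spikes) < 1:
            raise InputError("SpikeTrainSet requires at least one channel")
        if self.duration_ms <= 0:
            raise ParameterError("duration_ms must be positive")
        clean = []
        for c, ts in enumerate(self.channel_spikes):
            ts = np.asarray(ts, dtype=float)
            if ts.ndim != 1:
                raise InputError(f"channel {c}: spike times must be 1-D")
            if ts.size and np.any(np.diff(ts) < 0):
                raise InputError(f"channel {c}: spike times must be ascending")
            if ts.size and (ts[0] < 0 or ts[-1] > self.duration_ms):
                raise InputError(
                    f"channel {c}: spike times outside [0, {self.duration_ms}]"
                )
            clean.append(ts)
        self.channel_spikes = clean

    @property
    def n_channels(self) -> int:
        return len(self.channel_spikes)


@dataclass
class RateMatrix:
    """Instantaneous firing rates (spikes/ms) on the 1 kHz grid.

    ``values`` is time-sample x channel; ``time_grid`` gives the sample times
    in ms.
    """

    values: np.ndarray
    time_grid: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.time_grid = np.asarray(self.time_grid, dtype=float)
        if self.values.ndim != 2:
            raise InputError("RateMatrix.values must be 2-D (time x channel)")
        if self.values.shape[0] != self.time_grid.shape[0]:
            raise InputError("time grid length must match number of rows")
        if np.any(self.values < 0):
            raise InputError("firing rates must be non-negative")

    @property
    def n_channels(self) -> int:
        return self.values.shape[1]


@dataclass
class KinematicsTrace:
    """2-D cursor kinematics on the 1 kHz grid.

    Velocities ``vx``/``vy`` (device units per second) are optional and are
    derived from position by :func:`compute_velocity` when absent.
    """

    time_grid: np.ndarray
    x: np.ndarray
    y: np.ndarray
    vx: np.ndarray | None = None
    vy: np.ndarray | None = None
    go_cue_ms: float | None = None

    def __post_init__(self):
        self.time_grid = np.asarray(self.time_grid, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        n = self.time_grid.shape[0]
        if self.x.shape[0] != n or self.y.shape[0] != n:
            raise InputError("x, y and time_grid must have equal length")
        if n >= 2:
            steps = np.diff(self.time_grid)
            if np.any(steps <= 0):
                raise InputError("time_grid must be strictly increasing")
        for name in ("vx", "vy"):
            v = getattr(self, name)
            if v is not None:
                v = np.asarray(v, dtype=float)
                if v.shape[0] != n:
                    raise InputError(f"{name} length must match time_grid")
                setattr(self, name, v)


@dataclass
class LabelingParams:
    """Parameters of the change-point based reference labeling.

    Defaults follow the worked labeling example: smoothing kernel SD 10 ms and
    cutoff 0.05 on the unit-sum smoothed impulse trace. The change detector is
    a sliding two-window mean-difference scan (window ``detector_window_ms``,
    sensitivity ``detector_k`` local noise SDs).
    """

    kernel_sd_ms: float = 10.0
    cutoff: float = 0.05
    detector_window_ms: int = 10
    detector_k: float = 6.0

    def __post_init__(self):
        if self.kernel_sd_ms <= 0:
            raise ParameterError("kernel_sd_ms must be > 0")
        if self.cutoff <= 0:
            raise ParameterError("cutoff must be > 0")
        if self.detector_window_ms < 1:
            raise ParameterError("detector_window_ms must be >= 1")
        if self.detector_k <= 0:
            raise ParameterError("detector_k must be > 0")


@dataclass
class StateLabels:
    """Per-sample binary state: 0 = stationary, 1 = movement."""

    labels: np.ndarray
    time_grid: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if not np.isin(self.labels, (0, 1)).all():
            raise InputError("labels must contain only 0 and 1")
        self.labels = self.labels.astype(np.int8)
        if self.time_grid is None:
            self.time_grid = np.arange(self.labels.shape[0], dtype=float)
        self.time_grid = np.asarray(self.time_grid, dtype=float)
        if self.time_grid.shape[0] != self.labels.shape[0]:
            raise InputError("labels and time_grid must have equal length")

    def __len__(self) -> int:
        return self.labels.shape[0]


def gaussian_kernel(sd_ms: float, sample_rate: float = 1000.0) -> np.ndarray:
    """Discrete zero-mean Gaussian kernel, unit sum, truncated at +-5 SD.

    Unit-sum normalization means convolving a unit impulse preserves total
    mass: a single spike contributes exactly one spike's worth of rate.
    """
    if sd_ms <= 0:
        raise ParameterError("sd_ms must be > 0")
    sd_samples = sd_ms * sample_rate / 1000.0
    radius = int(np.ceil(5.0 * sd_samples))
    t = np.arange(-radius, radius + 1, dtype=float)
    k = np.exp(-0.5 * (t / sd_samples) ** 2)
    return k / k.sum()


def _smooth(impulses: np.ndarray, sd_ms: float, sample_rate: float = 1000.0) -> np.ndarray:
    kernel = gaussian_kernel(sd_ms, sample_rate)
    return np.convolve(np.asarray(impulses, dtype=float), kernel, mode="same")


def estimate_firing_rates(spikes: SpikeTrainSet, sd_ms: float = 3.0) -> RateMatrix:
    """Estimate instantaneous firing rates by Gaussian convolution of spikes.

    Each spike is binned to its 1 ms sample and contributes a unit-area
    Gaussian bump (SD ``sd_ms``); the output is spikes/ms on the 1 kHz grid.
    """
    if sd_ms <= 0:
        raise ParameterError("sd_ms must be > 0")
    fs = spikes.sample_rate
    n = int(round(spikes.duration_ms * fs / 1000.0))
    if n < 1:
        raise InputError("duration too short for the sampling grid")
    kernel = gaussian_kernel(sd_ms, fs)
    values = np.zeros((n, spikes.n_channels))
    for c, ts in enumerate(spikes.channel_spikes):
        if ts.size == 0:
            continue
        idx = np.minimum((ts * fs / 1000.0).astype(int), n - 1)
        counts = np.bincount(idx, minlength=n).astype(float)
        values[:, c] = np.convolve(counts, kernel, mode="same")
    time_grid = np.arange(n) * (1000.0 / fs)
    return RateMatrix(values=values, time_grid=time_grid)


def detect_change_points(
    trace: np.ndarray, window_ms: int = 10, k: float = 6.0
) -> np.ndarray:
    """Mark abrupt changes in the local mean of a 1-D trace.

    A sliding two-window scan compares the mean of the ``window_ms`` samples
    before each sample with the mean of the ``window_ms`` samples from it
    onward; samples where the absolute mean difference exceeds ``k`` times the
    noise SD of that statistic are marked 1. The noise level is a robust (MAD
    of first differences) estimate, so a noiseless trace marks any sustained
    change. Returns a binary vector of the input length.
    """
    x = np.asarray(trace, dtype=float)
    n = x.shape[0]
    if n < 3:
        raise InputError("trace must have at least 3 samples")
    w = min(int(window_ms), n // 2)
    if w < 1:
        w = 1
    cs = np.concatenate(([0.0], np.cumsum(x)))
    # left mean over [i-w, i), right mean over [i, i+w), valid for i in [w, n-w]
    i = np.arange(w, n - w + 1)
    left = (cs[i] - cs[i - w]) / w
    right = (cs[i + w] - cs[i]) / w
    stat = np.abs(right - left)

    d = np.diff(x)
    mad = np.median(np.abs(d - np.median(d)))
    sigma = mad / 0.6745 / np.sqrt(2.0)  # per-sample noise SD
    scale = np.ptp(x)
    floor = 1e-9 * (scale if scale > 0 else 1.0)
    threshold = max(k * sigma * np.sqrt(2.0 / w), floor)

    marks = np.zeros(n, dtype=np.int8)
    marks[i[stat > threshold]] = 1
    return marks


def labels_from_impulses(
    impulses: np.ndarray, params: LabelingParams, sample_rate: float = 1000.0
) -> StateLabels:
    """Smooth a change-point impulse vector and threshold it into state labels.

    Impulses (integer counts; coincident x/y change points superpose) are
    convolved with a unit-sum Gaussian of SD ``kernel_sd_ms``; samples where
    the smoothed trace is >= ``cutoff`` are labeled movement.
    """
    smoothed = _smooth(impulses, params.kernel_sd_ms, sample_rate)
    return StateLabels(labels=(smoothed >= params.cutoff).astype(np.int8))


def generate_reference_labels(
    kin: KinematicsTrace, params: LabelingParams | None = None
) -> StateLabels:
    """Behavioral reference labels from cursor position.

    Change points are detected independently on the x- and y-position traces,
    the two impulse vectors are added (a simultaneous change on both axes
    counts twice — stronger evidence of movement), and the summed impulses are
    smoothed and thresholded.
    """
    if params is None:
        params = LabelingParams()
    imp_x = detect_change_points(kin.x, params.detector_window_ms, params.detector_k)
    imp_y = detect_change_points(kin.y, params.detector_window_ms, params.detector_k)
    impulses = imp_x.astype(int) + imp_y.astype(int)
    out = labels_from_impulses(impulses, params)
    out.time_grid = kin.time_grid.copy()
    return out


def compute_velocity(kin: KinematicsTrace) -> KinematicsTrace:
    """Cursor velocity in device units per second.

    Central finite differences of position (one-sided at the endpoints),
    scaled by the sampling rate. If the trace already carries velocities they
    are passed through unchanged.
    """
    if kin.vx is not None and kin.vy is not None:
        return kin
    if kin.x.shape[0] < 2:
        raise InputError("need at least 2 samples to differentiate position")
    dt_s = np.diff(kin.time_grid).mean() / 1000.0
    kin.vx = np.gradient(kin.x, dt_s)
    kin.vy = np.gradient(kin.y, dt_s)
    return kin
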