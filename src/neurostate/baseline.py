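"""Threshold-crossing (TC) baseline: velocity gating of the movement state.

The TC rule needs no training: a sample is movement whenever the cursor
velocity magnitude on either axis reaches its threshold, else stationary.
The same comparison implements the generic output gate that zeroes decoder
outputs below threshold. Thresholds are calibrated by an exhaustive sweep
against reference labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InputError, ParameterError
from .preprocess import StateLabels

__all__ = ["TCParams", "SweepResult", "tc_classify", "gate_output", "sweep_tc_threshold"]


@dataclass
class TCParams:
    """Velocity thresholds (device units per second) and the sweep grid."""

    threshold_x: float = 25.0
    threshold_y: float = 25.0
    sweep_range: range = field(default_factory=lambda: range(10, 41))

    def __post_init__(self):
        if self.threshold_x <= 0 or self.threshold_y <= 0:
            raise ParameterError("thresholds must be positive")
        if len(self.sweep_range) == 0:
            raise ParameterError("sweep_range must be non-empty")


@dataclass
class SweepResult:
    """Arg-max of mean per-trial accuracy over the threshold grid."""

    threshold_x: float
    threshold_y: float
    accuracy: float
    grid: np.ndarray          # mean accuracy, shape (len(range_x), len(range_y))
    range_x: np.ndarray
    range_y: np.ndarray


def tc_classify(vx: np.ndarray, vy: np.ndarray, params: TCParams | None = None) -> StateLabels:
    """Movement iff |vx| >= threshold_x or |vy| >= threshold_y.

    Velocities are compared by absolute value (thresholds are positive speed
    limits; signed comparison would misclassify leftward/downward moves), and
    the boundary case is movement, matching the >= convention of the output
    gate.
    """
    if params is None:
        params = TCParams()
    vx = np.asarray(vx, dtype=float)
    vy = np.asarray(vy, dtype=float)
    if vx.shape != vy.shape:
        raise InputError("vx and vy must have equal length")
    movement = (np.abs(vx) >= params.threshold_x) | (np.abs(vy) >= params.threshold_y)
    return StateLabels(labels=movement.astype(np.int8))


def gate_output(output: np.ndarray, threshold: float) -> np.ndarray:
    """Zero every output below threshold; pass through at/above it."""
    if threshold < 0:
        raise ParameterError("threshold must be >= 0")
    out = np.asarray(output, dtype=float)
    return np.where(out >= threshold, out, 0.0)


def sweep_tc_threshold(
    trials: list[tuple[np.ndarray, np.ndarray, StateLabels]],
    sweep_range: range | None = None,
) -> SweepResult:
    """Exhaustive grid search of (threshold_x, threshold_y) by mean accuracy.

    ``trials`` holds (vx, vy, reference labels) per trial. The mean of
    per-trial accuracies is maximized over the integer grid; ties go to the
    smallest thresholds (x first, then y).
    """
    if len(trials) == 0:
        raise InputError("empty trial list")
    if sweep_range is None:
        sweep_range = TCParams().sweep_range
    tx = np.asarray(list(sweep_range), dtype=float)
    ty = tx.copy()

    ax = [np.abs(np.asarray(vx, dtype=float)) for vx, _, _ in trials]
    ay = [np.abs(np.asarray(vy, dtype=float)) for _, vy, _ in trials]
    refs = [lab.labels.astype(bool) for _, _, lab in trials]

    grid = np.zeros((tx.size, ty.size))
    for t, (a, b, ref) in enumerate(zip(ax, ay, refs)):
        n = ref.size
        # pred(i,j) = (a >= tx[i]) | (b >= ty[j]); accumulate accuracy per trial
        mx = a[None, :] >= tx[:, None]          # (nx, n)
        my = b[None, :] >= ty[:, None]          # (ny, n)
        for i in range(tx.size):
            pred = mx[i][None, :] | my          # (ny, n)
            correct = (pred == ref[None, :]).sum(axis=1)
            grid[i] += correct / n
    grid /= len(trials)

    best = np.unravel_index(np.argmax(grid), grid.shape)
    # argmax returns the first (row-major) maximum: smallest x then y on ties
    return SweepResult(
        threshold_x=float(tx[best[0]]),
        threshold_y=float(ty[best[1]]),
        accuracy=float(grid[best]),
        grid=grid,
        range_x=tx,
        range_y=ty,
    )
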