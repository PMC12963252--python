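"""Evaluation battery: confusion metrics, transitions, responsiveness, stats.

Classification quality is reported per declared positive class (movement or
stationary) as accuracy, sensitivity, specificity, precision and F-score.
Output continuity is measured by transition counts (any label change), and
timing by responsiveness: the signed difference between each decoded state
onset and the corresponding reference transition (reactivity; negative =
decoder led behavior) and its absolute value (sensitivity in ms). State
comparisons delegate the standard tests (Shapiro-Wilk, Wilcoxon signed-rank,
t distributions) to scipy; pairing logic and Cohen's d are computed here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import InputError, ParameterError
from .preprocess import RateMatrix, StateLabels

__all__ = [
    "ConfusionCounts",
    "PerformanceMetrics",
    "TransitionList",
    "ResponsivenessResult",
    "EffectSizeReport",
    "StateRateComparison",
    "confusion_metrics",
    "count_transitions",
    "extract_onsets",
    "compute_responsiveness",
    "summarize_trial_responsiveness",
    "compare_states_spike_rates",
    "effect_size_report",
]


@dataclass
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int
    positive_class: int = 1

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class PerformanceMetrics:
    """The five headline metrics; zero-denominator metrics are NaN and listed
    in ``undefined``."""

    accuracy: float
    sensitivity: float
    specificity: float
    precision: float
    f_score: float
    undefined: list[str] = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "precision": self.precision,
            "f_score": self.f_score,
        }


@dataclass
class TransitionList:
    """Times (ms) and directions of label changes; directions alternate."""

    times: np.ndarray
    directions: list[str]  # "start" (0->1) or "end" (1->0)

    def __len__(self) -> int:
        return self.times.shape[0]


@dataclass
class ResponsivenessResult:
    """Signed (reactivity) and absolute (sensitivity) onset differences, ms."""

    start_reactivity_ms: np.ndarray
    end_reactivity_ms: np.ndarray
    unmatched_starts: int = 0
    unmatched_ends: int = 0
    empty: bool = False

    @property
    def start_sensitivity_ms(self) -> np.ndarray:
        return np.abs(self.start_reactivity_ms)

    @property
    def end_sensitivity_ms(self) -> np.ndarray:
        return np.abs(self.end_reactivity_ms)


@dataclass
class EffectSizeReport:
    t_statistic: float
    degrees_of_freedom: int
    p_value: float
    cohens_d: float
    test_kind: str


@dataclass
class StateRateComparison:
    """Per (channel, trial) mean rates by state plus the paired comparison."""

    stationary_means: np.ndarray   # (pairs,) Hz
    movement_means: np.ndarray     # (pairs,) Hz
    channel_mean_abs_diff: np.ndarray  # per channel, Hz
    wilcoxon_statistic: float
    wilcoxon_p: float
    shapiro_p: float
    n_pairs: int
    skipped_pairs: int
    underpowered: bool = False


def confusion_metrics(
    pred: StateLabels, ref: StateLabels, positive_class: int = 1
) -> tuple[ConfusionCounts, PerformanceMetrics]:
    """Confusion counts and the five metrics for the declared positive class."""
    p = pred.labels if isinstance(pred, StateLabels) else np.asarray(pred)
    r = ref.labels if isinstance(ref, StateLabels) else np.asarray(ref)
    if p.shape[0] != r.shape[0]:
        raise InputError("prediction and reference must have equal length")
    pos = positive_class
    pp, rp = (p == pos), (r == pos)
    counts = ConfusionCounts(
        tp=int(np.sum(pp & rp)),
        fp=int(np.sum(pp & ~rp)),
        tn=int(np.sum(~pp & ~rp)),
        fn=int(np.sum(~pp & rp)),
        positive_class=pos,
    )
    return counts, metrics_from_counts(counts)


def metrics_from_counts(c: ConfusionCounts) -> PerformanceMetrics:
    undefined: list[str] = []

    def ratio(num: int, den: int, name: str) -> float:
        if den == 0:
            undefined.append(name)
            return float("nan")
        return num / den

    accuracy = ratio(c.tp + c.tn, c.total, "accuracy")
    sensitivity = ratio(c.tp, c.tp + c.fn, "sensitivity")
    specificity = ratio(c.tn, c.tn + c.fp, "specificity")
    precision = ratio(c.tp, c.tp + c.fp, "precision")
    if np.isnan(precision) or np.isnan(sensitivity) or (precision + sensitivity) == 0:
        undefined.append("f_score")
        f_score = float("nan")
    else:
        f_score = 2 * precision * sensitivity / (precision + sensitivity)
    if undefined:
        warnings.warn(f"undefined metrics (zero denominator): {undefined}")
    return PerformanceMetrics(accuracy, sensitivity, specificity, precision,
                              f_score, undefined)


def count_transitions(labels: StateLabels) -> int:
    """Number of adjacent unequal label pairs."""
    v = labels.labels if isinstance(labels, StateLabels) else np.asarray(labels)
    if v.shape[0] < 2:
        return 0
    return int(np.count_nonzero(np.diff(v.astype(int))))


def extract_onsets(labels: StateLabels) -> TransitionList:
    """Transition times (first sample of the new state) and directions."""
    if not isinstance(labels, StateLabels):
        labels = StateLabels(np.asarray(labels))
    v = labels.labels.astype(int)
    if v.shape[0] < 2:
        return TransitionList(times=np.array([]), directions=[])
    d = np.diff(v)
    idx = np.flatnonzero(d != 0) + 1
    times = labels.time_grid[idx]
    directions = ["start" if d[i - 1] > 0 else "end" for i in idx]
    return TransitionList(times=np.asarray(times, dtype=float), directions=directions)


def _match_nearest(ref_times: np.ndarray, pred_times: np.ndarray,
                   window_ms: float = 0.0) -> tuple[np.ndarray, int]:
    """Nearest pred transition per ref transition; ties -> earlier candidate."""
    if pred_times.size == 0:
        return np.array([]), ref_times.size
    out = np.empty(ref_times.size)
    for j, t in enumerate(ref_times):
        d = pred_times - t
        best = np.argmin(np.abs(d) - 1e-9 * (d < 0))  # tie-break toward earlier
        out[j] = d[best]
    return out, 0


def _match_first_after(ref_times: np.ndarray, pred_times: np.ndarray,
                       window_ms: float = 100.0) -> tuple[np.ndarray, int]:
    """First pred transition at/after (ref - window); unmatched refs counted."""
    out, unmatched = [], 0
    for t in ref_times:
        later = pred_times[pred_times >= t - window_ms]
        if later.size:
            out.append(later[0] - t)
        else:
            unmatched += 1
    return np.asarray(out), unmatched


_MATCHERS = {"nearest": _match_nearest, "first_after": _match_first_after}


def compute_responsiveness(pred: StateLabels, ref: StateLabels,
                           matching: str = "nearest",
                           window_ms: float = 100.0) -> ResponsivenessResult:
    """Match each reference transition with a same-direction decoded transition
    and return the signed onset differences (decoded - reference).

    ``matching`` is "nearest" (default; ties -> earlier) or "first_after"
    (first decoded transition at/after reference minus ``window_ms``)."""
    if matching not in _MATCHERS:
        raise ParameterError(f"unknown matching rule: {matching!r}")
    match = _MATCHERS[matching]
    ref_tr = extract_onsets(ref)
    if len(ref_tr) == 0:
        raise InputError("reference labels contain no transitions")
    pred_tr = extract_onsets(pred)
    if len(pred_tr) == 0:
        return ResponsivenessResult(
            start_reactivity_ms=np.array([]), end_reactivity_ms=np.array([]),
            unmatched_starts=sum(d == "start" for d in ref_tr.directions),
            unmatched_ends=sum(d == "end" for d in ref_tr.directions),
            empty=True,
        )
    out = {}
    unmatched = {}
    for kind in ("start", "end"):
        rt = ref_tr.times[[d == kind for d in ref_tr.directions]]
        pt = pred_tr.times[[d == kind for d in pred_tr.directions]]
        out[kind], unmatched[kind] = match(rt, pt, window_ms)
    return ResponsivenessResult(
        start_reactivity_ms=out["start"],
        end_reactivity_ms=out["end"],
        unmatched_starts=unmatched["start"],
        unmatched_ends=unmatched["end"],
    )


def summarize_trial_responsiveness(pred: StateLabels, ref: StateLabels) -> dict:
    """One start/end reactivity pair per trial.

    When the reference carries more than two transitions the FIRST start and
    LAST end are used (trials nominally contain exactly one movement bout).
    """
    ref_tr = extract_onsets(ref)
    if len(ref_tr) == 0:
        raise InputError("reference labels contain no transitions")
    pred_tr = extract_onsets(pred)
    result: dict = {"start_ms": np.nan, "end_ms": np.nan}
    starts = ref_tr.times[[d == "start" for d in ref_tr.directions]]
    ends = ref_tr.times[[d == "end" for d in ref_tr.directions]]
    for kind, ref_t in (("start", starts[:1]), ("end", ends[-1:])):
        if ref_t.size == 0:
            continue
        pt = pred_tr.times[[d == kind for d in pred_tr.directions]]
        delta, _ = _match_nearest(ref_t, pt)
        if delta.size:
            result[f"{kind}_ms"] = float(delta[0])
    return result


def compare_states_spike_rates(
    trials: list[tuple[RateMatrix, StateLabels]],
) -> StateRateComparison:
    """Mean rate per (channel, trial, state), paired nonparametric comparison.

    Rates are reported in Hz. Pairs where a trial lacks one of the states are
    skipped (and counted). Also emits the per-channel mean |rate difference|
    consumed by the loading regression.
    """
    if len(trials) == 0:
        raise InputError("empty trial list")
    sta, mov = [], []
    n_channels = trials[0][0].n_channels
    diffs_by_channel = [[] for _ in range(n_channels)]
    skipped = 0
    for rates, labels in trials:
        y = labels.labels.astype(bool)
        if y.all() or (~y).all():
            skipped += rates.n_channels
            continue
        m_mov = rates.values[y].mean(axis=0) * 1000.0
        m_sta = rates.values[~y].mean(axis=0) * 1000.0
        sta.append(m_sta)
        mov.append(m_mov)
        for c in range(n_channels):
            diffs_by_channel[c].append(abs(m_mov[c] - m_sta[c]))
    if not sta:
        raise InputError("no trial contained both states")
    sta_arr = np.concatenate(sta)
    mov_arr = np.concatenate(mov)
    d = mov_arr - sta_arr
    underpowered = d.size < 10
    if np.allclose(d, 0):
        w_stat, w_p = np.nan, 1.0
    else:
        nz = d[d != 0]
        w = stats.wilcoxon(nz) if nz.size else None
        w_stat = float(w.statistic) if w else np.nan
        w_p = float(w.pvalue) if w else 1.0
    # Shapiro-Wilk is only defined for n in [3, 5000]; subsample deterministically
    if d.size >= 3:
        sample = d if d.size <= 5000 else d[:: d.size // 5000 + 1][:5000]
        try:
            sh_p = float(stats.shapiro(sample).pvalue)
        except ValueError:
            sh_p = np.nan
    else:
        sh_p = np.nan
    chan_diff = np.array([np.mean(v) if v else np.nan for v in diffs_by_channel])
    return StateRateComparison(
        stationary_means=sta_arr,
        movement_means=mov_arr,
        channel_mean_abs_diff=chan_diff,
        wilcoxon_statistic=w_stat,
        wilcoxon_p=w_p,
        shapiro_p=sh_p,
        n_pairs=int(d.size),
        skipped_pairs=skipped,
        underpowered=underpowered,
    )


def effect_size_report(
    x: np.ndarray,
    y: np.ndarray | None = None,
    kind: str = "one-sample",
    direction: str = "two-sided",
    popmean: float = 0.0,
) -> EffectSizeReport:
    """t-test with Cohen's d.

    ``kind``: "paired" compares x against y on the difference distribution
    (d = mean(diff)/SD(diff)); "one-sample" tests x against ``popmean``
    (d = mean(x - popmean)/SD(x)). ``direction`` is scipy's alternative
    ("two-sided", "less", "greater"). SD uses ddof = 1; df = n - 1.
    """
    x = np.asarray(x, dtype=float)
    if kind == "paired":
        if y is None:
            raise ParameterError("paired test requires two samples")
        y = np.asarray(y, dtype=float)
        if x.shape != y.shape:
            raise InputError("paired samples must have equal length")
        diff = x - y
    elif kind == "one-sample":
        diff = x - popmean
    else:
        raise ParameterError(f"unknown test kind: {kind!r}")
    n = diff.shape[0]
    if n < 2:
        raise InputError("need at least 2 observations")
    sd = diff.std(ddof=1)
    if sd == 0:
        raise InputError("zero standard deviation; effect size undefined")
    d = float(diff.mean() / sd)
    res = stats.ttest_1samp(diff, 0.0, alternative=direction)
    return EffectSizeReport(
        t_statistic=float(res.statistic),
        degrees_of_freedom=n - 1,
        p_value=float(res.pvalue),
        cohens_d=d,
        test_kind=kind if direction == "two-sided" else f"{kind} ({direction})",
    )
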