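"""Metric battery: confusion metrics, transitions, responsiveness, statistics."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from neurostate import (
    InputError,
    StateLabels,
    compare_states_spike_rates,
    compute_responsiveness,
    confusion_metrics,
    count_transitions,
    effect_size_report,
    extract_onsets,
)
from neurostate.evaluate import (
    ConfusionCounts,
    metrics_from_counts,
    summarize_trial_responsiveness,
)
from neurostate.preprocess import RateMatrix


class TestConfusionMetrics:
    def test_perfect_prediction(self):
        y = StateLabels(np.tile([0, 1], 10))
        _, pm = confusion_metrics(y, y)
        assert all(v == 1.0 for v in pm.as_dict().values())

    def test_inverted_prediction_zero_accuracy(self):
        y = np.tile([0, 1], 10)
        _, pm = confusion_metrics(StateLabels(1 - y), StateLabels(y))
        assert pm.accuracy == 0.0

    def test_hand_computed_example(self):
        pm = metrics_from_counts(ConfusionCounts(tp=9, fp=1, tn=8, fn=2))
        assert pm.accuracy == pytest.approx(0.85)
        assert pm.precision == pytest.approx(0.9)
        assert pm.sensitivity == pytest.approx(9 / 11)
        assert pm.specificity == pytest.approx(8 / 9)
        assert pm.f_score == pytest.approx(2 * 0.9 * (9 / 11) / (0.9 + 9 / 11))

    def test_zero_denominator_flagged_undefined(self):
        with pytest.warns(UserWarning):
            pm = metrics_from_counts(ConfusionCounts(tp=0, fp=0, tn=5, fn=0))
        assert np.isnan(pm.sensitivity)
        assert "sensitivity" in pm.undefined

    def test_length_mismatch(self):
        with pytest.raises(InputError):
            confusion_metrics(StateLabels(np.zeros(3, int)),
                              StateLabels(np.zeros(4, int)))

    def test_class_swap_symmetry_enumerated(self):
        """Swapping the positive class exchanges sensitivity and specificity
        and maps precision to the negative predictive value."""
        for tp, fp, tn, fn in itertools.product(range(4), repeat=4):
            if tp + fp + tn + fn == 0:
                continue
            import warnings
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                pos = metrics_from_counts(ConfusionCounts(tp, fp, tn, fn))
                neg = metrics_from_counts(ConfusionCounts(tp=tn, fp=fn, tn=tp, fn=fp))
            for a, b in [(pos.sensitivity, neg.specificity),
                         (pos.specificity, neg.sensitivity)]:
                assert (np.isnan(a) and np.isnan(b)) or a == pytest.approx(b)

    def test_f_score_between_precision_and_sensitivity(self):
        for tp, fp, tn, fn in itertools.product(range(1, 4), repeat=4):
            pm = metrics_from_counts(ConfusionCounts(tp, fp, tn, fn))
            lo = min(pm.precision, pm.sensitivity)
            hi = max(pm.precision, pm.sensitivity)
            assert lo - 1e-12 <= pm.f_score <= hi + 1e-12


class TestTransitions:
    def test_examples(self):
        assert count_transitions(StateLabels(np.array([0, 0, 1, 1, 0]))) == 2
        assert count_transitions(StateLabels(np.zeros(5, int))) == 0
        assert count_transitions(StateLabels(np.tile([0, 1], 6))) == 11

    @settings(derandomize=True, max_examples=100)
    @given(st.lists(st.integers(0, 1), min_size=1, max_size=12))
    def test_matches_bruteforce_and_onset_list(self, bits):
        labels = StateLabels(np.asarray(bits))
        brute = sum(1 for a, b in zip(bits, bits[1:]) if a != b)
        assert count_transitions(labels) == brute
        assert len(extract_onsets(labels)) == brute

    def test_onset_times_and_directions(self):
        tr = extract_onsets(StateLabels(np.array([0, 0, 1])))
        assert tr.times.tolist() == [2.0]
        assert tr.directions == ["start"]
        tr = extract_onsets(StateLabels(np.array([1, 0, 1])))
        assert tr.times.tolist() == [1.0, 2.0]
        assert tr.directions == ["end", "start"]
        # alternation invariant
        assert all(a != b for a, b in zip(tr.directions, tr.directions[1:]))

    def test_all_stationary_empty_onsets(self):
        assert len(extract_onsets(StateLabels(np.zeros(10, int)))) == 0


def labels_with_bout(n, on, off):
    v = np.zeros(n, dtype=int)
    v[on:off] = 1
    return StateLabels(v)


class TestResponsiveness:
    def test_shifted_prediction_constant_reactivity(self):
        ref = labels_with_bout(1000, 500, 800)
        pred = labels_with_bout(1000, 490, 790)
        res = compute_responsiveness(pred, ref)
        assert res.start_reactivity_ms.tolist() == [-10.0]
        assert res.end_reactivity_ms.tolist() == [-10.0]
        assert res.start_sensitivity_ms.tolist() == [10.0]

    def test_identical_labels_zero_reactivity(self):
        ref = labels_with_bout(1000, 500, 800)
        res = compute_responsiveness(ref, ref)
        assert res.start_reactivity_ms.tolist() == [0.0]
        assert res.end_reactivity_ms.tolist() == [0.0]

    def test_nearest_match_not_first(self):
        # reference start at 500; decoded starts at 460 and 530 -> +30 wins
        ref = labels_with_bout(1000, 500, 900)
        pred = np.zeros(1000, dtype=int)
        pred[460:470] = 1
        pred[530:900] = 1
        res = compute_responsiveness(StateLabels(pred), ref)
        assert res.start_reactivity_ms.tolist() == [30.0]

    def test_tie_prefers_earlier(self):
        ref = labels_with_bout(1000, 500, 900)
        pred = np.zeros(1000, dtype=int)
        pred[480:490] = 1   # start at 480 (-20)
        pred[520:900] = 1   # start at 520 (+20)
        res = compute_responsiveness(StateLabels(pred), ref)
        assert res.start_reactivity_ms.tolist() == [-20.0]

    def test_no_decoded_transitions_flagged(self):
        ref = labels_with_bout(100, 40, 60)
        res = compute_responsiveness(StateLabels(np.zeros(100, int)), ref)
        assert res.empty
        assert res.unmatched_starts == 1 and res.unmatched_ends == 1

    def test_antisymmetry_for_one_to_one_matching(self):
        ref = labels_with_bout(1000, 500, 800)
        pred = labels_with_bout(1000, 520, 790)
        fwd = compute_responsiveness(pred, ref)
        bwd = compute_responsiveness(ref, pred)
        np.testing.assert_array_equal(fwd.start_reactivity_ms,
                                      -bwd.start_reactivity_ms)
        np.testing.assert_array_equal(fwd.end_reactivity_ms,
                                      -bwd.end_reactivity_ms)

    def test_first_after_matching_rule(self):
        # decoded starts at 460 and 530; first-after(ref-100) picks 460
        ref = labels_with_bout(1000, 500, 900)
        pred = np.zeros(1000, dtype=int)
        pred[460:470] = 1
        pred[530:900] = 1
        res = compute_responsiveness(StateLabels(pred), ref,
                                     matching="first_after", window_ms=100.0)
        assert res.start_reactivity_ms.tolist() == [-40.0]

    def test_trial_summary_uses_first_start_last_end(self):
        ref = np.zeros(1000, dtype=int)
        ref[300:400] = 1
        ref[600:700] = 1  # two bouts: starts 300,600; ends 400,700
        pred = labels_with_bout(1000, 290, 710)
        summ = summarize_trial_responsiveness(StateLabels(pred.labels),
                                              StateLabels(ref))
        assert summ["start_ms"] == -10.0  # vs first start (300)
        assert summ["end_ms"] == 10.0     # vs last end (700)


class TestStateRates:
    def _trials(self, factor, n_trials=5, n=200, n_ch=12):
        trials = []
        for _ in range(n_trials):
            y = np.zeros(n, dtype=int)
            y[n // 2 :] = 1
            base = np.linspace(0.01, 0.05, n_ch)
            vals = np.tile(base, (n, 1))
            vals[y == 1] *= factor
            trials.append((RateMatrix(vals, np.arange(n, dtype=float)),
                           StateLabels(y)))
        return trials

    def test_identical_rates_null_comparison(self):
        cmp = compare_states_spike_rates(self._trials(1.0))
        assert cmp.wilcoxon_p == pytest.approx(1.0)
        np.testing.assert_allclose(cmp.channel_mean_abs_diff, 0.0, atol=1e-12)

    def test_doubled_movement_rates_all_positive_significant(self):
        cmp = compare_states_spike_rates(self._trials(2.0))
        assert cmp.n_pairs >= 50
        assert np.all(cmp.movement_means > cmp.stationary_means)
        assert cmp.wilcoxon_p < 0.001

    def test_single_pair_underpowered_but_reported(self):
        trials = self._trials(2.0, n_trials=1, n_ch=1)
        cmp = compare_states_spike_rates(trials)
        assert cmp.underpowered
        assert cmp.n_pairs == 1
        assert cmp.movement_means[0] > cmp.stationary_means[0]

    def test_single_class_trial_skipped(self):
        trials = self._trials(2.0, n_trials=2)
        n, n_ch = 200, 12
        vals = np.full((n, n_ch), 0.02)
        trials.append((RateMatrix(vals, np.arange(n, dtype=float)),
                       StateLabels(np.zeros(n, dtype=int))))
        cmp = compare_states_spike_rates(trials)
        assert cmp.skipped_pairs == n_ch


class TestEffectSize:
    def test_one_sample_unit_effect(self):
        x = np.array([0.0, 2.0, 0.0, 2.0, 0.0, 2.0])  # mean 1
        rep = effect_size_report(x, kind="one-sample")
        assert rep.cohens_d == pytest.approx(x.mean() / x.std(ddof=1))
        assert rep.degrees_of_freedom == 5

    def test_hand_computed_example(self):
        x = np.array([-2.0, -1.0, -1.0, 0.0])
        rep = effect_size_report(x, kind="one-sample")
        assert rep.cohens_d == pytest.approx(-1.2247, abs=1e-4)
        assert rep.t_statistic == pytest.approx(-2.449, abs=1e-3)

    def test_one_sided_less_smaller_p_for_negative_mean(self):
        x = np.array([-2.0, -1.0, -1.5, -0.5, -1.0])
        two = effect_size_report(x, direction="two-sided")
        less = effect_size_report(x, direction="less")
        assert less.p_value == pytest.approx(two.p_value / 2)

    def test_paired_identical_samples_error(self):
        x = np.arange(5, dtype=float)
        with pytest.raises(InputError):
            effect_size_report(x, x, kind="paired")

    def test_paired_matches_difference_one_sample(self):
        rng = np.random.default_rng(0)
        x, y = rng.normal(1, 1, 30), rng.normal(0, 1, 30)
        paired = effect_size_report(x, y, kind="paired")
        onesample = effect_size_report(x - y, kind="one-sample")
        assert paired.t_statistic == pytest.approx(onesample.t_statistic)
        assert paired.cohens_d == pytest.approx(onesample.cohens_d)
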