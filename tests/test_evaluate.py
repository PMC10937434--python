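"""Flag combination, threshold tuning and statistics oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oarqa.evaluate import (combine_flags, confusion_metrics, mcnemar_midp,
                            mcnemar_midp_counts, roc_auc, subsample_balanced,
                            tune_threshold)


def brute_force_auc(scores, truth):
    pos = [s for s, t in zip(scores, truth) if t]
    neg = [s for s, t in zip(scores, truth) if not t]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


def brute_force_tune(scores, truth, fixed):
    scores = np.asarray(scores, float)
    candidates = np.concatenate((
        [-np.inf, np.inf],
        (np.sort(np.unique(scores))[:-1] + np.sort(np.unique(scores))[1:]) / 2
        if len(np.unique(scores)) > 1 else [],
    ))
    best = (-np.inf, None)
    for thr in sorted(candidates):
        pred = (scores > thr) | fixed
        m = confusion_metrics(pred, truth)
        if m.balanced_accuracy >= best[0]:
            best = (m.balanced_accuracy, thr)
    return best[1], best[0]


class TestCombineAndConfusion:
    @pytest.mark.parametrize("flags,expected", [
        ((0, 0, 0), 0), ((0, 1, 0), 1), ((1, 1, 1), 1), ((0, 0, 1), 1),
    ])
    def test_or_combination(self, flags, expected):
        assert combine_flags(*flags) == bool(expected)

    def test_perfect_prediction(self):
        truth = ["erroneous", "acceptable", "erroneous"]
        m = confusion_metrics([True, False, True], truth)
        assert (m.sensitivity, m.specificity, m.balanced_accuracy) == (1, 1, 1)

    def test_counts_to_metrics(self):
        # confusion row with known sensitivity/specificity at 3 decimals
        pred = [True] * 31 + [False] * 6 + [False] * 1848 + [True] * 157
        truth = ["erroneous"] * 37 + ["acceptable"] * 2005
        m = confusion_metrics(pred, truth)
        r = m.rounded()
        assert (r["sensitivity"], r["specificity"],
                r["balanced_accuracy"]) == (0.838, 0.922, 0.880)

    def test_empty_is_fatal(self):
        with pytest.raises(ValueError):
            confusion_metrics([], [])


class TestRocAuc:
    def test_perfect_separation(self):
        assert roc_auc([1, 2, 9, 10], ["acceptable", "acceptable",
                                       "erroneous", "erroneous"]) == 1.0

    def test_all_ties(self):
        assert roc_auc([5, 5, 5, 5], [True, False, True, False]) == 0.5

    def test_three_of_four_concordant(self):
        assert roc_auc([1, 3, 2, 4], ["acceptable", "acceptable",
                                      "erroneous", "erroneous"]) == 0.75

    def test_one_class_is_fatal(self):
        with pytest.raises(ValueError):
            roc_auc([1, 2], [True, True])

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_equals_pairwise_concordance(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(4, 60)
        scores = rng.normal(size=n).round(1)  # rounding forces ties
        truth = rng.integers(0, 2, size=n).astype(bool)
        if truth.all() or not truth.any():
            truth[0] = ~truth[0]
        assert roc_auc(scores, truth) == pytest.approx(
            brute_force_auc(scores, truth), abs=1e-12)


class TestTuneThreshold:
    def test_separable_fixture_reaches_perfect_ba(self):
        thr, ba = tune_threshold([0.1, 0.2, 0.8, 0.9],
                                 ["acceptable", "acceptable",
                                  "erroneous", "erroneous"])
        assert 0.2 < thr < 0.8
        assert ba == 1.0

    def test_degenerate_equal_metrics_fall_back_to_fixed_flags(self):
        truth = ["acceptable", "erroneous", "acceptable", "erroneous"]
        fixed = [False, True, False, True]
        thr, ba = tune_threshold([1.0] * 4, truth, fixed_flags=fixed)
        assert thr == np.inf
        assert ba == 1.0

    def test_fixed_flags_allow_higher_threshold(self):
        # the one erroneous contour below the best blind cut is covered by a
        # CCR flag, so tuning with the flag can afford a higher threshold
        scores = [0.1, 0.15, 0.2, 0.25, 0.3, 0.45, 0.5, 0.6, 0.7, 0.8]
        truth = (["acceptable"] * 5 + ["erroneous"]
                 + ["acceptable"] * 2 + ["erroneous"] * 2)
        fixed = np.zeros(10, bool)
        fixed[5] = True
        thr_blind, _ = tune_threshold(scores, truth)
        thr_fixed, ba_fixed = tune_threshold(scores, truth, fixed_flags=fixed)
        assert thr_fixed > thr_blind
        bf_thr, bf_ba = brute_force_tune(scores, truth, fixed)
        assert ba_fixed == pytest.approx(bf_ba)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_matches_exhaustive_scan(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(6, 40))
        scores = rng.normal(size=n).round(1)
        truth = rng.integers(0, 2, size=n).astype(bool)
        if truth.all() or not truth.any():
            truth[0] = ~truth[0]
        fixed = rng.random(n) < 0.2
        thr, ba = tune_threshold(scores, truth, fixed_flags=fixed)
        bf_thr, bf_ba = brute_force_tune(scores, truth, fixed)
        assert ba == pytest.approx(bf_ba, abs=1e-12)
        assert thr == pytest.approx(bf_thr)

    def test_combined_at_least_fixed_flags_alone(self):
        """The tuner can always retreat to threshold +inf, so the combined
        balanced accuracy is never below that of the fixed flags alone."""
        rng = np.random.default_rng(11)
        scores = rng.normal(size=60)
        truth = rng.integers(0, 2, size=60).astype(bool)
        fixed = rng.random(60) < 0.3
        _, ba = tune_threshold(scores, truth, fixed_flags=fixed)
        ba_fixed = confusion_metrics(fixed, truth).balanced_accuracy
        assert ba >= ba_fixed - 1e-12


class TestSubsample:
    def _tables(self):
        acc = pd.DataFrame({
            "oar_type": np.repeat([f"oar{i:02d}" for i in range(42)], 12),
            "truth": "acceptable",
        })
        err = pd.DataFrame({"oar_type": ["oar00"] * 190,
                            "truth": "erroneous"})
        return acc, err

    def test_five_per_oar_gives_210_plus_errors(self):
        acc, err = self._tables()
        sub = subsample_balanced(acc, err, n_per_oar=5, seed=0)
        assert (sub["truth"] == "acceptable").sum() == 210
        assert (sub["truth"] == "erroneous").sum() == 190

    def test_deterministic_given_seed(self):
        acc, err = self._tables()
        s1 = subsample_balanced(acc, err, seed=7)
        s2 = subsample_balanced(acc, err, seed=7)
        pd.testing.assert_frame_equal(s1, s2)

    def test_zero_per_oar_keeps_only_errors(self):
        acc, err = self._tables()
        sub = subsample_balanced(acc, err, n_per_oar=0, seed=0)
        assert (sub["truth"] == "acceptable").sum() == 0


class TestMcNemar:
    @pytest.mark.parametrize("b,c,expected", [
        (1, 5, 0.125),
        (3, 3, 1.0),
        (0, 10, 1.0 / 1024.0),
        (0, 0, 1.0),
    ])
    def test_midp_closed_forms(self, b, c, expected):
        assert mcnemar_midp_counts(b, c) == pytest.approx(expected, abs=1e-12)

    def test_from_predictions(self):
        truth = np.array([True] * 6 + [False] * 4)
        a = truth.copy()               # A always correct
        bpred = truth.copy()
        bpred[:5] = ~bpred[:5]         # B wrong on 5 of them -> b=5, c=0
        assert mcnemar_midp(a, bpred, truth) == pytest.approx(
            mcnemar_midp_counts(5, 0))

    def test_identical_predictions_give_one(self):
        truth = [True, False, True]
        preds = [True, True, False]
        assert mcnemar_midp(preds, preds, truth) == 1.0
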