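"""Diagnostic accuracy: confusion tables, binary AUC, ROC and Youden."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import roc_auc_score

from shuntpred.metrics import (
    ConfusionCounts,
    MetricsError,
    binary_auc,
    confusion_counts,
    diagnostic_performance,
    roc_and_youden,
    round_half_away,
)


class TestConfusionCounts:
    def test_perfect_agreement(self):
        truth = [True] * 6 + [False] * 4
        c = confusion_counts(truth, truth)
        assert (c.tp, c.fp, c.fn, c.tn) == (6, 0, 0, 4)

    def test_reference_tap_cross_tab(self, fixture_cohort, pinned_config):
        from shuntpred.rules import classify_tap_response

        preds = [classify_tap_response(r.tap).positive for r in fixture_cohort]
        truth = [r.outcome_label == "responder" for r in fixture_cohort]
        c = confusion_counts(preds, truth)
        assert (c.tp, c.fp, c.fn, c.tn) == (61, 28, 35, 42)

    def test_all_negative_predictor(self):
        c = confusion_counts([False] * 5, [True, True, False, False, False])
        assert c.tp == 0 and c.fp == 0 and c.fn == 2 and c.tn == 3

    def test_missing_predictions_excluded_and_tallied(self):
        c = confusion_counts([True, None, False, None], [True, True, False, False])
        assert c.total == 2 and c.n_excluded == 2

    def test_length_mismatch_raises(self):
        with pytest.raises(MetricsError):
            confusion_counts([True], [True, False])


class TestDiagnosticPerformance:
    @pytest.mark.parametrize(
        "counts, sens2dp, spec2dp",
        [
            ((61, 28, 35, 42), 0.64, 0.60),  # tap test row
            ((53, 8, 43, 62), 0.55, 0.89),  # DESH row
        ],
    )
    def test_reference_rows_round_to_printed_values(self, counts, sens2dp, spec2dp):
        perf = diagnostic_performance(ConfusionCounts(*counts))
        assert round_half_away(perf.sensitivity) == sens2dp
        assert round_half_away(perf.specificity) == spec2dp

    def test_perfect_classifier(self):
        perf = diagnostic_performance(ConfusionCounts(5, 0, 0, 5))
        assert (perf.sensitivity, perf.specificity, perf.ppv, perf.npv, perf.auc) == (
            1.0, 1.0, 1.0, 1.0, 1.0,
        )

    def test_empty_class_raises(self):
        with pytest.raises(MetricsError, match="positive"):
            diagnostic_performance(ConfusionCounts(0, 3, 0, 4))

    def test_ppv_flagged_without_positive_calls(self):
        perf = diagnostic_performance(ConfusionCounts(0, 0, 4, 5))
        assert perf.ppv is None
        assert "ppv_undefined_no_positive_calls" in perf.flags

    def test_all_small_tables_match_hand_ratios(self):
        # exhaustive oracle over every 2x2 table with entries <= 5
        for tp, fp, fn, tn in itertools.product(range(6), repeat=4):
            if tp + fn == 0 or tn + fp == 0:
                continue
            perf = diagnostic_performance(ConfusionCounts(tp, fp, fn, tn))
            assert perf.sensitivity == pytest.approx(tp / (tp + fn))
            assert perf.specificity == pytest.approx(tn / (tn + fp))
            if tp + fp:
                assert perf.ppv == pytest.approx(tp / (tp + fp))
            if tn + fn:
                assert perf.npv == pytest.approx(tn / (tn + fn))


class TestBinaryAuc:
    @pytest.mark.parametrize(
        "sens, spec, expected",
        [
            (0.6354, 0.60, 0.62),
            (0.77, 0.67, 0.72),
            (1.0, 1.0, 1.0),
            (0.79, 0.53, 0.66),
            (0.85, 0.51, 0.68),
        ],
    )
    def test_printed_pairs(self, sens, spec, expected):
        assert round_half_away(binary_auc(sens, spec)) == expected

    @settings(max_examples=100, deadline=None)
    @given(s=st.floats(0, 1), p=st.floats(0, 1))
    def test_symmetry(self, s, p):
        assert binary_auc(s, p) == binary_auc(p, s)

    def test_out_of_range_raises(self):
        with pytest.raises(MetricsError):
            binary_auc(1.2, 0.5)

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.booleans(), min_size=8, max_size=40))
    def test_equals_roc_of_dichotomized_marker(self, truth):
        # need both classes and an imperfect split for a nondegenerate 2x2
        if sum(truth) < 2 or sum(truth) > len(truth) - 2:
            return
        rng = np.random.default_rng(7)
        marker = np.where(rng.uniform(size=len(truth)) < 0.7, truth, ~np.asarray(truth))
        c = confusion_counts((marker == 1).tolist(), truth)
        if min(c.tp + c.fn, c.tn + c.fp) < 2:
            return
        perf = diagnostic_performance(c)
        roc = roc_and_youden(marker.astype(float), truth, "higher_is_positive")
        assert roc.auc == pytest.approx(binary_auc(perf.sensitivity, perf.specificity))


class TestRounding:
    @pytest.mark.parametrize(
        "x, expected", [(0.595, 0.60), (0.6177, 0.62), (0.544, 0.54), (0.545, 0.55), (-0.125, -0.13)]
    )
    def test_half_away_from_zero(self, x, expected):
        assert round_half_away(x) == expected


def _u_statistic(pos, neg):
    """Brute-force Mann-Whitney U with half credit for ties."""
    u = 0.0
    for a in pos:
        for b in neg:
            u += 1.0 if a > b else (0.5 if a == b else 0.0)
    return u


class TestRocAndYouden:
    def test_perfect_separation(self):
        r = roc_and_youden([50, 55, 60, 80, 85, 90], [1, 1, 1, 0, 0, 0], "lower_is_positive")
        assert r.auc == 1.0
        assert r.youden_j_max == 1.0
        assert 60 < r.optimal_cutoff < 80

    def test_identical_class_distributions_give_half(self):
        vals = [1.0, 2.0, 3.0, 4.0] * 2
        truth = [True] * 4 + [False] * 4
        assert roc_and_youden(vals, truth, "lower_is_positive").auc == pytest.approx(0.5)

    def test_constant_marker_flagged(self):
        r = roc_and_youden([5.0] * 10, [True] * 5 + [False] * 5, "lower_is_positive")
        assert r.auc == 0.5
        assert r.optimal_cutoff is None
        assert "constant_marker_cutoff_undefined" in r.flags

    def test_sentinels_put_corners_on_curve(self):
        r = roc_and_youden([1.0, 2.0, 3.0, 4.0], [True, True, False, False], "lower_is_positive")
        pts = r.points
        assert (pts[0][1], pts[0][2]) == (0.0, 0.0)
        assert (pts[-1][1], pts[-1][2]) == (1.0, 1.0)

    @settings(max_examples=60, deadline=None)
    @given(
        pos=st.lists(st.integers(0, 8), min_size=2, max_size=25),
        neg=st.lists(st.integers(0, 8), min_size=2, max_size=25),
    )
    def test_auc_equals_normalized_u_with_ties(self, pos, neg):
        vals = [float(v) for v in pos + neg]
        truth = [True] * len(pos) + [False] * len(neg)
        r = roc_and_youden(vals, truth, "higher_is_positive")
        assert r.auc == pytest.approx(_u_statistic(pos, neg) / (len(pos) * len(neg)))

    @settings(max_examples=40, deadline=None)
    @given(st.integers(0, 10_000))
    def test_auc_matches_sklearn_on_random_data(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=40) + np.round(rng.uniform(size=40))  # induces near-ties
        y = rng.uniform(size=40) < 0.5
        if y.sum() < 2 or (~y).sum() < 2:
            return
        r = roc_and_youden(x, y, "higher_is_positive")
        assert r.auc == pytest.approx(roc_auc_score(y, x))

    def test_tiebreak_prefers_higher_specificity(self):
        # thresholds 1.5 (sens .5, spec 1) and 4.5 (sens 1, spec .5) both
        # reach J = 0.5; the higher-specificity one must win
        vals = [1.0, 4.0, 2.0, 5.0]
        truth = [True, True, False, False]
        r = roc_and_youden(vals, truth, "lower_is_positive")
        assert r.youden_j_max == pytest.approx(0.5)
        assert r.optimal_cutoff == pytest.approx(1.5)

    def test_lower_and_higher_directions_mirror(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=60)
        y = rng.uniform(size=60) < 0.5
        lo = roc_and_youden(x, y, "lower_is_positive")
        hi = roc_and_youden(-x, y, "higher_is_positive")
        assert lo.auc == pytest.approx(hi.auc)
        assert lo.optimal_cutoff == pytest.approx(-hi.optimal_cutoff)
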