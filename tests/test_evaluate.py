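"""Diagnostic statistics: Wilson CIs, AUC/DeLong, McNemar, kappa."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from marrowtex.evaluate import (
    binarize_scores,
    cohen_kappa,
    compare_auc,
    confusion_metrics,
    kappa_band,
    mcnemar_test,
    roc_auc,
    wilson_ci,
)


def _pairwise_auc(scores, truth):
    """Exhaustive pairwise-probability AUC (independent oracle)."""
    pos = scores[truth == 1]
    neg = scores[truth == 0]
    wins = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1.0
            elif p == q:
                wins += 0.5
    return wins / (len(pos) * len(neg))


class TestBinarize:
    @pytest.mark.parametrize(
        "score, call", [(0, 0), (1, 0), (2, 0), (3, 1), (4, 1)]
    )
    def test_cut_between_equivocal_and_probably_present(self, score, call):
        assert binarize_scores([score])[0] == call

    def test_all_zero_scores_all_negative(self):
        assert not binarize_scores(np.zeros(10, int)).any()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            binarize_scores([5])


class TestConfusionMetrics:
    def test_accuracy_counts_identity(self):
        rng = np.random.default_rng(0)
        truth = rng.integers(0, 2, 60)
        pred = rng.integers(0, 2, 60)
        rep = confusion_metrics(pred, truth)
        assert rep.accuracy * rep.n == rep.counts.TP + rep.counts.TN

    def test_perfect_prediction_upper_ci_is_one(self):
        truth = np.array([0] * 5 + [1] * 5)
        rep = confusion_metrics(truth, truth)
        assert rep.accuracy == 1.0
        assert rep.accuracy_ci[1] == pytest.approx(1.0)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            confusion_metrics([], [])

    def test_single_class_truth_rejected(self):
        with pytest.raises(ValueError):
            confusion_metrics([0, 1], [1, 1])

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.integers(0, 50), st.integers(1, 50))
    def test_wilson_interval_contains_point(self, k_raw, n):
        k = min(k_raw, n)
        lo, hi = wilson_ci(k, n)
        assert lo - 1e-12 <= k / n <= hi + 1e-12

    def test_wilson_width_shrinks_with_n(self):
        widths = []
        for n in (10, 40, 160, 640):
            lo, hi = wilson_ci(int(0.8 * n), n)
            widths.append(hi - lo)
        assert widths == sorted(widths, reverse=True)


class TestAUC:
    def test_perfect_separation(self):
        auc, _ = roc_auc([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1])
        assert auc == 1.0

    def test_all_tied_scores(self):
        auc, _ = roc_auc([5, 5, 5, 5], [0, 1, 0, 1])
        assert auc == 0.5

    def test_three_by_three_example(self):
        scores = np.array([0.9, 0.8, 0.4, 0.7, 0.3, 0.2])
        truth = np.array([1, 1, 1, 0, 0, 0])
        auc, _ = roc_auc(scores, truth)
        assert auc == pytest.approx(8 / 9)

    @pytest.mark.parametrize("seed", range(5))
    def test_equals_pairwise_probability_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = 30
        truth = rng.integers(0, 2, n)
        truth[:2] = [0, 1]
        scores = np.round(rng.normal(size=n), 1)  # induces ties
        auc, _ = roc_auc(scores, truth)
        assert auc == pytest.approx(_pairwise_auc(scores, truth))

    def test_equals_trapezoidal_roc_area(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(9)
        truth = rng.integers(0, 2, 50)
        truth[:2] = [0, 1]
        scores = rng.normal(truth, 1.0)
        auc, _ = roc_auc(scores, truth)
        assert auc == pytest.approx(roc_auc_score(truth, scores))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([1, 2], [1, 1])

    def test_ci_contains_point_and_is_clipped(self):
        rng = np.random.default_rng(4)
        truth = np.array([0] * 20 + [1] * 20)
        scores = rng.normal(truth, 1.0)
        auc, (lo, hi) = roc_auc(scores, truth)
        assert 0.0 <= lo <= auc <= hi <= 1.0


class TestCompareAUC:
    def test_identical_scores_give_p_one(self):
        rng = np.random.default_rng(0)
        truth = np.array([0] * 10 + [1] * 10)
        s = rng.normal(size=20)
        assert compare_auc(s, s, truth) == 1.0

    def test_monotone_transform_gives_p_one(self):
        rng = np.random.default_rng(1)
        truth = np.array([0] * 10 + [1] * 10)
        s = rng.normal(size=20)
        assert compare_auc(s, np.exp(s), truth) == pytest.approx(1.0)

    def test_mismatched_subjects_rejected(self):
        with pytest.raises(ValueError):
            compare_auc([1, 2], [1, 2, 3], [0, 1, 1])

    def test_clearly_different_aucs_detected(self):
        rng = np.random.default_rng(2)
        truth = np.array([0] * 100 + [1] * 100)
        good = rng.normal(3 * truth, 1.0)
        noise = rng.normal(size=200)
        assert compare_auc(good, noise, truth) < 0.001


class TestMcNemar:
    def test_identical_predictions_p_one(self):
        truth = np.array([0, 1] * 10)
        pred = 1 - truth
        assert mcnemar_test(pred, pred, truth) == 1.0

    def test_exact_binomial_example(self):
        """8 vs 2 discordant pairs: exact two-sided p = 112/1024."""
        truth = np.zeros(20, int)
        pred_a = np.zeros(20, int)
        pred_b = np.zeros(20, int)
        pred_b[:8] = 1  # a correct, b wrong on 8
        pred_a[8:10] = 1  # b correct, a wrong on 2
        p = mcnemar_test(pred_a, pred_b, truth)
        assert p == pytest.approx(112 / 1024)

    def test_balanced_discordance_is_maximal(self):
        truth = np.zeros(30, int)
        base_a = np.zeros(30, int)
        base_b = np.zeros(30, int)
        base_a[:5] = 1
        base_b[5:10] = 1  # 5 vs 5 discordant
        assert mcnemar_test(base_a, base_b, truth) == 1.0

    def test_asymptotic_branch_used_for_many_discordant_pairs(self):
        truth = np.zeros(100, int)
        pred_a = np.zeros(100, int)
        pred_b = np.zeros(100, int)
        pred_a[:20] = 1
        pred_b[20:35] = 1  # 35 discordant -> chi-square branch
        p = mcnemar_test(pred_a, pred_b, truth)
        from scipy.stats import chi2

        expected = chi2.sf((abs(20 - 15) - 1) ** 2 / 35, 1)
        assert p == pytest.approx(expected)


class TestKappa:
    def test_self_agreement_is_one(self):
        labels = np.array([0, 1, 1, 0, 1])
        res = cohen_kappa(labels, labels)
        assert res.kappa == 1.0
        assert res.band == "almost perfect"

    def test_forty_ten_table(self):
        a = np.array([0] * 50 + [1] * 50)
        b = np.array([0] * 40 + [1] * 10 + [0] * 10 + [1] * 40)
        res = cohen_kappa(a, b)
        assert res.kappa == pytest.approx(0.6)
        assert res.band == "moderate"

    @pytest.mark.parametrize(
        "kappa, band",
        [(-0.2, "poor"), (0.1, "slight"), (0.3, "fair"), (0.45, "moderate"),
         (0.7, "substantial"), (0.9, "almost perfect")],
    )
    def test_band_cut_points(self, kappa, band):
        assert kappa_band(kappa) == band

    def test_label_swap_invariance(self):
        rng = np.random.default_rng(0)
        a = rng.integers(0, 2, 40)
        b = rng.integers(0, 2, 40)
        assert cohen_kappa(a, b).kappa == pytest.approx(
            cohen_kappa(1 - a, 1 - b).kappa
        )

    def test_constant_identical_raters_flagged(self):
        res = cohen_kappa([1, 1, 1], [1, 1, 1])
        assert res.kappa == 1.0
        assert res.degenerate
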