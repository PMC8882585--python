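"""Agreement and evaluation statistics against worked values and oracles."""

import math

import numpy as np
import pytest
from scipy.stats import chi2_contingency
from sklearn.metrics import cohen_kappa_score, roc_auc_score

from pterymeter.stats import (BinaryConfusion, CrossTab, binary_metrics,
                              bland_altman, chi_square_with_C, cohen_kappa,
                              dice_coefficient, miou, pixel_accuracy,
                              roc_auc_youden)


def random_tab(rng, k=3):
    while True:
        counts = rng.integers(0, 40, size=(k, k))
        if (counts.sum(axis=0) > 0).all() and (counts.sum(axis=1) > 0).all():
            return CrossTab(counts)


class TestMaskScores:
    def test_dice_basic_cases(self):
        a = np.zeros((10, 10), bool)
        a[:5] = True
        assert dice_coefficient(a, a) == 1.0
        assert dice_coefficient(a, ~a) == 0.0
        assert dice_coefficient(np.zeros((4, 4)), np.zeros((4, 4))) == 1.0

    def test_dice_half_overlap(self):
        x = np.zeros(200, bool)
        y = np.zeros(200, bool)
        x[:100] = True
        y[50:150] = True
        assert dice_coefficient(x.reshape(10, 20), y.reshape(10, 20)) == 0.5

    def test_miou_half_foreground_all_background_prediction(self):
        truth = np.zeros((10, 10), bool)
        truth[:5] = True
        pred = np.zeros_like(truth)
        assert miou(pred, truth) == pytest.approx(0.25)

    @pytest.mark.parametrize("seed", range(10))
    def test_foreground_iou_dice_identity(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.random((30, 30)) > 0.6
        t = rng.random((30, 30)) > 0.4
        d = dice_coefficient(p, t)
        inter = np.logical_and(p, t).sum()
        union = np.logical_or(p, t).sum()
        assert inter / union == pytest.approx(d / (2 - d), abs=1e-12)

    def test_pixel_accuracy(self):
        t = np.zeros((4, 4), bool)
        t[:2] = True
        assert pixel_accuracy(t, t) == 1.0
        assert pixel_accuracy(~t, t) == 0.0
        assert pixel_accuracy(np.zeros_like(t), t) == 0.5


class TestChiSquare:
    def test_published_crosstab_values(self, staging_crosstab):
        r = chi_square_with_C(staging_crosstab)
        assert r.chi2 == pytest.approx(386.233, abs=5e-4)
        assert r.df == 4
        assert r.p_value < 1e-4
        assert round(r.C, 3) == 0.786
        assert r.C_max == pytest.approx(math.sqrt(2 / 3))

    def test_independent_table_is_zero(self):
        r = chi_square_with_C(CrossTab(np.array([[1, 1], [1, 1]])))
        assert r.chi2 == 0.0
        assert r.C == 0.0

    def test_diagonal_2x2_hand_computation(self):
        r = chi_square_with_C(CrossTab(np.array([[10, 0], [0, 10]])))
        assert r.chi2 == pytest.approx(20.0)
        assert r.C == pytest.approx(math.sqrt(0.5))

    def test_zero_margin_raises_with_location(self):
        with pytest.raises(ValueError, match="column 2"):
            chi_square_with_C(CrossTab(np.array([[5, 1, 0], [2, 3, 0], [1, 1, 0]])))

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_scipy_uncorrected(self, seed):
        tab = random_tab(np.random.default_rng(seed))
        r = chi_square_with_C(tab)
        chi2, p, df, _ = chi2_contingency(tab.counts, correction=False)
        assert r.chi2 == pytest.approx(chi2)
        assert r.p_value == pytest.approx(p)
        assert r.df == df

    def test_permutation_invariance(self):
        rng = np.random.default_rng(5)
        tab = random_tab(rng)
        perm = rng.permutation(3)
        permuted = CrossTab(tab.counts[np.ix_(perm, perm)])
        assert chi_square_with_C(permuted).chi2 == pytest.approx(
            chi_square_with_C(tab).chi2)


class TestKappa:
    def test_published_crosstab_kappa(self, staging_crosstab):
        r = cohen_kappa(staging_crosstab)
        assert round(r.kappa, 3) == 0.918
        assert r.po == pytest.approx(227 / 239)
        assert r.pe == pytest.approx(22045 / 57121)

    def test_diagonal_table_is_one(self):
        assert cohen_kappa(CrossTab(np.diag([5, 7, 3]))).kappa == 1.0

    def test_chance_agreement_is_zero(self):
        assert cohen_kappa(CrossTab(np.array([[5, 5], [5, 5]]))).kappa == 0.0

    def test_kappa_one_only_for_diagonal(self):
        r = cohen_kappa(CrossTab(np.array([[10, 1], [0, 10]])))
        assert r.kappa < 1.0

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_sklearn(self, seed):
        tab = random_tab(np.random.default_rng(seed))
        ref, pred = [], []
        for i in range(3):
            for j in range(3):
                ref += [i] * tab.counts[i, j]
                pred += [j] * tab.counts[i, j]
        assert cohen_kappa(tab).kappa == pytest.approx(
            cohen_kappa_score(ref, pred))

    def test_linear_weighted_variant(self, staging_crosstab):
        r = cohen_kappa(staging_crosstab, weighted=True)
        assert r.kappa == pytest.approx(
            cohen_kappa_score(*_expand(staging_crosstab), weights="linear"))

    def test_degenerate_table_raises(self):
        with pytest.raises(ValueError):
            cohen_kappa(CrossTab(np.array([[10, 0], [0, 0]])))


def _expand(tab):
    ref, pred = [], []
    for i in range(tab.k):
        for j in range(tab.k):
            ref += [i] * tab.counts[i, j]
            pred += [j] * tab.counts[i, j]
    return ref, pred


class TestBinaryMetrics:
    def test_published_threshold3_row(self):
        m = binary_metrics(BinaryConfusion(tp=38, tn=68, fp=8, fn=4))
        assert round(m.accuracy, 4) == 0.8983
        assert round(m.sensitivity, 4) == 0.9048
        assert round(m.precision, 4) == 0.8261
        assert round(m.f1, 4) == 0.8636

    def test_perfect_confusion(self):
        m = binary_metrics(BinaryConfusion(tp=10, tn=20, fp=0, fn=0))
        assert (m.accuracy, m.specificity, m.sensitivity, m.precision, m.f1) == \
            (1.0, 1.0, 1.0, 1.0, 1.0)

    def test_uniform_confusion_all_half(self):
        m = binary_metrics(BinaryConfusion(tp=1, tn=1, fp=1, fn=1))
        assert (m.accuracy, m.specificity, m.sensitivity, m.precision, m.f1) == \
            (0.5, 0.5, 0.5, 0.5, 0.5)

    def test_undefined_metric_is_none_not_zero(self):
        m = binary_metrics(BinaryConfusion(tp=0, tn=5, fp=0, fn=0))
        assert m.precision is None
        assert m.sensitivity is None

    def test_crosstab_collapse(self, staging_crosstab):
        c = BinaryConfusion.from_crosstab_surgery(staging_crosstab)
        assert (c.tp, c.tn, c.fp, c.fn) == (38, 68, 8, 4)


def auc_pair_counting(scores, labels):
    """Mann-Whitney oracle: fraction of positive-negative pairs ranked
    correctly, ties counted half."""
    s = np.asarray(scores, float)
    y = np.asarray(labels, bool)
    pos, neg = s[y], s[~y]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestRoc:
    def test_perfect_separation(self):
        r = roc_auc_youden([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1])
        assert r.auc == 1.0
        assert 3 < r.youden_threshold <= 10
        assert r.youden_index == 1.0

    def test_uninformative_scores_near_half(self):
        rng = np.random.default_rng(0)
        scores = rng.random(2000)
        labels = rng.random(2000) < 0.5
        assert roc_auc_youden(scores, labels).auc == pytest.approx(0.5, abs=0.05)

    @pytest.mark.parametrize("seed", range(10))
    def test_trapezoid_equals_pair_counting_oracle(self, seed):
        rng = np.random.default_rng(seed)
        scores = np.round(rng.random(30), 2)  # induce ties
        labels = rng.random(30) < 0.4
        if labels.all() or not labels.any():
            labels[0] = ~labels[0]
        r = roc_auc_youden(scores, labels)
        assert r.auc == pytest.approx(auc_pair_counting(scores, labels), abs=1e-12)
        assert r.auc == pytest.approx(roc_auc_score(labels, scores), abs=1e-12)

    def test_tie_broken_toward_larger_threshold(self):
        # thresholds 4 and 2 both give Youden index 0.5
        r = roc_auc_youden([1, 2, 3, 4], [0, 1, 0, 1])
        assert r.youden_threshold == 4.0

    def test_single_class_raises(self):
        with pytest.raises(ValueError):
            roc_auc_youden([1, 2, 3], [1, 1, 1])


class TestBlandAltman:
    def test_identical_measurements(self):
        r = bland_altman([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert (r.mean_diff, r.sd_diff, r.loa_low, r.loa_high, r.n_outside) == \
            (0.0, 0.0, 0.0, 0.0, 0)

    def test_constant_offset(self):
        r = bland_altman([1.0, 2.0, 3.0], [3.0, 4.0, 5.0])
        assert r.mean_diff == -2.0
        assert r.sd_diff == 0.0

    def test_hand_computed_limits(self):
        r = bland_altman([1, 2, 3, 4], [1, 1, 1, 1])
        assert r.mean_diff == pytest.approx(1.5)
        assert r.sd_diff == pytest.approx(1.2909944487)
        assert r.loa_low == pytest.approx(-1.0303491195)
        assert r.loa_high == pytest.approx(4.0303491195)
        assert r.n_outside == 0

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError):
            bland_altman([1, 2], [1, 2, 3])
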