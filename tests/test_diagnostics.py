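"""ROC construction, AUC and its CI, Youden cutoffs, and comparison tests."""
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps
from sklearn.metrics import roc_auc_score

from metsdx.diagnostics import (auc, auc_confidence_interval, fisher_exact,
                                likelihood_ratios, p_bin,
                                pearson_with_strength, roc_analyze,
                                roc_points, strength_of, trapezoid_auc,
                                unpaired_t_test, youden_cutoff)


def _instance(rng, n_max=30):
    n = int(rng.integers(4, n_max + 1))
    scores = np.round(rng.normal(size=n), 1)  # rounding forces ties
    labels = rng.random(n) < 0.5
    if labels.all():
        labels[0] = False
    if not labels.any():
        labels[0] = True
    return scores, labels


class TestRocPoints:
    def test_perfect_separation(self):
        pts = roc_points([1, 2, 3, 4], [False, False, True, True])
        row = pts[pts[:, 0] == 3][0]
        assert row[1] == 100.0 and row[2] == 100.0

    def test_all_scores_equal(self):
        pts = roc_points([5, 5, 5, 5], [True, False, True, False])
        pairs = {(s, sp) for _, s, sp in pts}
        assert pairs == {(0.0, 100.0), (100.0, 0.0)}

    def test_tied_scores_hand_count(self):
        pts = roc_points([1, 2, 2, 3], [False, True, False, True])
        row = pts[pts[:, 0] == 2][0]
        assert row[1] == 100.0 and row[2] == 50.0

    def test_descending_thresholds_with_sentinels(self):
        pts = roc_points([1, 2, 3], [False, True, True])
        assert pts[0, 0] == np.inf and pts[-1, 0] == -np.inf
        assert np.all(np.diff(pts[:, 0]) < 0)

    def test_degenerate_labels_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            roc_points([1, 2], [True, True])


class TestAuc:
    def test_perfect(self):
        assert auc([1, 2, 3, 4], [False, False, True, True]) == 1.0

    def test_tied_pairs(self):
        # brute force over the 4 (pos, neg) pairs: 3.5 / 4
        assert auc([1, 2, 2, 3], [False, True, False, True]) == pytest.approx(0.875)

    def test_matches_sklearn(self):
        rng = np.random.default_rng(5)
        for _ in range(200):
            scores, labels = _instance(rng)
            assert auc(scores, labels) == pytest.approx(
                roc_auc_score(labels, scores), abs=1e-12)

    def test_trapezoid_equivalence(self):
        rng = np.random.default_rng(6)
        for _ in range(300):
            scores, labels = _instance(rng)
            assert abs(auc(scores, labels)
                       - trapezoid_auc(roc_points(scores, labels))) < 1e-12

    @settings(max_examples=100, deadline=None)
    @given(st.data())
    def test_invariant_under_monotone_transform(self, data):
        n = data.draw(st.integers(4, 15))
        # scores on a 0.001 grid: distinct values survive the transforms
        scores = np.array(data.draw(st.lists(
            st.integers(-5000, 5000), min_size=n, max_size=n))) / 1000.0
        labels = np.array(data.draw(st.lists(st.booleans(), min_size=n,
                                             max_size=n)))
        if labels.all() or not labels.any():
            labels[0] = not labels[0]
        base = auc(scores, labels)
        assert auc(np.exp(scores / 2), labels) == pytest.approx(base, abs=1e-12)
        assert auc(3 * scores + 7, labels) == pytest.approx(base, abs=1e-12)


class TestYouden:
    def test_perfect_separation(self):
        cutoff, sens, spec, j = youden_cutoff(
            roc_points([1, 2, 3, 4], [False, False, True, True]))
        assert cutoff == 3.0 and j == pytest.approx(1.0)

    def test_tied_j_prefers_higher_specificity(self):
        # J = 0.5 at thresholds 2 (100/50) and 3 (50/100); the screening
        # tie-break picks the higher-specificity operating point
        cutoff, sens, spec, j = youden_cutoff(
            roc_points([1, 2, 2, 3], [False, True, False, True]))
        assert j == pytest.approx(0.5)
        assert spec == 100.0 and cutoff == 3.0

    def test_uninformative_score(self):
        _, _, _, j = youden_cutoff(roc_points([5, 5, 5, 5],
                                              [True, False, True, False]))
        assert j == pytest.approx(0.0)

    def test_matches_exhaustive_search(self):
        rng = np.random.default_rng(7)
        for _ in range(200):
            scores, labels = _instance(rng)
            pts = roc_points(scores, labels)
            got = youden_cutoff(pts)
            best = max(((r[1] / 100 + r[2] / 100 - 1, r[2], r[0]) for r in pts))
            assert got[0] == best[2]
            assert got[3] == pytest.approx(best[0], abs=1e-12)


class TestLikelihoodRatios:
    @pytest.mark.parametrize("sens, spec, lr_expected", [
        (63.06, 86.55, 4.69),
        (30.31, 74.48, 1.19),
        (67.59, 81.55, 3.66),
    ])
    def test_reported_pairs(self, sens, spec, lr_expected):
        lr_pos, _ = likelihood_ratios(sens, spec)
        assert round(lr_pos, 2) == lr_expected

    def test_perfect_test(self):
        lr_pos, lr_neg = likelihood_ratios(100.0, 100.0)
        assert lr_pos == math.inf and lr_neg == 0.0

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            likelihood_ratios(120.0, 50.0)


class TestConfidenceInterval:
    def test_deterministic(self):
        rng = np.random.default_rng(8)
        scores, labels = rng.normal(size=60), rng.random(60) < 0.5
        a = auc_confidence_interval(scores, labels)
        b = auc_confidence_interval(scores, labels)
        assert a == b

    def test_contains_auc_and_clamped(self):
        rng = np.random.default_rng(9)
        scores = np.concatenate([rng.normal(2, 0.2, 40), rng.normal(0, 0.2, 40)])
        labels = np.concatenate([np.ones(40, bool), np.zeros(40, bool)])
        lo, hi = auc_confidence_interval(scores, labels)
        a = auc(scores, labels)
        assert 0.0 <= lo <= a <= hi <= 1.0

    def test_collapses_for_wide_margin_separation(self):
        n = 400
        scores = np.concatenate([np.linspace(10, 11, n), np.linspace(0, 1, n)])
        labels = np.concatenate([np.ones(n, bool), np.zeros(n, bool)])
        lo, hi = auc_confidence_interval(scores, labels)
        assert lo == pytest.approx(1.0) and hi == 1.0

    def test_bootstrap_seeded_and_agrees_roughly(self):
        rng = np.random.default_rng(10)
        scores = np.concatenate([rng.normal(1, 1, 80), rng.normal(0, 1, 80)])
        labels = np.concatenate([np.ones(80, bool), np.zeros(80, bool)])
        b1 = auc_confidence_interval(scores, labels, method="bootstrap",
                                     n_boot=500, seed=1)
        b2 = auc_confidence_interval(scores, labels, method="bootstrap",
                                     n_boot=500, seed=1)
        assert b1 == b2
        d = auc_confidence_interval(scores, labels, method="delong")
        assert b1[0] == pytest.approx(d[0], abs=0.05)
        assert b1[1] == pytest.approx(d[1], abs=0.05)

    def test_small_class_rejected(self):
        with pytest.raises(ValueError):
            auc_confidence_interval([1, 2, 3], [True, False, False])


class TestTTest:
    def test_identical_groups(self):
        t, p = unpaired_t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == 0.0 and p == pytest.approx(1.0)

    def test_matches_textbook_pooled_formula(self):
        a = np.array([1.1, 2.3, 3.0])
        b = np.array([2.0, 2.8, 4.1])
        t, p = unpaired_t_test(a, b)
        sp2 = ((a.var(ddof=1) * 2 + b.var(ddof=1) * 2) / 4)
        t_hand = (a.mean() - b.mean()) / math.sqrt(sp2 * (1 / 3 + 1 / 3))
        p_hand = 2 * sps.t.sf(abs(t_hand), 4)
        assert t == pytest.approx(t_hand, abs=1e-9)
        assert p == pytest.approx(p_hand, abs=1e-9)

    def test_shift_increases_statistic(self):
        a = [1.0, 2.0, 3.0, 4.0]
        b = [1.5, 2.5, 3.5, 4.5]
        t1, _ = unpaired_t_test(a, b)
        t2, _ = unpaired_t_test(a, [x + 1.0 for x in b])
        assert abs(t2) > abs(t1)

    def test_welch_differs_under_unequal_variance(self):
        a = [0.0, 0.1, -0.1, 0.05, -0.05]
        b = [1.0, 5.0, -3.0, 7.0, -4.0]
        _, p_pooled = unpaired_t_test(a, b, welch=False)
        _, p_welch = unpaired_t_test(a, b, welch=True)
        assert p_pooled != p_welch


class TestFisher:
    def test_strong_association(self):
        assert fisher_exact([[161, 61], [1030, 660]]) < 0.001

    def test_no_association(self):
        assert fisher_exact([[5, 5], [5, 5]]) == pytest.approx(1.0)

    def test_matches_scipy(self):
        rng = np.random.default_rng(11)
        for _ in range(200):
            table = rng.integers(1, 15, size=(2, 2))
            ours = fisher_exact(table)
            theirs = sps.fisher_exact(table)[1]
            assert ours == pytest.approx(theirs, rel=1e-6)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError, match="margin"):
            fisher_exact([[0, 0], [3, 4]])


class TestPearson:
    def test_affine_relationship(self):
        x = np.arange(10.0)
        res = pearson_with_strength(x, 2 * x + 1)
        assert res.r == pytest.approx(1.0)
        assert res.strength == "very strong"

    def test_independent_is_negligible(self):
        rng = np.random.default_rng(12)
        res = pearson_with_strength(rng.normal(size=5000), rng.normal(size=5000))
        assert abs(res.r) < 0.1 and res.strength == "negligible"

    def test_r_squared_identity(self):
        rng = np.random.default_rng(13)
        x = rng.normal(size=50)
        res = pearson_with_strength(x, x + rng.normal(size=50))
        assert res.r_squared == pytest.approx(res.r**2, abs=1e-12)

    @pytest.mark.parametrize("r, band", [
        (0.05, "negligible"), (-0.05, "negligible"),
        (0.10, "weak"), (0.39, "weak"),
        (0.40, "moderate"), (-0.69, "moderate"),
        (0.70, "strong"), (0.89, "strong"),
        (0.90, "very strong"), (-0.95, "very strong"),
    ])
    def test_strength_band_boundaries(self, r, band):
        assert strength_of(r) == band

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            pearson_with_strength([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestRocAnalyze:
    def test_result_identities(self):
        rng = np.random.default_rng(14)
        scores = np.concatenate([rng.normal(1, 1, 50), rng.normal(0, 1, 50)])
        labels = np.concatenate([np.ones(50, bool), np.zeros(50, bool)])
        res = roc_analyze(scores, labels)
        assert res.ci_low <= res.auc <= res.ci_high
        assert res.youden_j == pytest.approx(
            res.sensitivity_at_cutoff / 100 + res.specificity_at_cutoff / 100 - 1)
        if res.specificity_at_cutoff < 100:
            assert res.lr_pos == pytest.approx(
                res.sensitivity_at_cutoff / (100 - res.specificity_at_cutoff))
        assert res.n_pos == 50 and res.n_neg == 50


def test_p_bins():
    assert p_bin(0.2) == "ns"
    assert p_bin(0.04) == "<0.05"
    assert p_bin(0.005) == "<0.01"
    assert p_bin(0.0005) == "<0.001"
    assert p_bin(1e-6) == "<0.0001"
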