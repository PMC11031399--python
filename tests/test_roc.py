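import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from triagekit import (Orientation, auc_mw, binormal_scores, delong_paired,
                       fit_logistic_score, roc_points)
from conftest import brute_force_auc, delong_components_oracle


class TestAucMW:
    def test_perfect_separation(self):
        scores = np.array([0.0, 1.0, 2.0, 10.0, 11.0, 12.0])
        labels = np.array([0, 0, 0, 1, 1, 1])
        assert auc_mw(scores, labels).auc == 1.0

    def test_all_ties_give_half(self):
        scores = np.ones(10)
        labels = np.array([0, 1] * 5)
        assert auc_mw(scores, labels).auc == 0.5

    def test_four_subject_example(self):
        # positives {3, 1}, negatives {2, 0}: 3 of 4 pairs won
        scores = np.array([3.0, 1.0, 2.0, 0.0])
        labels = np.array([1, 1, 0, 0])
        assert auc_mw(scores, labels).auc == pytest.approx(0.75)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            auc_mw(np.array([1.0, 2.0]), np.array([1, 1]))

    @given(st.integers(0, 2**31 - 1))
    @settings(deadline=None, max_examples=40, derandomize=True)
    def test_matches_pair_counting_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(4, 13)
        scores = rng.integers(0, 6, size=n).astype(float)  # ties likely
        labels = np.zeros(n, int)
        labels[rng.choice(n, size=rng.integers(1, n), replace=False)] = 1
        if labels.min() == labels.max():
            return
        assert auc_mw(scores, labels).auc == pytest.approx(
            brute_force_auc(scores, labels), abs=1e-12)

    @given(st.integers(0, 2**31 - 1))
    @settings(deadline=None, max_examples=25, derandomize=True)
    def test_orientation_complement_is_exact(self, seed):
        rng = np.random.default_rng(seed)
        scores = rng.integers(0, 8, size=20).astype(float)
        labels = (rng.random(20) < 0.5).astype(int)
        if labels.min() == labels.max():
            return
        a = auc_mw(scores, labels, Orientation.HIGHER_IS_POSITIVE).auc
        b = auc_mw(scores, labels, Orientation.LOWER_IS_POSITIVE).auc
        assert a + b == pytest.approx(1.0, abs=1e-12)

    def test_invariant_under_increasing_transform(self):
        s, y = binormal_scores(80, 60, 1.2, seed=5)
        assert auc_mw(np.exp(s), y).auc == pytest.approx(auc_mw(s, y).auc, abs=1e-12)

    def test_ci_contains_point_and_is_truncated(self):
        s, y = binormal_scores(50, 50, 3.0, seed=6)
        r = auc_mw(s, y)
        assert 0 <= r.ci_low <= r.auc <= r.ci_high <= 1


class TestRocPoints:
    def test_threshold_count_with_sentinels(self):
        curve = roc_points(np.array([1.0, 1.0, 2.0, 2.0]), np.array([0, 1, 0, 1]))
        assert len(curve.thresholds) == 3  # 2 distinct scores + 1 midpoint + 2 sentinels... = 3
        assert curve.thresholds[0] == np.inf and curve.thresholds[-1] == -np.inf

    def test_endpoints(self):
        s, y = binormal_scores(30, 30, 1.0, seed=1)
        c = roc_points(s, y)
        assert (c.sensitivity[0], c.specificity[0]) == (0.0, 1.0)
        assert (c.sensitivity[-1], c.specificity[-1]) == (1.0, 0.0)
        assert (np.diff(c.sensitivity) >= 0).all()

    def test_trapezoid_area_equals_mw_auc(self):
        scores = np.array([3.0, 1.0, 2.0, 0.0])
        labels = np.array([1, 1, 0, 0])
        assert roc_points(scores, labels).auc() == pytest.approx(0.75, abs=1e-12)

    @given(st.integers(0, 2**31 - 1))
    @settings(deadline=None, max_examples=25, derandomize=True)
    def test_trapezoid_equals_mw_with_ties(self, seed):
        rng = np.random.default_rng(seed)
        scores = rng.integers(0, 5, size=30).astype(float)
        labels = (rng.random(30) < 0.4).astype(int)
        if labels.min() == labels.max():
            return
        assert roc_points(scores, labels).auc() == pytest.approx(
            auc_mw(scores, labels).auc, abs=1e-12)

    def test_flipped_orientation_reflects_curve(self):
        scores = np.array([3.0, 1.0, 2.0, 0.0])
        labels = np.array([1, 1, 0, 0])
        area = roc_points(scores, labels, Orientation.LOWER_IS_POSITIVE).auc()
        assert area == pytest.approx(0.25, abs=1e-12)


class TestDeLong:
    def test_variance_matches_placement_oracle(self):
        rng = np.random.default_rng(12)
        for _ in range(30):
            n = rng.integers(6, 51)
            scores = rng.integers(0, 10, size=n).astype(float)
            labels = np.zeros(n, int)
            labels[rng.choice(n, size=rng.integers(2, n - 1), replace=False)] = 1
            if labels.min() == labels.max():
                continue
            res = auc_mw(scores, labels)
            auc_o, var_o, _, _ = delong_components_oracle(scores, labels)
            assert res.auc == pytest.approx(auc_o, abs=1e-12)
            assert res.variance == pytest.approx(var_o, abs=1e-10)

    def test_self_comparison_degenerate(self):
        s, y = binormal_scores(20, 20, 1.0, seed=3)
        cmp = delong_paired(s, s, y)
        assert cmp.difference == 0.0
        assert (cmp.ci_low, cmp.ci_high) == (0.0, 0.0)
        assert np.isnan(cmp.p_value)

    def test_rank_invariance_gives_zero_difference(self):
        s, y = binormal_scores(25, 25, 1.5, seed=4)
        cmp = delong_paired(s, np.exp(s), y)
        assert cmp.difference == pytest.approx(0.0, abs=1e-12)

    def test_paired_variance_matches_brute_force(self):
        # hand-sized instance: full covariance of placement values
        rng = np.random.default_rng(8)
        y = np.array([1, 1, 1, 0, 0, 0, 0, 1])
        a = rng.normal(size=8) + y
        b = 0.5 * a + rng.normal(size=8)
        cmp = delong_paired(a, b, y)
        _, _, v10a, v01a = delong_components_oracle(a, y)
        _, _, v10b, v01b = delong_components_oracle(b, y)
        m, n = 4, 4
        var = (np.var(v10a, ddof=1) + np.var(v10b, ddof=1)
               - 2 * np.cov(v10a, v10b, ddof=1)[0, 1]) / m + \
              (np.var(v01a, ddof=1) + np.var(v01b, ddof=1)
               - 2 * np.cov(v01a, v01b, ddof=1)[0, 1]) / n
        assert cmp.variance == pytest.approx(var, abs=1e-10)

    def test_correlated_markers_tighter_than_independent(self):
        rng = np.random.default_rng(9)
        y = (rng.random(300) < 0.5).astype(int)
        a = y + rng.normal(size=300)
        b = a + 0.2 * rng.normal(size=300)  # strongly correlated
        c = y + rng.normal(size=300)        # independent noise
        assert delong_paired(a, b, y).variance < delong_paired(a, c, y).variance


def _irls_logistic(X, y, iters=100):
    """Independent Newton-Raphson oracle for the logistic MLE."""
    beta = np.zeros(X.shape[1])
    for _ in range(iters):
        eta = X @ beta
        p = 1 / (1 + np.exp(-eta))
        W = p * (1 - p)
        grad = X.T @ (y - p)
        hess = (X * W[:, None]).T @ X
        step = np.linalg.solve(hess, grad)
        beta = beta + step
        if np.abs(step).max() < 1e-12:
            break
    return beta


class TestLogisticScore:
    def test_coefficients_match_irls_oracle(self):
        x1 = np.array([0.2, 1.1, 0.7, 1.9, 2.5, 0.4, 1.5, 2.2])
        x2 = np.array([1.0, 0.3, 2.1, 0.8, 1.2, 1.7, 0.5, 1.1])
        y = np.array([0, 0, 1, 0, 1, 1, 1, 0])
        lp = fit_logistic_score(x1, x2, y)
        X = np.column_stack([np.ones(8), x1, x2])
        beta = _irls_logistic(X, y)
        np.testing.assert_allclose(lp, X @ beta, atol=1e-6)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            fit_logistic_score(np.arange(4.0), np.arange(4.0), np.ones(4))

    def test_perfect_separation_falls_back_with_warning(self):
        x1 = np.array([0.0, 1.0, 2.0, 10.0, 11.0, 12.0])
        y = np.array([0, 0, 0, 1, 1, 1])
        with pytest.warns(UserWarning, match="separation"):
            lp = fit_logistic_score(x1, x1 * 0.5, y)
        np.testing.assert_array_equal(lp, x1)

    def test_null_covariate_preserves_auc(self):
        rng = np.random.default_rng(15)
        n = 2000
        y = (rng.random(n) < 0.5).astype(int)
        primary = y * 1.5 + rng.normal(size=n)
        covariate = rng.normal(size=n)  # unrelated to outcome and primary
        lp = fit_logistic_score(primary, covariate, y)
        a0 = auc_mw(primary, y).auc
        a1 = auc_mw(lp, y).auc
        assert abs(a1 - a0) < 0.02
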