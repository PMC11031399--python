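import functools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from triagekit import (BootstrapConfig, CutoffSet, Orientation,
                       binormal_scores, derive_single_cutoff,
                       derive_two_cutoffs, inbag_estimates, oob_bootstrap,
                       paired_difference, stratified_resample,
                       transfer_evaluation, verdict_from_ci)

single_rule = functools.partial(derive_single_cutoff)
dual_rule = functools.partial(derive_two_cutoffs)
# on perfectly separable data a floor of 1.0 puts the unique optimum in the
# gap between classes, making the fitted rule a perfect classifier
gap_rule = functools.partial(derive_single_cutoff, spec_floor=1.0)


class TestStratifiedResample:
    def test_preserves_class_counts(self):
        y = np.r_[np.ones(10, int), np.zeros(20, int)]
        rng = np.random.default_rng(0)
        for _ in range(20):
            idx = stratified_resample(y, rng)
            assert (y[idx] == 1).sum() == 10 and (y[idx] == 0).sum() == 20

    def test_same_seed_same_indices(self):
        y = np.r_[np.ones(5, int), np.zeros(5, int)]
        a = stratified_resample(y, np.random.default_rng(3))
        b = stratified_resample(y, np.random.default_rng(3))
        np.testing.assert_array_equal(a, b)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            stratified_resample(np.ones(5, int), np.random.default_rng(0))


class TestVerdict:
    @given(st.floats(-1, 1, allow_nan=False), st.floats(0, 1, allow_nan=False))
    @settings(deadline=None, max_examples=100)
    def test_three_way_partition(self, lo, width):
        hi = lo + width
        v = verdict_from_ci(lo, hi)
        if lo > 0:
            assert v == "plasma_superior"
        elif hi < 0:
            assert v == "csf_favored"
        else:
            assert v == "equivalent"


class TestInbag:
    def test_perfect_classifier_degenerate_ci(self):
        scores = np.r_[np.arange(20.0), np.arange(30.0, 50.0)]
        y = np.r_[np.zeros(20, int), np.ones(20, int)]
        est = inbag_estimates(scores, y, gap_rule,
                              config=BootstrapConfig(n_resamples=50, seed=1))
        acc = est["accuracy"]
        assert (acc.point, acc.ci_low, acc.ci_high) == (1.0, 1.0, 1.0)

    def test_boot_mean_close_to_observed(self):
        scores, y = binormal_scores(500, 500, 2.3, seed=2)
        est = inbag_estimates(scores, y, single_rule,
                              config=BootstrapConfig(n_resamples=400, seed=3))
        for m in ("accuracy", "sensitivity", "specificity"):
            assert abs(est[m].point - est[m].observed) < 0.01

    def test_ci_width_shrinks_with_n(self):
        def width(n, seed):
            scores, y = binormal_scores(n // 2, n // 2, 2.3, seed=seed)
            est = inbag_estimates(scores, y, single_rule,
                                  config=BootstrapConfig(n_resamples=400, seed=7))
            return est["accuracy"].ci_high - est["accuracy"].ci_low

        ratio = width(200, 11) / width(800, 12)
        assert 1.4 < ratio < 2.8  # about sqrt(4) = 2

    def test_specificity_constraint_attained_on_average(self):
        # in-bag specificity estimate stays near the 90% floor
        scores, y = binormal_scores(400, 400, 2.3, seed=5)
        est = inbag_estimates(scores, y, single_rule,
                              config=BootstrapConfig(n_resamples=300, seed=6))
        assert est["specificity"].point >= 0.90 - 2 * 0.015


class TestPairedDifference:
    def test_self_comparison_all_zero(self):
        scores, y = binormal_scores(100, 100, 2.0, seed=4)
        verdicts, _ = paired_difference(scores, scores, y, single_rule,
                                        single_rule,
                                        config=BootstrapConfig(100, seed=5))
        for v in verdicts:
            assert v.difference.point == 0.0
            assert (v.difference.ci_low, v.difference.ci_high) == (0.0, 0.0)
            assert v.verdict == "equivalent"

    def test_stronger_marker_judged_superior(self):
        rng = np.random.default_rng(6)
        n = 1000
        y = np.r_[np.zeros(n // 2, int), np.ones(n // 2, int)]
        strong = 2.5 * y + rng.normal(size=n)
        weak = 1.0 * y + rng.normal(size=n)
        verdicts, _ = paired_difference(strong, weak, y, single_rule, single_rule,
                                        config=BootstrapConfig(300, seed=7))
        by_metric = {v.metric: v for v in verdicts}
        assert by_metric["accuracy"].verdict == "plasma_superior"

    def test_intermediate_fraction_difference_oriented_for_plasma(self):
        # plasma has the narrower intermediate zone, so csf - plasma > 0
        rng = np.random.default_rng(8)
        n = 800
        y = np.r_[np.zeros(n // 2, int), np.ones(n // 2, int)]
        plasma = 3.0 * y + rng.normal(size=n)
        csf = 1.2 * y + rng.normal(size=n)
        verdicts, est = paired_difference(plasma, csf, y, dual_rule, dual_rule,
                                          config=BootstrapConfig(300, seed=9))
        v = {x.metric: x for x in verdicts}["intermediate_fraction"]
        assert v.difference.observed == pytest.approx(
            est["csf"]["intermediate_fraction"].observed
            - est["plasma"]["intermediate_fraction"].observed)
        assert v.difference.point > 0
        assert v.verdict == "plasma_superior"

    def test_missing_values_rejected(self):
        scores, y = binormal_scores(10, 10, 1.0, seed=1)
        bad = scores.copy()
        bad[0] = np.nan
        with pytest.raises(ValueError, match="complete-case"):
            paired_difference(scores, bad, y, single_rule, single_rule)


class TestOob:
    def test_oob_fraction_near_e_inverse(self):
        scores, y = binormal_scores(300, 300, 2.0, seed=10)
        _, info = oob_bootstrap(scores, y, single_rule,
                                config=BootstrapConfig(n_resamples=200, seed=11))
        assert abs(info["oob_fraction"] - np.exp(-1)) < 0.01

    def test_perfect_separation_oob_accuracy_one(self):
        scores = np.r_[np.arange(30.0), np.arange(50.0, 80.0)]
        y = np.r_[np.zeros(30, int), np.ones(30, int)]
        est, _ = oob_bootstrap(scores, y, gap_rule,
                               config=BootstrapConfig(n_resamples=50, seed=12))
        assert est["accuracy"].point == 1.0

    def test_oob_not_better_than_inbag_on_average(self):
        scores, y = binormal_scores(150, 150, 1.5, seed=13)
        cfg = BootstrapConfig(n_resamples=200, seed=14)
        inbag = inbag_estimates(scores, y, single_rule, config=cfg)
        oob, _ = oob_bootstrap(scores, y, single_rule, config=cfg)
        assert oob["accuracy"].point <= inbag["accuracy"].point + 0.01


class TestTransfer:
    def test_identity_transfer_matches_inbag_observed(self):
        scores, y = binormal_scores(200, 200, 2.0, seed=15)
        cut = derive_single_cutoff(scores, y)
        cfg = BootstrapConfig(n_resamples=100, seed=16)
        est = transfer_evaluation(cut, scores, y, config=cfg)
        inbag = inbag_estimates(scores, y, single_rule, config=cfg)
        for m in ("accuracy", "sensitivity", "specificity"):
            assert est[m].observed == inbag[m].observed

    def test_same_distribution_transfer_within_ci(self):
        s1, y1 = binormal_scores(400, 400, 2.0, seed=17)
        s2, y2 = binormal_scores(400, 400, 2.0, seed=18)
        cut = derive_single_cutoff(s1, y1)
        est = transfer_evaluation(cut, s2, y2,
                                  config=BootstrapConfig(300, seed=19))
        acc = est["accuracy"]
        assert acc.ci_low - 0.02 < acc.observed < acc.ci_high + 0.02

    def test_scale_shift_degrades_specificity(self):
        s1, y1 = binormal_scores(400, 400, 2.0, seed=20)
        cut = derive_single_cutoff(s1, y1)
        shifted = 2.0 * s1 + 1.0  # assay recalibration without cutoff transfer
        est = transfer_evaluation(cut, shifted, y1,
                                  config=BootstrapConfig(100, seed=21))
        assert est["specificity"].observed < cut.achieved_inbag["specificity"] - 0.05
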