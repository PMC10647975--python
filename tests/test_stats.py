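"""Biomarker statistics: repeatability, group comparison, ROC, correlation."""

import itertools

import numpy as np
import pytest
from sklearn.metrics import roc_auc_score

from hepamap import (bootstrap_validate, coefficient_of_variation,
                     correlation_strength, dice_similarity, fisher_z_average,
                     mann_whitney_u, percent_difference, roc_analysis,
                     roc_auc, session_cv, voxelwise_pearson,
                     within_subject_cv)


class TestPercentDifference:
    def test_equal_is_zero(self):
        assert percent_difference(1.0, 1.0) == 0.0

    def test_hand_value(self):
        np.testing.assert_allclose(percent_difference(1.077, 1.000), 7.7)

    def test_sign_convention_and_absolute(self):
        assert percent_difference(0.9, 1.0) == pytest.approx(-10.0)
        assert percent_difference(0.9, 1.0, absolute=True) == \
            pytest.approx(10.0)

    def test_zero_reference_rejected(self):
        with pytest.raises(ValueError):
            percent_difference(1.0, 0.0)


class TestCoefficientOfVariation:
    def test_constant_is_zero(self):
        assert coefficient_of_variation([5.0, 5.0, 5.0]) == 0.0

    def test_hand_value_sample_sd(self):
        np.testing.assert_allclose(coefficient_of_variation([9.0, 11.0]),
                                   100 * np.sqrt(2) / 10)

    def test_session_decomposition_matches_groupby_oracle(self, rng):
        table = rng.uniform(8, 12, size=(3, 4))  # 3 sessions x 4 repeats
        intra, inter = session_cv(table)
        oracle_intra = np.mean([100 * s.std(ddof=1) / s.mean()
                                for s in table])
        means = table.mean(axis=1)
        oracle_inter = 100 * means.std(ddof=1) / means.mean()
        np.testing.assert_allclose(intra, oracle_intra)
        np.testing.assert_allclose(inter, oracle_inter)

    def test_zero_mean_rejected(self):
        with pytest.raises(ValueError):
            coefficient_of_variation([-1.0, 1.0])


class TestWithinSubjectCv:
    def test_identical_pair_zero(self):
        per, summ = within_subject_cv([(5.0, 5.0)])
        assert per[0] == 0.0 and summ["mean"] == 0.0

    def test_hand_value(self):
        per, _ = within_subject_cv({"s1": (8.0, 12.0)})
        np.testing.assert_allclose(per["s1"], 100 * 2 * np.sqrt(2) / 10)

    def test_recovers_generative_cv(self, rng):
        # scan/rescan values with 10% within-subject CV; E[wCV] ~ 10% * c4
        true_cv = 0.10
        n = 400
        base = rng.uniform(50, 150, n)
        pairs = [(b * (1 + true_cv * rng.standard_normal()),
                  b * (1 + true_cv * rng.standard_normal())) for b in base]
        _, summ = within_subject_cv(pairs)
        # sample SD of 2 values underestimates sigma by sqrt(2/pi)
        expected = 100 * true_cv * np.sqrt(2 / np.pi)
        assert abs(summ["mean"] - expected) < 0.15 * expected

    def test_missing_rescan_rejected(self):
        with pytest.raises(ValueError):
            within_subject_cv({"s1": (np.nan, 5.0)})


class TestMannWhitney:
    def test_toy_exact_p(self):
        res = mann_whitney_u([1.0, 2.0], [3.0, 4.0])
        assert res.u_statistic == 0.0
        np.testing.assert_allclose(res.p_value, 1.0 / 3.0)
        assert res.method == "exact"

    def test_identical_groups_p_one(self):
        res = mann_whitney_u([1, 2, 3, 4, 5], [1, 2, 3, 4, 5])
        assert res.p_value > 0.99

    def test_exact_matches_enumeration_all_splits_n8(self):
        # full enumeration oracle over all two-group splits of 8 values
        values = np.array([3.1, 1.2, 4.8, 2.4, 9.6, 5.5, 7.3, 0.4])
        idx = set(range(8))
        for k in range(1, 8):
            for comb in itertools.combinations(range(8), k):
                a = values[list(comb)]
                b = values[list(idx - set(comb))]
                res = mann_whitney_u(a, b)
                # brute force: distribution of U over all C(8, k) splits
                u_obs = res.u_statistic
                us = []
                for c2 in itertools.combinations(range(8), k):
                    ranks = np.argsort(np.argsort(values)) + 1
                    r_a = ranks[list(c2)].sum()
                    us.append(r_a - k * (k + 1) / 2)
                us = np.array(us)
                u_other = k * (8 - k) - u_obs
                p_oracle = np.mean(us <= min(u_obs, u_other)) \
                    + np.mean(us >= max(u_obs, u_other))
                np.testing.assert_allclose(res.p_value, min(1.0, p_oracle),
                                           atol=1e-12)

    def test_large_shift_detected(self, rng):
        detected = 0
        for k in range(50):
            a = rng.normal(0, 1, 10)
            b = rng.normal(4, 1, 12)
            if mann_whitney_u(a, b).p_value < 0.001:
                detected += 1
        assert detected >= 48

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1.0])


class TestRoc:
    def test_perfect_separation(self):
        res = roc_analysis([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1])
        assert res.auc == 1.0
        assert res.sensitivity == 1.0 and res.specificity == 1.0
        assert 3 < res.optimal_cutoff < 10

    def test_uninformative_scores(self):
        assert roc_auc([5, 5, 5, 5], [0, 0, 1, 1]) == 0.5

    def test_matches_pairwise_counting_oracle(self, rng):
        for _ in range(20):
            n = rng.integers(6, 50)
            scores = rng.normal(size=n).round(1)  # induce some ties
            labels = rng.integers(0, 2, n)
            if labels.sum() in (0, n):
                continue
            pos = scores[labels == 1]
            neg = scores[labels == 0]
            pairs = (pos[:, None] > neg[None, :]).sum() \
                + 0.5 * (pos[:, None] == neg[None, :]).sum()
            oracle = pairs / (len(pos) * len(neg))
            np.testing.assert_allclose(roc_auc(scores, labels), oracle)
            # cross-check against the reference implementation
            np.testing.assert_allclose(roc_auc(scores, labels),
                                       roc_auc_score(labels, scores))

    def test_direction_auto_flip(self):
        # lower scores indicate disease
        res = roc_analysis([10, 11, 12, 1, 2, 3], [0, 0, 0, 1, 1, 1])
        assert res.direction == "lower"
        assert res.auc == 1.0

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_analysis([1, 2, 3], [1, 1, 1])


class TestBootstrap:
    def test_perfect_separation_degenerate_ci(self):
        scores = [1, 2, 3, 10, 11, 12]
        labels = [0, 0, 0, 1, 1, 1]
        lo, hi, info = bootstrap_validate(scores, labels, "auc",
                                         n_samples=200, seed=1)
        assert lo == hi == 1.0
        assert info["n_samples"] == 200

    def test_seeded_determinism(self, rng):
        scores = rng.normal(size=22)
        labels = np.r_[np.zeros(10, int), np.ones(12, int)]
        a = bootstrap_validate(scores, labels, "auc", 300, seed=5)
        b = bootstrap_validate(scores, labels, "auc", 300, seed=5)
        assert a[:2] == b[:2]

    def test_cutoff_statistic_supported(self, rng):
        scores = rng.normal(size=22)
        labels = np.r_[np.zeros(10, int), np.ones(12, int)]
        lo, hi, _ = bootstrap_validate(scores, labels, "cutoff", 100, seed=2)
        assert lo <= hi

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            bootstrap_validate([1, 2], [0, 1], n_samples=10)
        with pytest.raises(ValueError):
            bootstrap_validate([1, 2], [0, 1], level=40.0)


class TestPearsonAndFisher:
    def test_self_correlation(self, rng):
        m = rng.random((5, 5))
        roi = np.ones((5, 5), bool)
        assert voxelwise_pearson(m, m, roi)["r"] == pytest.approx(1.0)

    def test_anticorrelation(self, rng):
        m = rng.random((5, 5))
        res = voxelwise_pearson(m, -m + 3.0, np.ones((5, 5), bool))
        assert res["r"] == pytest.approx(-1.0)

    def test_definitional_oracle_10_voxels(self, rng):
        a = rng.random(10)
        b = rng.random(10)
        res = voxelwise_pearson(a.reshape(2, 5), b.reshape(2, 5),
                                np.ones((2, 5), bool))
        cov = np.mean((a - a.mean()) * (b - b.mean()))
        oracle = cov / (a.std() * b.std())
        np.testing.assert_allclose(res["r"], oracle, rtol=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            voxelwise_pearson(np.ones((2, 3)), np.random.rand(2, 3),
                              np.ones((2, 3), bool))

    def test_strength_bands(self):
        assert correlation_strength(0.05) == "negligible"
        assert correlation_strength(-0.2) == "small"
        assert correlation_strength(0.4) == "medium"
        assert correlation_strength(-0.9) == "large"

    def test_fisher_idempotent(self):
        r_bar, _ = fisher_z_average([0.5, 0.5])
        assert r_bar == pytest.approx(0.5)

    def test_fisher_hand_value(self):
        r_bar, z_bar = fisher_z_average([0.2, 0.6])
        expected = np.tanh((np.arctanh(0.2) + np.arctanh(0.6)) / 2)
        np.testing.assert_allclose(r_bar, expected)
        np.testing.assert_allclose(r_bar, 0.420, atol=5e-4)

    def test_fisher_antisymmetry(self):
        r_bar, _ = fisher_z_average([0.7, -0.7])
        assert r_bar == pytest.approx(0.0)

    def test_fisher_bounded_by_extremes(self, rng):
        for _ in range(20):
            r = rng.uniform(-0.95, 0.95, rng.integers(2, 10))
            r_bar, _ = fisher_z_average(r)
            assert r.min() - 1e-12 <= r_bar <= r.max() + 1e-12

    def test_degenerate_r_rejected(self):
        with pytest.raises(ValueError):
            fisher_z_average([0.5, 1.0])


class TestDice:
    def test_identical_masks(self):
        m = np.zeros((4, 4), bool)
        m[:2] = True
        assert dice_similarity(m, m) == 1.0

    def test_disjoint_masks(self):
        a = np.zeros((4, 4), bool)
        b = np.zeros((4, 4), bool)
        a[0], b[3] = True, True
        assert dice_similarity(a, b) == 0.0

    def test_hand_value_60_of_100(self):
        a = np.zeros(200, bool)
        b = np.zeros(200, bool)
        a[:100] = True
        b[40:140] = True  # overlap 60
        assert dice_similarity(a, b) == pytest.approx(0.6)

    def test_both_empty_convention(self):
        assert dice_similarity(np.zeros((3, 3), bool),
                               np.zeros((3, 3), bool)) == 1.0

    def test_grid_mismatch_rejected(self):
        with pytest.raises(ValueError):
            dice_similarity(np.zeros((2, 2), bool), np.zeros((3, 3), bool))
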