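"""Discrimination and reclassification metrics: DeLong AUC, paired AUC
comparison, IDI, categorical and category-free NRI, and stratified CV."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from depgrs.calibration import replicate_data
from depgrs.metrics import (
    bootstrap_reclass_ci,
    categorical_nri,
    category_free_nri,
    compare_auc,
    evaluate_model_suite,
    idi,
    kfold_cv,
    roc_auc,
)


class TestRocAuc:
    def test_perfect_separation(self):
        auc, _ = roc_auc([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0])
        assert auc == 1.0

    def test_all_ties(self):
        auc, _ = roc_auc([0.5] * 6, [1, 1, 0, 0, 0, 0])
        assert auc == 0.5

    def test_three_of_four_concordant(self):
        auc, _ = roc_auc([0.9, 0.4, 0.5, 0.1], [1, 1, 0, 0])
        assert auc == 0.75

    def test_single_class_error(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.2], [1, 1])

    @given(st.integers(5, 200), st.integers(0, 10_000))
    @settings(max_examples=100, deadline=None)
    def test_equals_mann_whitney_u(self, n, seed):
        """AUC equals U / (n1 * n0) with ties counted one half."""
        rng = np.random.default_rng(seed)
        labels = rng.integers(0, 2, size=n)
        if labels.sum() in (0, n):
            labels[0], labels[1] = 0, 1
        scores = rng.choice(np.linspace(0, 1, 7), size=n)  # forces ties
        auc, _ = roc_auc(scores, labels)
        u = stats.mannwhitneyu(scores[labels == 1], scores[labels == 0],
                               alternative="two-sided").statistic
        n1, n0 = labels.sum(), (1 - labels).sum()
        assert auc == pytest.approx(u / (n1 * n0), abs=1e-12)

    def test_monotone_transform_invariance(self, rng):
        labels = rng.integers(0, 2, size=100)
        labels[:2] = [0, 1]
        scores = rng.normal(size=100)
        a1, _ = roc_auc(scores, labels)
        a2, _ = roc_auc(np.exp(3 * scores), labels)
        assert a1 == pytest.approx(a2, abs=1e-12)

    def test_ci_brackets_estimate(self, rng):
        labels = np.r_[np.ones(40), np.zeros(160)]
        scores = rng.normal(size=200) + 0.8 * labels
        auc, (lo, hi) = roc_auc(scores, labels)
        assert lo <= auc <= hi


class TestCompareAuc:
    def test_identical_scores(self):
        labels = np.r_[np.ones(20), np.zeros(80)]
        s = np.random.default_rng(0).normal(size=100)
        out = compare_auc(s, s, labels)
        assert out["delta_auc"] == 0.0 and out["p"] == 1.0

    def test_added_signal_detected(self, rng):
        labels = rng.integers(0, 2, size=2000)
        labels[:2] = [0, 1]
        old = rng.normal(size=2000)
        new = old + 1.5 * labels
        assert compare_auc(old, new, labels)["p"] < 0.01

    def test_mismatched_lengths(self):
        with pytest.raises(ValueError):
            compare_auc([0.1, 0.2], [0.1], [1, 0])

    def test_permutation_null_size(self, rng):
        """Rejection rate of the paired test is near 5% when the added
        score carries no signal."""
        rejections = 0
        n_reps = 400
        for _ in range(n_reps):
            labels = np.r_[np.ones(30), np.zeros(170)]
            old = rng.normal(size=200)
            new = old + 0.8 * rng.normal(size=200)  # noise, no signal
            if compare_auc(old, new, labels)["p"] < 0.05:
                rejections += 1
        assert rejections / n_reps == pytest.approx(0.05, abs=0.035)


class TestIdi:
    def test_no_change(self):
        p = np.array([0.1, 0.2, 0.3, 0.4])
        labels = np.array([1, 1, 0, 0])
        est, _, pval = idi(labels, p, p)
        assert est == 0.0 and pval == 1.0

    def test_hand_means(self):
        labels = np.array([1, 1, 0, 0])
        p_old = np.array([0.2, 0.4, 0.1, 0.3])
        p_new = np.array([0.3, 0.5, 0.05, 0.25])
        est, _, _ = idi(labels, p_old, p_new)
        assert est == pytest.approx(0.15)

    def test_label_swap_negates(self, rng):
        labels = rng.integers(0, 2, size=50)
        labels[:4] = [0, 0, 1, 1]
        p_old = rng.uniform(size=50)
        p_new = rng.uniform(size=50)
        est, _, _ = idi(labels, p_old, p_new)
        est_swapped, _, _ = idi(1 - labels, p_old, p_new)
        assert est_swapped == pytest.approx(-est)

    def test_discrimination_slope_equivalence(self, rng):
        """IDI equals the change in discrimination slope
        (mean case risk - mean control risk, new minus old)."""
        labels = rng.integers(0, 2, size=300)
        labels[:4] = [0, 0, 1, 1]
        p_old = rng.uniform(size=300)
        p_new = rng.uniform(size=300)
        est, _, _ = idi(labels, p_old, p_new)
        slope = lambda p: p[labels == 1].mean() - p[labels == 0].mean()  # noqa: E731
        assert est == pytest.approx(slope(p_new) - slope(p_old), abs=1e-12)

    def test_out_of_range_probability(self):
        with pytest.raises(ValueError):
            idi([1, 1, 0, 0], [0.1, 0.2, 0.3, 1.4], [0.1, 0.2, 0.3, 0.4])


class TestCategoricalNri:
    def test_both_components_perfect(self):
        labels = np.array([1, 0])
        est, _, _ = categorical_nri(labels, [0.20, 0.06], [0.30, 0.04])
        assert est == pytest.approx(2.0)

    def test_no_category_change(self):
        labels = np.array([1, 1, 0, 0])
        p = np.array([0.01, 0.1, 0.1, 0.5])
        est, _, pval = categorical_nri(labels, p, p + 0.001)
        assert est == 0.0

    def test_worst_case(self):
        labels = np.array([1, 0])
        est, _, _ = categorical_nri(labels, [0.30, 0.04], [0.20, 0.06])
        assert est == pytest.approx(-2.0)

    def test_boundary_membership(self):
        """0.05 belongs to the medium category, 0.25 to high."""
        from depgrs.metrics import risk_category

        assert list(risk_category(np.array([0.049, 0.05, 0.249, 0.25]))) == [
            0, 1, 1, 2,
        ]

    def test_invalid_cuts(self):
        with pytest.raises(ValueError):
            categorical_nri([1, 0], [0.1, 0.2], [0.2, 0.1], cuts=(0.25, 0.05))


class TestCategoryFreeNri:
    def test_no_movement(self):
        labels = np.array([1, 1, 0, 0])
        p = np.array([0.1, 0.2, 0.3, 0.4])
        est, _, _ = category_free_nri(labels, p, p)
        assert est == 0.0

    def test_hand_count(self):
        labels = np.array([1, 1, 0])
        p_old = np.array([0.2, 0.3, 0.1])
        p_new = np.array([0.25, 0.25, 0.2])
        est, _, _ = category_free_nri(labels, p_old, p_new)
        assert est == pytest.approx(-1.0)

    def test_maximum(self):
        labels = np.array([1, 1, 0, 0])
        est, _, _ = category_free_nri(
            labels, [0.2, 0.3, 0.4, 0.5], [0.3, 0.4, 0.3, 0.4]
        )
        assert est == pytest.approx(2.0)

    def test_fine_categorical_cuts_recover_category_free(self, rng):
        """With cuts between every pair of adjacent observed risks, the
        categorical NRI degenerates to the category-free NRI."""
        labels = rng.integers(0, 2, size=60)
        labels[:2] = [0, 1]
        p_old = rng.uniform(0.01, 0.99, size=60)
        p_new = rng.uniform(0.01, 0.99, size=60)
        grid = np.unique(np.r_[p_old, p_new])
        cuts = tuple((grid[:-1] + grid[1:]) / 2)
        cat, _, _ = categorical_nri(labels, p_old, p_new, cuts=cuts)
        free, _, _ = category_free_nri(labels, p_old, p_new)
        assert cat == pytest.approx(free, abs=1e-12)


class TestBootstrapCi:
    def test_brackets_estimate_and_matches_asymptotic_roughly(self, rng):
        labels = np.r_[np.ones(80), np.zeros(320)].astype(int)
        p_old = np.clip(rng.uniform(0.02, 0.4, size=400), 0, 1)
        p_new = np.clip(p_old + 0.1 * labels * rng.uniform(size=400)
                        - 0.02 * (1 - labels), 0, 1)
        est, (lo, hi) = bootstrap_reclass_ci(labels, p_old, p_new,
                                             statistic="idi", n_boot=300,
                                             seed=4)
        assert lo <= est <= hi
        asym_est, (alo, ahi), _ = idi(labels, p_old, p_new)
        assert est == pytest.approx(asym_est)
        # the two interval widths agree to within a factor of two
        assert 0.5 < (hi - lo) / (ahi - alo) < 2.0

    def test_same_seed_reproducible(self, rng):
        labels = np.r_[np.ones(20), np.zeros(80)].astype(int)
        p_old = rng.uniform(size=100)
        p_new = rng.uniform(size=100)
        a = bootstrap_reclass_ci(labels, p_old, p_new, "cfnri", 100, seed=3)
        b = bootstrap_reclass_ci(labels, p_old, p_new, "cfnri", 100, seed=3)
        assert a == b

    def test_unknown_statistic(self):
        with pytest.raises(ValueError):
            bootstrap_reclass_ci([1, 0], [0.1, 0.2], [0.2, 0.1], "auc")


class TestModelSuite:
    def test_no_interaction_ladder(self):
        """GRS effect, no BMI effect, no interaction: adding the GRS
        yields positive IDI while adding BMI alone does essentially
        nothing (replicate means)."""
        idi12, idi13 = [], []
        for seed in range(5):
            data = replicate_data(seed=seed, interaction_or=1.0)
            _, reports = evaluate_model_suite(data)
            by = {r.comparison: r for r in reports}
            idi12.append(by[(1, 2)].idi)
            idi13.append(by[(1, 3)].idi)
        assert abs(np.mean(idi12)) < 0.01
        assert np.mean(idi13) > 0.01

    def test_interaction_comparison_positive(self):
        data = replicate_data(seed=3, interaction_or=1.14)
        _, reports = evaluate_model_suite(data)
        by = {r.comparison: r for r in reports}
        assert by[(4, 5)].idi > 0

    def test_null_truth_centres_on_zero(self):
        ests = []
        for seed in range(5):
            data = replicate_data(seed=seed, or_per_allele=1.0,
                                  interaction_or=1.0)
            _, reports = evaluate_model_suite(data)
            ests.extend(r.idi for r in reports)
        assert np.mean(ests) == pytest.approx(0.0, abs=0.01)


class TestKfoldCv:
    def test_stratified_fold_case_counts(self):
        """104 cases split over 5 stratified folds gives 20 or 21 per fold."""
        data = replicate_data(seed=12)  # calibrated to ~104 cases
        rep = kfold_cv(data, k=5, seed=1)
        y = data["depression"]
        from sklearn.model_selection import StratifiedKFold

        skf = StratifiedKFold(n_splits=5, shuffle=True, random_state=1)
        counts = [int(y.iloc[test].sum()) for _, test in
                  skf.split(np.zeros(len(y)), y)]
        n_cases = int(y.sum())
        lo, hi = n_cases // 5, n_cases // 5 + (n_cases % 5 > 0)
        assert set(counts) <= {lo, hi}
        assert rep.fold_auc.shape == (5, 5)

    def test_same_seed_reproducible(self):
        data = replicate_data(seed=13)
        r1 = kfold_cv(data, k=5, seed=9)
        r2 = kfold_cv(data, k=5, seed=9)
        pd.testing.assert_frame_equal(r1.fold_auc, r2.fold_auc)
        pd.testing.assert_frame_equal(r1.mean_metrics, r2.mean_metrics)

    def test_k_exceeding_cases_error(self):
        data = replicate_data(seed=14, n_subjects=300)
        n_cases = int(data["depression"].sum())
        with pytest.raises(ValueError):
            kfold_cv(data, k=n_cases + 1, seed=1)

    def test_out_of_fold_auc_ordering(self):
        """Model 5 discriminates better than the demographics-only model
        out of sample when GRS and interaction effects are present."""
        data = replicate_data(seed=15, interaction_or=1.14)
        rep = kfold_cv(data, k=5, seed=2)
        assert rep.mean_auc[5] > rep.mean_auc[1]
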