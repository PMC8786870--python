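"""Regression layer: GLM fitting, FDR control, quartile contrasts,
interaction geometry, effect sizes and the power approximation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import logit

from depgrs.calibration import replicate_data
from depgrs.grs import assign_quartiles
from depgrs.models import (
    MODEL_TERMS,
    ModelSpec,
    PowerParams,
    bh_adjust,
    cohens_d_from_summary,
    cramers_v,
    fit_glm,
    fit_model_suite,
    grs_quartile_contrasts,
    group_compare,
    interaction_grid,
    interaction_model,
    logistic_power,
    univariate_snp_scan,
)
from depgrs.simulate import simulate_study


def bh_stepup_oracle(p):
    """Brute-force Benjamini-Hochberg step-up: adjusted p_(i) =
    min_{j>=i} ( m * p_(j) / j ), capped at 1."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p)
    adj_sorted = np.minimum.accumulate(
        (m * p[order] / np.arange(1, m + 1))[::-1]
    )[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj_sorted, 1.0)
    return out


class TestFitGlm:
    def test_intercept_only_closed_form(self):
        y = np.r_[np.ones(50), np.zeros(950)]
        data = pd.DataFrame({"depression": y})
        fit = fit_glm(data, ModelSpec("depression", ()))
        assert fit.params.loc["const", "beta"] == pytest.approx(
            float(logit(0.05)), abs=1e-6
        )

    def test_separation_flagged(self):
        data = pd.DataFrame({
            "depression": [0, 0, 0, 1, 1, 1],
            "grs": [1.0, 2.0, 3.0, 10.0, 11.0, 12.0],
        })
        fit = fit_glm(data, ModelSpec("depression", ("grs",)))
        assert fit.separation

    def test_non_binary_outcome_rejected(self):
        data = pd.DataFrame({"depression": [0, 1, 2], "grs": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError):
            fit_glm(data, ModelSpec("depression", ("grs",)))

    def test_interaction_requires_marginals(self):
        with pytest.raises(ValueError):
            ModelSpec("depression", ("grs", "grs:bmi"))

    def test_d_squared_nesting_never_decreases(self):
        data = replicate_data(seed=17, n_subjects=1200, n_snps=20)
        fits = fit_model_suite(data)
        d2 = {m: f.d_squared for m, f in fits.items()}
        assert 0.0 <= d2[1] <= 1.0
        for sub, sup in [(1, 2), (1, 3), (2, 4), (3, 4), (4, 5)]:
            assert d2[sup] >= d2[sub] - 1e-10

    def test_null_model_d_squared_zero(self):
        y = np.r_[np.ones(30), np.zeros(170)]
        fit = fit_glm(pd.DataFrame({"depression": y}), ModelSpec("depression", ()))
        assert fit.d_squared == pytest.approx(0.0, abs=1e-12)


class TestBenjaminiHochberg:
    def test_hand_example(self):
        adj = bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert adj == pytest.approx([0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert bh_adjust([0.037]) == pytest.approx([0.037])

    @given(st.lists(st.floats(1e-8, 1.0), min_size=1, max_size=100))
    @settings(max_examples=200, deadline=None)
    def test_matches_stepup_oracle(self, p):
        assert bh_adjust(p) == pytest.approx(bh_stepup_oracle(p), abs=1e-12)


class TestSnpScan:
    def test_monomorphic_skipped(self, small_study):
        geno = small_study.genotypes.iloc[:, :3].copy()
        geno["rs_mono"] = 0.0
        scan = univariate_snp_scan(geno, small_study.pheno)
        row = scan.set_index("snp_id").loc["rs_mono"]
        assert row["skipped"] == "monomorphic"
        assert np.isnan(row["p_adj"])

    def test_adjusted_p_at_least_raw(self, small_study):
        scan = univariate_snp_scan(small_study.genotypes.iloc[:, :6],
                                   small_study.pheno)
        ok = scan["skipped"] == ""
        assert (scan.loc[ok, "p_adj"] >= scan.loc[ok, "p"] - 1e-12).all()

    def test_bmi_outcome_linear_family(self, small_study):
        scan = univariate_snp_scan(small_study.genotypes.iloc[:, :4],
                                   small_study.pheno, outcome="bmi")
        assert "or_" not in scan.columns
        assert scan["p"].between(0, 1).all()


class TestQuartileContrasts:
    def test_monotone_odds_under_generative_model(self):
        """Simulated per-allele risk effects produce increasing odds
        ratios across quartiles (replicate average)."""
        ors = []
        for seed in range(4):
            # interaction off: the linear predictor is monotone in the GRS
            data = replicate_data(seed=seed, with_quartiles=True,
                                  interaction_or=1.0)
            fit = grs_quartile_contrasts(data)
            ors.append([fit.params.loc[f"quartile[{q}]", "or_"]
                        for q in ("Q2", "Q3", "Q4")])
        mean_or = np.mean(ors, axis=0)
        assert mean_or[2] > mean_or[1] > mean_or[0] > 1.0

    def test_shuffled_grs_null(self, rng):
        data = replicate_data(seed=5, with_quartiles=True)
        data["grs"] = rng.permutation(data["grs"].to_numpy())
        data["quartile"] = assign_quartiles(data["grs"])
        fit = grs_quartile_contrasts(data)
        for q in ("Q2", "Q3", "Q4"):
            assert fit.params.loc[f"quartile[{q}]", "or_"] == pytest.approx(
                1.0, abs=0.8
            )

    def test_empty_quartile_error(self):
        data = replicate_data(seed=6, with_quartiles=True)
        data = data[data["quartile"] != "Q2"]
        with pytest.raises(ValueError, match="Q2"):
            grs_quartile_contrasts(data)


class TestInteraction:
    def test_no_interaction_gives_parallel_logit_curves(self):
        data = replicate_data(seed=8, interaction_or=1.0)
        fit = fit_glm(data, ModelSpec("depression", tuple(MODEL_TERMS[4])))
        grid = interaction_grid(fit, data, bmi_sds=(-1.0, 1.0), n_grs=5)
        wide = grid.pivot(index="grs", columns="bmi_stratum",
                          values="predicted_probability")
        lo = logit(wide.iloc[:, 0].to_numpy())
        hi = logit(wide.iloc[:, 1].to_numpy())
        gaps = hi - lo
        assert np.ptp(gaps) == pytest.approx(0.0, abs=1e-9)

    def test_positive_interaction_steepens_with_bmi(self):
        data = replicate_data(seed=9, interaction_or=1.14)
        fit = interaction_model(data)
        assert fit.params.loc["grs:bmi", "beta"] > 0
        grid = interaction_grid(fit, data, bmi_sds=(-1.0, 1.0), n_grs=5)
        wide = grid.pivot(index="grs", columns="bmi_stratum",
                          values="predicted_probability")
        slope = lambda col: np.diff(logit(wide[col].to_numpy())).mean()  # noqa: E731
        assert slope("+1SD") > slope("-1SD")


class TestEffectSizes:
    def test_cohens_d_from_printed_summaries(self):
        d = cohens_d_from_summary(22.38, 2.91, 104, 20.71, 2.94, 1546)
        assert round(d, 2) == 0.57

    def test_identical_groups(self, rng):
        x = rng.normal(size=40)
        rep = group_compare(np.r_[x, x], np.r_[np.zeros(40), np.ones(40)])
        assert rep.cohens_d == pytest.approx(0.0)

    def test_cramers_v_perfect_association(self):
        assert cramers_v(np.array([[10, 0], [0, 10]])) == pytest.approx(1.0)

    def test_chi_squared_path(self):
        rep = group_compare(contingency=np.array([[20, 30], [25, 25]]))
        assert rep.test_used == "chi_squared"
        assert 0 <= rep.cramers_v <= 1

    def test_cohens_d_antisymmetric(self):
        d1 = cohens_d_from_summary(5.0, 1.0, 30, 3.0, 1.2, 40)
        d2 = cohens_d_from_summary(3.0, 1.2, 40, 5.0, 1.0, 30)
        assert d1 == pytest.approx(-d2)

    def test_cramers_v_permutation_invariant(self, rng):
        t = rng.integers(1, 50, size=(3, 4)).astype(float)
        v = cramers_v(t)
        assert cramers_v(t[::-1]) == pytest.approx(v)
        assert cramers_v(t[:, ::-1]) == pytest.approx(v)
        assert cramers_v(t.T) == pytest.approx(v)

    def test_nonnormal_uses_mann_whitney(self, rng):
        a = rng.exponential(size=200)
        b = rng.exponential(size=200) + 0.5
        rep = group_compare(np.r_[a, b], np.r_[np.zeros(200), np.ones(200)])
        assert rep.test_used == "mann_whitney"


class TestLogisticPower:
    def test_null_or_returns_alpha(self):
        p = logistic_power(PowerParams(1.0, 2.97, 0.063, 1650, alpha=0.05))
        assert p == pytest.approx(0.05, abs=1e-10)

    def test_study_design_point_is_decisive(self):
        p = logistic_power(PowerParams(1.35, 2.97, 104 / 1650, 1650))
        assert p >= 0.9999

    def test_monotone_in_n_and_effect(self):
        grid_n = [50, 200, 800, 3200]
        powers_n = [
            logistic_power(PowerParams(1.2, 1.0, 0.1, n)) for n in grid_n
        ]
        assert all(a < b for a, b in zip(powers_n, powers_n[1:]))
        grid_or = [1.05, 1.2, 1.5, 2.0]
        powers_or = [
            logistic_power(PowerParams(r, 1.0, 0.1, 500)) for r in grid_or
        ]
        assert all(a < b for a, b in zip(powers_or, powers_or[1:]))
        # symmetric in the direction of the effect
        assert logistic_power(PowerParams(0.5, 1.0, 0.1, 500)) == pytest.approx(
            logistic_power(PowerParams(2.0, 1.0, 0.1, 500))
        )

    def test_invalid_or(self):
        with pytest.raises(ValueError):
            PowerParams(-1.0, 1.0, 0.1, 100)
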