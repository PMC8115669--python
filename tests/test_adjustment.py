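"""Log transformation, Pearson statistics and the two adjustment methods."""

import numpy as np
import pandas as pd
import pytest

from mrmkit.adjustment import (
    adjust_division,
    adjust_regression,
    log_transform,
    pearson,
    residual_table,
    significance_stars,
)
from mrmkit.simulate import CohortParams, simulate_cohort


@pytest.fixture(scope="module")
def log_cohort():
    cohort, _ = simulate_cohort(CohortParams(n_samples=200, seed=1))
    logged, _ = log_transform(cohort)
    return logged


class TestLogTransform:
    def test_base10_values(self):
        df = pd.DataFrame({"a": [1.0, 10.0, 100.0]})
        logged, masked = log_transform(df)
        assert list(logged["a"]) == [0.0, 1.0, 2.0]
        assert masked["a"] == 0

    def test_non_positive_masked_and_counted(self):
        df = pd.DataFrame({"a": [1.0, 0.0, -3.0, np.nan, 10.0]})
        logged, masked = log_transform(df)
        assert masked["a"] == 3
        assert logged["a"].notna().sum() == 2

    def test_correlation_invariant_to_base(self, log_cohort):
        cohort, _ = simulate_cohort(CohortParams(n_samples=100, seed=3))
        log10, _ = log_transform(cohort, base=10.0)
        ln, _ = log_transform(cohort, base=np.e)
        r10 = pearson(log10["CC16"], log10["B2M"]).r
        rln = pearson(ln["CC16"], ln["B2M"]).r
        assert r10 == pytest.approx(rln, abs=1e-12)


class TestPearson:
    def test_self_correlation(self):
        x = pd.Series([1.0, 2.0, 5.0, 3.0])
        assert pearson(x, x).r == pytest.approx(1.0)

    def test_anticorrelation(self):
        x = pd.Series([1.0, 2.0, 5.0, 3.0])
        assert pearson(x, -x).r == pytest.approx(-1.0)

    def test_hand_computed_r_and_p(self):
        # r = 8 / sqrt(10*10) = 0.8; t = 0.8 sqrt(3/0.36) = 2.3094 on 3 df
        res = pearson([1, 2, 3, 4, 5], [2, 1, 4, 3, 5])
        assert res.r == pytest.approx(0.8)
        assert res.p == pytest.approx(0.104, abs=0.001)
        assert res.n == 5

    def test_pairwise_complete(self):
        x = pd.Series([1.0, 2.0, np.nan, 4.0, 5.0])
        y = pd.Series([2.0, 4.0, 6.0, 8.0, np.nan])
        res = pearson(x, y)
        assert res.n == 3 and res.r == pytest.approx(1.0)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            pearson([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_too_few_pairs(self):
        with pytest.raises(ValueError, match="at least 3"):
            pearson([1.0, 2.0], [2.0, 1.0])


def test_significance_tiers():
    assert significance_stars(0.04) == "$"
    assert significance_stars(0.005) == "#"
    assert significance_stars(0.0005) == "*"
    assert significance_stars(0.2) == ""


class TestDivisionAdjustment:
    def test_self_adjustment_is_zero(self, log_cohort):
        adjusted = adjust_division(log_cohort["CC16"], log_cohort["CC16"])
        assert np.allclose(adjusted, 0.0)

    def test_constant_adjuster_preserves_correlations(self, log_cohort):
        const = pd.Series(2.0, index=log_cohort.index)
        adjusted = adjust_division(log_cohort["CC16"], const)
        r_adj = pearson(adjusted, log_cohort["B2M"]).r
        r_raw = pearson(log_cohort["CC16"], log_cohort["B2M"]).r
        assert r_adj == pytest.approx(r_raw, abs=1e-12)

    def test_creatinine_division_overcorrects_diuresis(self):
        # CC16 loads less on diuresis than creatinine does, so dividing by
        # creatinine flips the residual correlation negative
        cohort, _ = simulate_cohort(CohortParams(seed=1))
        logged, _ = log_transform(cohort)
        adjusted = adjust_division(logged["CC16"], logged["CREAT"])
        assert pearson(adjusted, logged["CREAT"]).r < 0


class TestRegressionAdjustment:
    def test_orthogonality_over_seeded_cohorts(self):
        for seed in range(100):
            cohort, _ = simulate_cohort(CohortParams(n_samples=60, seed=seed))
            logged, _ = log_transform(cohort)
            result = adjust_regression(logged["CC16"], logged["B2M"])
            assert abs(pearson(result.adjusted, logged["B2M"]).r) < 1e-10

    def test_uncorrelated_adjuster_leaves_analyte(self):
        rng = np.random.default_rng(0)
        a = pd.Series(rng.normal(size=500))
        x = pd.Series(rng.normal(size=500))
        result = adjust_regression(a, x)
        assert abs(result.beta) < 0.1
        assert np.corrcoef(result.adjusted, a)[0, 1] > 0.99

    def test_exact_linear_relation_collapses_to_mean(self):
        x = pd.Series(np.linspace(0.0, 2.0, 50))
        a = 2.0 * x
        result = adjust_regression(a, x)
        assert result.beta == pytest.approx(2.0)
        assert np.allclose(result.adjusted, a.mean())

    def test_mean_preserved(self, log_cohort):
        result = adjust_regression(log_cohort["CC16"], log_cohort["B2M"])
        assert result.adjusted.mean() == pytest.approx(log_cohort["CC16"].mean())

    def test_beta_one_equals_division_up_to_constant(self, log_cohort):
        a, x = log_cohort["CC16"], log_cohort["B2M"]
        manual = a - 1.0 * (x - x.mean())
        division = adjust_division(a, x)
        diff = manual - division
        assert np.allclose(diff, diff.iloc[0])  # constant offset only
        r1 = pearson(manual, log_cohort["HSA"]).r
        r2 = pearson(division, log_cohort["HSA"]).r
        assert r1 == pytest.approx(r2, abs=1e-12)

    def test_zero_variance_adjuster_rejected(self, log_cohort):
        const = pd.Series(1.0, index=log_cohort.index)
        with pytest.raises(ValueError, match="zero variance"):
            adjust_regression(log_cohort["CC16"], const)


class TestResidualTable:
    def test_regression_zeroes_adjuster_entries(self, log_cohort):
        report = residual_table(log_cohort, method="regression")
        for analyte in ("CC16", "OPN"):
            for adj in ("RBP4", "B2M", "CREAT", "HSA"):
                assert abs(report.r.loc[f"{analyte}-{adj}", adj]) < 1e-10

    def test_matrix_symmetric_unit_diagonal(self, log_cohort):
        report = residual_table(log_cohort, method="division")
        r = report.r
        assert np.allclose(r.values, r.values.T, equal_nan=True)
        assert np.allclose(np.diag(r.values), 1.0)
        finite = r.values[np.isfinite(r.values)]
        assert np.all(np.abs(finite) <= 1 + 1e-12)

    def test_regression_reduces_residual_correlation_vs_division(self, log_cohort):
        division = residual_table(log_cohort, method="division")
        regression = residual_table(log_cohort, method="regression")
        assert abs(regression.r.loc["CC16-B2M", "HSA"]) < abs(
            division.r.loc["CC16-B2M", "HSA"]
        )

    def test_missing_column_noted_table_still_produced(self, log_cohort):
        broken = log_cohort.copy()
        broken["HSA"] = np.nan
        report = residual_table(broken, method="division")
        assert any("HSA" in note for note in report.notes)
        assert "CC16-B2M" in report.r.columns

    def test_self_adjustment_zero_variance_flagged(self, log_cohort):
        # an adjuster identical to the analyte makes the division-adjusted
        # series constant; it is flagged and excluded, the rest is produced
        dup = log_cohort.copy()
        dup["DUP"] = dup["CC16"]
        report = residual_table(
            dup, analytes=("CC16",), adjusters=("DUP", "B2M"), method="division"
        )
        assert any("CC16-DUP" in note for note in report.notes)
        assert "CC16-DUP" not in report.r.columns
        assert "CC16-B2M" in report.r.columns

    def test_stars_follow_footnote_tiers(self, log_cohort):
        report = residual_table(log_cohort, method="division")
        p, stars = report.p, report.stars
        for a in p.columns:
            for b in p.columns:
                pv = p.loc[a, b]
                if not np.isfinite(pv) or a == b:
                    continue
                expected = (
                    "*" if pv < 0.001 else "#" if pv < 0.01 else "$" if pv < 0.05 else ""
                )
                assert stars.loc[a, b] == expected


def test_parameter_recovery_regression_beats_creatinine_division():
    """On synthetic cohorts the regression-by-B2M adjusted CC16 tracks the
    latent airway signal better than the creatinine ratio does."""
    wins = []
    for seed in range(100):
        cohort, latents = simulate_cohort(CohortParams(seed=seed))
        logged, _ = log_transform(cohort)
        reg = adjust_regression(logged["CC16"], logged["B2M"]).adjusted
        div = adjust_division(logged["CC16"], logged["CREAT"])
        r_reg = pearson(reg, latents["S"]).r
        r_div = pearson(div, latents["S"]).r
        wins.append(r_reg - r_div)
    assert np.median(wins) > 0
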