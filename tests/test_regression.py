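"""Validity regressions, CI-overlap rule, 2SD scaling and the gamma GLM."""

import numpy as np
import pandas as pd
import pytest

import gicomp as g
from gicomp.intervals import Interval
from gicomp.io import build_difference_design
from gicomp.regression import fit_gamma_glm, likelihood_ratio_test


class TestGradeRegression:
    def test_perfect_linear_data(self):
        x = np.arange(20.0)
        fit = g.fit_grade_regression(2 * x + 1, x)
        assert fit.beta == pytest.approx(1.0)
        assert fit.r2 == pytest.approx(1.0)

    def test_beta_equals_pearson_r_and_r2_its_square(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal(500)
        y = 0.4 * x + rng.standard_normal(500)
        fit = g.fit_grade_regression(y, x)
        r = np.corrcoef(x, y)[0, 1]
        assert fit.beta == pytest.approx(r, abs=1e-12)
        assert fit.r2 == pytest.approx(r**2, abs=1e-10)
        assert fit.ci.contains(fit.beta)

    def test_generating_validity_recovered_on_latent_ability(self):
        cfg = g.demo_sim_config(n_subjects=50_000, seed=13)
        coh = g.generate_cohort(cfg)
        graded = g.generate_grades(coh, validity=0.4, seed=13)
        fit = g.fit_grade_regression(graded["grade_german"], coh["g"])
        assert fit.beta == pytest.approx(0.4, abs=0.02)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            g.fit_grade_regression(np.ones(20), np.arange(20.0))


class TestBetaCiOverlap:
    def test_identical_cis_not_different(self):
        frac, different = g.beta_ci_overlap_fraction(Interval(0.1, 0.5), Interval(0.1, 0.5))
        assert frac == 2.0
        assert not different

    def test_disjoint_cis_different(self):
        frac, different = g.beta_ci_overlap_fraction(Interval(0.0, 0.2), Interval(0.3, 0.5))
        assert frac == 0.0
        assert different

    def test_exact_half_overlap_is_the_rule_boundary(self):
        frac, different = g.beta_ci_overlap_fraction(Interval(0, 1), Interval(0.75, 1.75))
        assert frac == pytest.approx(0.5)
        assert different  # "50% or less" counts as different

    def test_symmetric_in_arguments(self):
        a, b = Interval(0.1, 0.6), Interval(0.4, 0.9)
        assert g.beta_ci_overlap_fraction(a, b) == g.beta_ci_overlap_fraction(b, a)

    def test_two_point_intervals_rejected(self):
        with pytest.raises(ValueError):
            g.beta_ci_overlap_fraction(Interval(0.3, 0.3), Interval(0.3, 0.3))


class TestMedianSplit:
    def _pair(self, abs_diffs):
        table = pd.DataFrame(
            {"iq_a": 100, "iq_b": 100 - np.asarray(abs_diffs), "diff": abs_diffs,
             "abs_diff": abs_diffs}
        )
        return g.PairComparison("A", "B", table)

    def test_even_split(self):
        split = g.median_split(self._pair([1, 2, 3, 4]))
        assert split.sizes == (2, 2)
        assert split.median == 2.5

    def test_all_tied_at_median_goes_to_large(self):
        split = g.median_split(self._pair([3, 3, 3, 3]))
        assert split.sizes == (0, 4)

    def test_split_partitions_subjects(self, pair):
        split = g.median_split(pair)
        assert sum(split.sizes) == pair.n


class TestTwoSdStandardize:
    def test_continuous_column_centered_and_divided(self):
        df = pd.DataFrame({"x": [0.0, 2.0, 4.0, 6.0]})  # SD 2.236 (ddof=0)
        out = g.two_sd_standardize(df)
        sd = df["x"].std(ddof=0)
        expected = (df["x"] - 3.0) / (2 * sd)
        pd.testing.assert_series_equal(out["x"], expected, check_names=False)

    def test_balanced_binary_unchanged(self):
        df = pd.DataFrame({"b": [0.0, 1.0] * 10})  # SD exactly .5 -> divisor 1
        out = g.two_sd_standardize(df)
        pd.testing.assert_series_equal(out["b"], df["b"], check_names=False)

    def test_not_idempotent_guarded_by_provenance_flag(self):
        df = pd.DataFrame({"x": [1.0, 2.0, 3.0]})
        once = g.two_sd_standardize(df)
        with pytest.raises(ValueError, match="already"):
            g.two_sd_standardize(once)

    def test_constant_column_named_in_error(self):
        with pytest.raises(ValueError, match="'flat'"):
            g.two_sd_standardize(pd.DataFrame({"flat": [1.0, 1.0, 1.0]}))


class TestGammaGlm:
    def test_intercept_only_mle_is_log_mean(self):
        rng = np.random.default_rng(4)
        y = rng.gamma(3.0, 2.0, size=2000)
        fit = fit_gamma_glm(y, None)
        assert fit.params["const"] == pytest.approx(np.log(y.mean()), abs=1e-8)

    def test_coefficients_recovered_from_known_model(self):
        rng = np.random.default_rng(8)
        n = 5000
        beta = {"const": 1.5, "x1": 0.3, "b1": -0.2}
        design = pd.DataFrame(
            {"x1": rng.standard_normal(n), "b1": (rng.random(n) < 0.4).astype(float)}
        )
        mu = np.exp(beta["const"] + design["x1"] * beta["x1"] + design["b1"] * beta["b1"])
        y = rng.gamma(5.0, mu / 5.0)
        fit = fit_gamma_glm(y, design)
        for name, true_val in beta.items():
            assert fit.params[name] == pytest.approx(true_val, abs=0.05)
        assert fit.shape == pytest.approx(5.0, rel=0.1)

    def test_zero_responses_replaced_by_half_point(self):
        y = np.array([0.0, 1.0, 2.0, 3.0, 4.0] * 5)
        fit = fit_gamma_glm(y, None)
        assert fit.n_zeros_adjusted == 5
        with pytest.raises(ValueError, match="zero"):
            fit_gamma_glm(y, None, zero_rule=None)

    def test_duplicated_column_is_rank_deficient(self):
        rng = np.random.default_rng(3)
        design = pd.DataFrame({"x": rng.standard_normal(50)})
        design["x_copy"] = design["x"]
        with pytest.raises(ValueError, match="rank deficient"):
            fit_gamma_glm(rng.gamma(2.0, 1.0, 50), design)


class TestLikelihoodRatioTest:
    def _fits(self, seed=0, n=500):
        rng = np.random.default_rng(seed)
        y = rng.gamma(4.0, 0.5, size=n)
        design = pd.DataFrame({"x": rng.standard_normal(n)})
        return fit_gamma_glm(y, design), fit_gamma_glm(y, None)

    def test_model_against_itself_gives_zero(self):
        full, _ = self._fits()
        res = likelihood_ratio_test(full, full)
        assert res.statistic == 0
        assert res.p == 1.0

    def test_statistic_nonnegative_and_df_counts_parameters(self):
        full, null = self._fits()
        res = likelihood_ratio_test(full, null)
        assert res.statistic >= 0
        assert res.df == 1

    def test_non_nested_models_rejected(self):
        rng = np.random.default_rng(1)
        y = rng.gamma(4.0, 0.5, size=100)
        a = fit_gamma_glm(y, pd.DataFrame({"x": rng.standard_normal(100)}))
        b = fit_gamma_glm(y, pd.DataFrame({"z": rng.standard_normal(100)}))
        with pytest.raises(ValueError, match="not nested"):
            likelihood_ratio_test(a, b)

    def test_different_responses_rejected(self):
        full, _ = self._fits(seed=0)
        _, other_null = self._fits(seed=99)
        with pytest.raises(ValueError, match="different responses"):
            likelihood_ratio_test(full, other_null)


def test_slodr_effect_detected_with_high_power():
    """An ability-dependent loading drop must surface as an above-average-IQ effect.

    Full pipeline — generator with SLODR slope 0.15, norming, composite IQs,
    2SD-standardized design, gamma GLM — over seeded replicates at n = 5000.
    """
    hits = 0
    n_rep = 40
    for rep in range(n_rep):
        cfg = g.demo_sim_config(n_subjects=5000, seed=10_000 + rep, slodr_slope=0.15)
        coh = g.generate_cohort(cfg)
        bat = cfg.battery
        norms = g.build_norm_table(coh, bat)
        pair = g.compare_pair(coh, bat, norms, "EBIQ14", "ABIQ2")
        iqs = g.compute_composite_iqs(coh, bat, norms, ["EBIQ14"])["EBIQ14"]
        design = build_difference_design(coh, iqs)
        fit = fit_gamma_glm(pair.abs_diff.to_numpy(float), design)
        if fit.pvalues["above_average_iq"] < 0.05 and fit.params["above_average_iq"] > 0:
            hits += 1
    assert hits / n_rep > 0.8
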