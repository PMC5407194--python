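"""Screening, logistic regression, LOOCV, baselines, covariate correlations."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from improvsync import cohort_stats as cs


def logistic_cohort(rng, n=2000, beta0=1.0, beta1=-2.0):
    x = rng.standard_normal(n)
    p = 1 / (1 + np.exp(-(beta0 + beta1 * x)))
    return pd.DataFrame({"group": rng.binomial(1, p), "x": x})


class TestScreen:
    def test_shifted_feature_ranks_first(self, rng):
        n = 14
        table = pd.DataFrame({
            "group": [1] * n + [0] * n,
            "signal": np.concatenate([rng.normal(2.0, 1, n), rng.normal(0, 1, n)]),
            "noise": rng.standard_normal(2 * n),
        })
        screen = cs.screen_variables(table, ["signal", "noise"])
        assert screen.iloc[0]["variable"] == "signal"
        assert screen.iloc[0]["p"] < 0.05
        assert (screen["p_bonferroni"] >= screen["p"]).all()

    def test_zero_variance_feature_skipped(self, rng):
        table = pd.DataFrame({
            "group": [1, 1, 1, 0, 0, 0],
            "flat": [2.0] * 6,
            "ok": rng.standard_normal(6),
        })
        screen = cs.screen_variables(table, ["flat", "ok"])
        assert list(screen["variable"]) == ["ok"]

    def test_all_missing_feature_skipped(self):
        table = pd.DataFrame({"group": [1, 1, 0, 0], "gone": [np.nan] * 4})
        assert cs.screen_variables(table, ["gone"]).empty

    def test_welch_matches_scipy_directly(self, rng):
        a, b = rng.normal(1, 2, 9), rng.normal(0, 1, 13)
        table = pd.DataFrame({"group": [1] * 9 + [0] * 13, "v": np.concatenate([a, b])})
        screen = cs.screen_variables(table, ["v"])
        ref = stats.ttest_ind(a, b, equal_var=False)
        assert screen.iloc[0]["t"] == pytest.approx(ref.statistic)
        assert screen.iloc[0]["df"] == pytest.approx(ref.df)


class TestLogisticFit:
    def test_recovers_known_coefficients_within_two_se(self, rng):
        table = logistic_cohort(rng)
        fit = cs.fit_logistic(table, ["x"])
        assert abs(fit.coef["Intercept"] - 1.0) < 2 * fit.se["Intercept"]
        assert abs(fit.coef["x"] - (-2.0)) < 2 * fit.se["x"]

    def test_intercept_only_model_has_zero_nagelkerke(self, rng):
        table = logistic_cohort(rng, n=200)
        fit = cs.fit_logistic(table, [])
        assert fit.nagelkerke_r2 == pytest.approx(0.0, abs=1e-8)
        assert fit.deviance == pytest.approx(fit.null_deviance)

    def test_nagelkerke_in_unit_interval_and_deviance_ordering(self, rng):
        table = logistic_cohort(rng, n=300)
        fit = cs.fit_logistic(table, ["x"])
        assert 0 <= fit.nagelkerke_r2 <= 1
        assert fit.deviance <= fit.null_deviance
        assert fit.aic == pytest.approx(fit.deviance + 2 * 2)

    def test_hosmer_lemeshow_df_is_groups_minus_two(self, rng):
        table = logistic_cohort(rng, n=400)
        fit = cs.fit_logistic(table, ["x"])
        assert fit.hl_df == 8  # g = 10 deciles
        assert 0 <= fit.hl_p <= 1

    def test_perfect_separation_is_flagged(self):
        table = pd.DataFrame({"group": [0] * 10 + [1] * 10,
                              "x": list(range(10)) + list(range(20, 30))})
        fit = cs.fit_logistic(table, ["x"])
        assert fit.separation_flag

    def test_missing_rows_dropped_complete_case(self, rng):
        table = logistic_cohort(rng, n=100)
        table.loc[:9, "x"] = np.nan
        fit = cs.fit_logistic(table, ["x"])
        assert fit.n == 90


class TestStepwise:
    def test_single_separating_variable_enters_first(self, rng):
        n = 14
        table = pd.DataFrame({
            "group": [1] * n + [0] * n,
            "signal": np.concatenate([rng.normal(1.5, 1, n), rng.normal(0, 1, n)]),
            "noise1": rng.standard_normal(2 * n),
            "noise2": rng.standard_normal(2 * n),
        })
        result = cs.stepwise(table, ["noise1", "signal", "noise2"])
        assert result.terms[0] == "signal"
        assert result.path  # the full path is logged

    def test_no_entry_when_nothing_passes_screen(self, rng):
        table = pd.DataFrame({
            "group": [1] * 10 + [0] * 10,
            "noise": np.concatenate([rng.normal(0, 1, 10), rng.normal(0, 1, 10) + 1e-4]),
        })
        # force a clearly null screen by shuffling labels
        table["group"] = rng.permutation(table["group"].to_numpy())
        result = cs.stepwise(table, ["noise"])
        if result.terms:  # a lucky draw can still enter; the path must say why
            assert result.fit is not None
        else:
            assert "no variable passed" in result.path[0]

    def test_seeded_path_keeps_seed_term(self, rng):
        n = 14
        table = pd.DataFrame({
            "group": [1] * n + [0] * n,
            "lp": np.concatenate([rng.normal(-0.8, 1, n), rng.normal(0.8, 1, n)]),
            "other": np.concatenate([rng.normal(0.8, 1, n), rng.normal(-0.8, 1, n)]),
        })
        result = cs.stepwise(table, ["lp", "other"], seed_terms=["lp"])
        assert "lp" in result.path[0]


class TestLOOCV:
    def test_perfectly_separable_cohort_has_zero_error(self):
        table = pd.DataFrame({"group": [0] * 8 + [1] * 8,
                              "x": list(range(8)) + list(range(100, 108))})
        report = cs.loocv(table, ["x"])
        assert report.error == 0.0
        assert report.n_correct == 16

    def test_error_is_a_proportion(self, rng):
        table = logistic_cohort(rng, n=40)
        report = cs.loocv(table, ["x"])
        assert 0.0 <= report.error <= 1.0
        assert sum(report.confusion.values()) == report.n

    def test_too_few_subjects_rejected(self):
        table = pd.DataFrame({"group": [0, 1], "x": [0.0, 1.0]})
        with pytest.raises(ValueError):
            cs.loocv(table, ["x"])


class TestBinomialBaseline:
    def test_printed_guessing_baselines(self):
        # reported to 3 d.p. (the first was truncated: exact value 0.04358)
        assert cs.binomial_baseline(28, 18, 0.5) == pytest.approx(0.043, abs=1e-3)
        assert cs.binomial_baseline(28, 20, 16 / 28) == pytest.approx(0.040, abs=1e-3)

    def test_cannot_exceed_n(self):
        assert cs.binomial_baseline(28, 28, 0.5) == 0.0

    def test_matches_explicit_summation(self):
        from math import comb

        n, k, p = 17, 9, 0.37
        explicit = sum(comb(n, j) * p**j * (1 - p) ** (n - j) for j in range(k + 1, n + 1))
        assert cs.binomial_baseline(n, k, p) == pytest.approx(explicit, rel=1e-12)

    def test_invalid_ranges_rejected(self):
        with pytest.raises(ValueError):
            cs.binomial_baseline(10, 11, 0.5)
        with pytest.raises(ValueError):
            cs.binomial_baseline(10, 5, 1.5)


class TestImprovementAndCovariates:
    def test_improvement_sign_convention(self):
        table = pd.DataFrame({"MD_m_B1": [0.030, 0.020], "MD_m_B2": [0.020, 0.020]})
        imp = cs.improvement_variable(table)
        assert imp.iloc[0] == pytest.approx(0.010)  # deviations shrink: improving
        assert imp.iloc[1] == 0.0

    def test_missing_inputs_propagate(self):
        table = pd.DataFrame({"MD_m_B1": [np.nan], "MD_m_B2": [0.02]})
        assert np.isnan(cs.improvement_variable(table).iloc[0])

    def test_target_regressed_on_itself_r2_one(self, rng):
        n = 16
        target = pd.Series(rng.standard_normal(n))
        table = pd.DataFrame({
            "group": [1] * n,
            "avoidance": target,            # identical to the target
            "anxiety": rng.standard_normal(n),
        })
        rep = cs.covariate_screen(table, target, ["avoidance"])
        assert rep["attachment_regression"]["r_squared"] == pytest.approx(1.0)

    def test_correlations_reported_per_group_with_df(self, rng):
        n = 16
        z = rng.standard_normal(n)
        table = pd.DataFrame({
            "group": [1] * n + [0] * 12,
            "avoidance": np.concatenate([z + 0.3 * rng.standard_normal(n),
                                         rng.standard_normal(12)]),
            "anxiety": rng.standard_normal(n + 12),
        })
        target = pd.Series(np.concatenate([z, rng.standard_normal(12)]))
        rep = cs.covariate_screen(table, target, ["avoidance", "anxiety"])
        pat = [c for c in rep["correlations"] if c["group"] == "patient" and c["covariate"] == "avoidance"]
        assert pat[0]["df"] == n - 2
        r, p = stats.pearsonr(table.loc[:n - 1, "avoidance"], target[:n])
        assert pat[0]["r"] == pytest.approx(r)
        assert pat[0]["p"] == pytest.approx(p)

    def test_constant_covariate_skipped(self, rng):
        n = 10
        table = pd.DataFrame({"group": [1] * n, "flat": [3.0] * n, "avoidance": rng.standard_normal(n), "anxiety": rng.standard_normal(n)})
        rep = cs.covariate_screen(table, pd.Series(rng.standard_normal(n)), ["flat"])
        assert rep["correlations"] == []

    def test_paired_t_restricted_to_matched_pairs(self, rng):
        table = pd.DataFrame({
            "group": [1, 1, 1, 0, 0],
            "matched_pair": ["a", "b", None, "a", "b"],
        })
        target = pd.Series([1.0, 2.0, 9.0, 0.5, 1.5])
        rep = cs.covariate_screen(table, target, [])
        assert rep["group_tests"]["paired"]["df"] == 1  # two complete pairs
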