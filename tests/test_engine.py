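"""SEM engine: implied covariance, ML fitting, SEs, standardization,
factor scores, fit indices and nested-model comparison."""

import numpy as np
import pandas as pd
import pytest

from condsem import (
    ConvergenceError,
    ModelError,
    RAMMatrices,
    SampleMoments,
    chisq_diff_test,
    discrepancy_fml,
    factor_scores,
    fit_indices,
    fit_ml,
    implied_covariance,
    parse_model,
    standard_errors,
    standardized_solution,
)


class TestImpliedCovariance:
    def test_no_structure_returns_ssym(self):
        ram = RAMMatrices(A=np.zeros((2, 2)), Ssym=np.diag([1.0, 2.0]), Fsel=np.eye(2))
        assert np.allclose(implied_covariance(ram), np.diag([1.0, 2.0]))

    def test_one_factor_hand_algebra(self):
        # lambda = (1, 0.8), factor var 1, residuals 0.5 -> lam lam' psi + diag(eps)
        A = np.zeros((3, 3))
        A[0, 2], A[1, 2] = 1.0, 0.8
        S = np.diag([0.5, 0.5, 1.0])
        F = np.eye(3)[:2]
        expect = np.array([[1.5, 0.8], [0.8, 1.14]])
        assert np.allclose(implied_covariance(RAMMatrices(A, S, F)), expect)

    def test_regression_hand_computation(self):
        # y = 0.5 x, var(x) = 2, resid var(y) = 1 -> cov(x,y) = 1, var(y) = 1.5
        A = np.array([[0.0, 0.0], [0.5, 0.0]])
        S = np.diag([2.0, 1.0])
        expect = np.array([[2.0, 1.0], [1.0, 1.5]])
        assert np.allclose(implied_covariance(RAMMatrices(A, S, np.eye(2))), expect)


class TestDiscrepancy:
    def test_zero_iff_equal(self):
        s = np.array([[2.0, 0.3], [0.3, 1.0]])
        assert discrepancy_fml(s, s) == pytest.approx(0.0, abs=1e-12)

    def test_hand_value(self):
        s = np.array([[1.0, 0.5], [0.5, 1.0]])
        assert discrepancy_fml(s, np.eye(2)) == pytest.approx(-np.log(0.75), abs=1e-12)

    def test_singular_sigma_rejected(self):
        s = np.eye(2)
        with pytest.raises(ModelError, match="positive definite"):
            discrepancy_fml(s, np.array([[1.0, 1.0], [1.0, 1.0]]))

    def test_nonnegative_on_random_pd_pairs(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            p = rng.integers(2, 6)
            a = rng.normal(size=(p, 2 * p))
            b = rng.normal(size=(p, 2 * p))
            S, Sig = a @ a.T / (2 * p), b @ b.T / (2 * p)
            assert discrepancy_fml(S, Sig) >= -1e-12


class TestFitML:
    def test_just_identified_factor_matches_closed_form(self, factor_data):
        """The three covariances determine the solution in closed form."""
        fit = fit_ml(parse_model("f =~ x1 + x2 + x3"), factor_data)
        S = fit.per_group_moments[""].cov
        s12, s13, s23 = S[0, 1], S[0, 2], S[1, 2]
        assert fit.converged
        assert fit.fml == pytest.approx(0.0, abs=1e-9)
        assert fit.estimate("f", "=~", "x2") == pytest.approx(s23 / s13, abs=1e-6)
        assert fit.estimate("f", "=~", "x3") == pytest.approx(s23 / s12, abs=1e-6)
        assert fit.estimate("f", "~~", "f") == pytest.approx(s12 * s13 / s23, abs=1e-6)

    def test_composite_reproduces_ols(self, regression_data):
        """Composite -> outcome total effects equal least-squares coefficients."""
        df = regression_data
        fit = fit_ml(parse_model("C <~ x1 + x2\ny ~ C"), df)
        g = fit.estimate("y", "~", "C")
        X = np.column_stack([np.ones(len(df)), df.x1, df.x2])
        b = np.linalg.lstsq(X, df.y.to_numpy(), rcond=None)[0]
        assert g * fit.estimate("C", "<~", "x1") == pytest.approx(b[1], abs=1e-6)
        assert g * fit.estimate("C", "<~", "x2") == pytest.approx(b[2], abs=1e-6)
        # R^2 equivalence through the implied covariance
        resid = fit.estimate("y", "~~", "y")
        var_y = fit.per_group_moments[""].cov[2, 2]
        yhat = X @ b
        r2_ols = 1 - np.sum((df.y - yhat) ** 2) / np.sum((df.y - df.y.mean()) ** 2)
        assert 1 - resid / var_y == pytest.approx(r2_ols, abs=1e-6)

    def test_saturated_model_reproduces_sample_cov(self, regression_data):
        spec = parse_model("x1 ~~ x2\nx1 ~~ y\nx2 ~~ y")
        fit = fit_ml(spec, regression_data)
        assert fit.chisq == pytest.approx(0.0, abs=1e-8)
        assert fit.df == 0

    def test_listwise_deletion_records_n(self, regression_data):
        df = regression_data.copy()
        df.loc[df.index[:25], "x1"] = np.nan
        fit = fit_ml(parse_model("y ~ x1 + x2"), df)
        assert fit.n_total == len(df) - 25

    def test_moments_input(self, regression_data):
        m = SampleMoments.from_dataframe(regression_data, ["x1", "x2", "y"])
        fit = fit_ml(parse_model("y ~ x1 + x2"), m)
        fit2 = fit_ml(parse_model("y ~ x1 + x2"), regression_data)
        assert fit.estimate("y", "~", "x1") == pytest.approx(
            fit2.estimate("y", "~", "x1"), abs=1e-9)

    def test_multigroup_same_data_equals_pooled(self, regression_data):
        """Duplicating the data into two groups reproduces the pooled fit."""
        both = pd.concat([regression_data.assign(g="a"),
                          regression_data.assign(g="b")], ignore_index=True)
        spec = parse_model("y ~ x1 + x2")
        fitg = fit_ml(spec, both, group="g")
        fitp = fit_ml(spec, regression_data)
        for grp in ("a", "b"):
            sub = fitg.params.query("group == @grp and op == '~'")
            pooled = fitp.params.query("op == '~'")
            assert np.allclose(sub.estimate.values, pooled.estimate.values, atol=1e-6)

    def test_parameter_recovery_large_n(self):
        """Fitting the generating model at n = 10,000 recovers the truth."""
        from condsem import fixture_true_model, simulate_dataset

        tm = fixture_true_model("energy")
        data = simulate_dataset(tm, 10_000, seed=11)
        fit = fit_ml(tm.spec, data)
        standard_errors(fit)
        free = fit.params[fit.params.free]
        for _, row in free.iterrows():
            truth = tm.true_value(row.lhs, row.op, row.rhs)
            assert abs(row.estimate - truth) < 3 * row.se, (
                f"{row.lhs} {row.op} {row.rhs}: {row.estimate} vs {truth}")


class TestStandardErrors:
    def test_simple_regression_matches_analytic(self, regression_data):
        import statsmodels.api as sm

        fit = fit_ml(parse_model("y ~ x1 + x2"), regression_data)
        standard_errors(fit)
        ols = sm.OLS(regression_data.y,
                     sm.add_constant(regression_data[["x1", "x2"]])).fit()
        n = len(regression_data)
        for x in ("x1", "x2"):
            row = fit.params.query("op == '~' and rhs == @x").iloc[0]
            # ML uses the N-1 variance denominator vs OLS's N - p - 1
            expected = ols.bse[x] * np.sqrt((n - 3) / (n - 1))
            assert row.se == pytest.approx(expected, rel=1e-3)

    def test_duplicated_data_shrinks_se_by_sqrt2(self, regression_data):
        spec = parse_model("y ~ x1")
        fit1 = fit_ml(spec, regression_data)
        fit2 = fit_ml(spec, pd.concat([regression_data] * 2, ignore_index=True))
        standard_errors(fit1)
        standard_errors(fit2)
        se1 = fit1.params.query("op == '~'").se.iloc[0]
        se2 = fit2.params.query("op == '~'").se.iloc[0]
        assert se2 / se1 == pytest.approx(1 / np.sqrt(2), rel=0.01)

    def test_nonconverged_fit_refused(self, regression_data):
        fit = fit_ml(parse_model("y ~ x1"), regression_data)
        fit.converged = False
        with pytest.raises(ConvergenceError):
            standard_errors(fit)


class TestStandardizedSolution:
    def test_simple_regression_equals_pearson(self, regression_data):
        fit = fit_ml(parse_model("y ~ x1"), regression_data[["x1", "y"]])
        standardized_solution(fit)
        r = np.corrcoef(regression_data.x1, regression_data.y)[0, 1]
        row = fit.params.query("op == '~'").iloc[0]
        assert row.std_estimate == pytest.approx(r, abs=1e-6)

    def test_rescaling_invariance(self, factor_data):
        """Multiplying any column by a constant leaves std estimates unchanged."""
        spec = parse_model("f =~ x1 + x2 + x3")
        base = standardized_solution(fit_ml(spec, factor_data))
        scaled = factor_data.copy()
        scaled["x2"] = scaled["x2"] * 37.5
        scaled["x3"] = scaled["x3"] * 0.01
        other = standardized_solution(fit_ml(spec, scaled))
        assert np.allclose(base.std_estimate.astype(float),
                           other.std_estimate.astype(float), atol=1e-6)

    def test_standardized_latent_variance_is_one(self, factor_data):
        fit = fit_ml(parse_model("f =~ x1 + x2 + x3"), factor_data)
        tab = standardized_solution(fit)
        row = tab.query("op == '~~' and lhs == 'f' and rhs == 'f'").iloc[0]
        assert row.std_estimate == pytest.approx(1.0, abs=1e-9)


class TestFactorScores:
    def test_two_equal_indicators_track_their_mean(self):
        rng = np.random.default_rng(8)
        n = 10_000
        f = rng.normal(size=n)
        data = pd.DataFrame({
            "x1": f + rng.normal(scale=0.4, size=n),
            "x2": f + rng.normal(scale=0.4, size=n),
            "x3": 0.5 * f + rng.normal(scale=1.0, size=n),
        })
        fit = fit_ml(parse_model("f =~ x1 + x2 + x3"), data)
        scores = factor_scores(fit, data)
        r = np.corrcoef(scores["f"], (data.x1 + data.x2) / 2)[0, 1]
        assert r > 0.99

    def test_energy_scores_match_first_principal_component(self):
        """Two indicators with r about 0.9: latent scores track PC1 closely."""
        from condsem import fixture_true_model, principal_components, simulate_dataset

        tm = fixture_true_model("energy")
        data = simulate_dataset(tm, 10_000, seed=12)
        fit = fit_ml(tm.spec, data)
        scores = factor_scores(fit, data)
        pca = principal_components(data, ["mass", "ratio"])
        r = abs(np.corrcoef(scores["energy"], pca.scores["PC1"])[0, 1])
        assert r >= 0.95

    def test_degenerate_single_indicator_latent(self, regression_data):
        spec = parse_model("L =~ 1*x1\nx1 ~~ 0*x1\ny ~ L")
        fit = fit_ml(spec, regression_data[["x1", "y"]])
        scores = factor_scores(fit, regression_data[["x1", "y"]])
        centred = regression_data.x1 - regression_data.x1.mean()
        assert np.allclose(scores["L"], centred, atol=1e-8)

    def test_missing_rows_skipped_with_warning(self, regression_data):
        df = regression_data.copy()
        df.loc[df.index[:3], "x1"] = np.nan
        fit = fit_ml(parse_model("y ~ x1 + x2"), df)
        spec = parse_model("C <~ x1 + x2\ny ~ C")
        fit = fit_ml(spec, df)
        with pytest.warns(UserWarning, match="skipped"):
            scores = factor_scores(fit, df)
        assert len(scores) == len(df) - 3


class TestFitIndices:
    def test_saturated_model_cfi_one(self, regression_data):
        spec = parse_model("x1 ~~ x2\nx1 ~~ y\nx2 ~~ y")
        fi = fit_indices(fit_ml(spec, regression_data))
        assert fi["chisq"] == pytest.approx(0.0, abs=1e-8)
        assert fi["cfi"] == 1.0

    def test_independence_model_against_itself_is_zero(self, regression_data):
        # a model with all covariances pinned to zero IS the independence model
        spec = parse_model(
            "x1 ~~ x1\nx2 ~~ x2\ny ~~ y\n"
            "x1 ~~ 0*x2\nx1 ~~ 0*y\nx2 ~~ 0*y"
        )
        fit = fit_ml(spec, regression_data)
        fi = fit_indices(fit)
        assert fi["cfi"] == pytest.approx(0.0, abs=1e-8)

    def test_chisq_mean_approximates_df(self):
        """Correct-model chi-square is asymptotically chi-square(df)."""
        from condsem import TrueModel, simulate_dataset

        spec = parse_model("f =~ x1 + x2 + x3 + x4")
        vals = {
            "f =~ x2": 0.8, "f =~ x3": 1.1, "f =~ x4": 0.9,
            "f ~~ f": 1.0,
            "x1 ~~ x1": 0.5, "x2 ~~ x2": 0.5, "x3 ~~ x3": 0.5, "x4 ~~ x4": 0.5,
        }
        tm = TrueModel(spec=spec, values=vals)
        chis = []
        for i in range(300):
            data = simulate_dataset(tm, 500, seed=99, stream=i)
            fit = fit_ml(tm.spec, data)
            chis.append(fit.chisq)
        assert np.mean(chis) == pytest.approx(2.0, abs=0.35)  # df = 2


class TestChisqDiff:
    def test_identical_models_refused(self, regression_data):
        spec = parse_model("y ~ x1 + x2")
        f1 = fit_ml(spec, regression_data)
        f2 = fit_ml(spec, regression_data)
        with pytest.raises(ModelError, match="equal df"):
            chisq_diff_test(f1, f2)

    def test_different_datasets_rejected(self, regression_data, factor_data):
        nested = fit_ml(parse_model("y ~ x1"), regression_data[["x1", "y"]])
        full = fit_ml(parse_model("x2 ~ x1"),
                      factor_data.rename(columns={"x3": "y"})[["x1", "x2"]])
        with pytest.raises(ModelError):
            chisq_diff_test(nested, full)

    def test_delta_between_nested_fits(self, regression_data):
        nested = fit_ml(parse_model("y ~ x1\nx1 ~~ x2"), regression_data)
        full = fit_ml(parse_model("y ~ x1 + x2"), regression_data)
        res = chisq_diff_test(nested, full)
        assert res["delta_df"] == 1
        assert res["delta_chisq"] >= 0
        assert 0 <= res["pvalue"] <= 1
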