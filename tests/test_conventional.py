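"""PCA variable reduction and the four-step stepwise condition index."""

import numpy as np
import pandas as pd
import pytest

from condsem import principal_components, residual_regression, stepwise_condition_index


@pytest.fixture(scope="module")
def bivariate():
    rng = np.random.default_rng(17)
    n = 5000
    z = rng.normal(size=n)
    x1 = z + rng.normal(scale=0.22, size=n)
    x2 = z + rng.normal(scale=0.22, size=n)
    return pd.DataFrame({"x1": x1, "x2": x2})


class TestPCA:
    def test_perfect_correlation_pc1_explains_all(self):
        x = np.linspace(-2, 2, 100)
        data = pd.DataFrame({"a": x, "b": 3 * x + 1})
        res = principal_components(data, ["a", "b"])
        assert res.variance_explained[0] == pytest.approx(1.0, abs=1e-12)

    def test_two_variable_eigenvalues_are_one_plus_minus_r(self):
        """PC1 share of a 2x2 correlation matrix is (1 + r)/2."""
        from condsem import SampleMoments  # noqa: F401  (documentation import)

        rng = np.random.default_rng(4)
        n = 200_000
        z = rng.normal(size=n)
        lam = np.sqrt(0.91)
        data = pd.DataFrame({
            "a": lam * z + np.sqrt(1 - 0.91) * rng.normal(size=n),
            "b": lam * z + np.sqrt(1 - 0.91) * rng.normal(size=n),
        })
        r = data.corr().iloc[0, 1]
        res = principal_components(data, ["a", "b"])
        assert res.variance_explained[0] == pytest.approx((1 + r) / 2, abs=1e-9)
        assert res.variance_explained[0] == pytest.approx(0.955, abs=0.005)

    def test_loadings_match_eigh_oracle_up_to_sign(self, bivariate):
        res = principal_components(bivariate, ["x1", "x2"])
        corr = bivariate.corr().to_numpy()
        w, v = np.linalg.eigh(corr)
        order = np.argsort(w)[::-1]
        w, v = w[order], v[:, order]
        oracle = v * np.sqrt(w)
        got = res.loadings.to_numpy()
        for k in range(2):
            assert np.allclose(got[:, k], oracle[:, k], atol=1e-9) or \
                np.allclose(got[:, k], -oracle[:, k], atol=1e-9)

    def test_sign_convention_largest_loading_positive(self, bivariate):
        res = principal_components(bivariate, ["x1", "x2"])
        for k in res.loadings.columns:
            col = res.loadings[k].to_numpy()
            assert col[np.argmax(np.abs(col))] > 0

    def test_uncorrelated_variables_share_evenly(self):
        rng = np.random.default_rng(9)
        data = pd.DataFrame(rng.normal(size=(100_000, 4)),
                            columns=["a", "b", "c", "d"])
        res = principal_components(data, ["a", "b", "c", "d"])
        assert np.allclose(res.variance_explained, 0.25, atol=0.01)

    def test_scores_are_uncorrelated(self, bivariate):
        res = principal_components(bivariate, ["x1", "x2"])
        r = np.corrcoef(res.scores["PC1"], res.scores["PC2"])[0, 1]
        assert abs(r) < 1e-8

    def test_constant_column_named_in_error(self):
        data = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [5.0, 5.0, 5.0]})
        with pytest.raises(ValueError, match="b"):
            principal_components(data, ["a", "b"])


class TestResidualRegression:
    def test_exact_linear_response_gives_zero_residuals(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=(50, 2))
        data = pd.DataFrame({"y": 2 * x[:, 0] - x[:, 1] + 3,
                             "a": x[:, 0], "b": x[:, 1]})
        resid = residual_regression(data, "y", ["a", "b"])
        assert np.allclose(resid, 0, atol=1e-10)

    def test_residuals_orthogonal_to_predictors(self, condition_data):
        resid = residual_regression(condition_data, "mass", ["tarsus", "head", "wing"])
        sub = condition_data.loc[resid.index]
        for p in ("tarsus", "head", "wing"):
            assert abs(resid @ sub[p]) < 1e-8 * len(resid)
        assert abs(resid.sum()) < 1e-8 * len(resid)

    def test_coefficients_match_lstsq_oracle(self, condition_data):
        resid = residual_regression(condition_data, "mass", ["tarsus", "head", "wing"])
        X = np.column_stack([np.ones(len(condition_data)),
                             condition_data[["tarsus", "head", "wing"]]])
        b = np.linalg.lstsq(X, condition_data["mass"], rcond=None)[0]
        assert np.allclose(resid, condition_data["mass"] - X @ b, atol=1e-8)

    def test_rank_deficiency_rejected(self):
        data = pd.DataFrame({"y": [1.0, 2, 3, 4], "a": [1.0, 2, 3, 4],
                             "b": [2.0, 4, 6, 8]})
        with pytest.raises(ValueError, match="rank"):
            residual_regression(data, "y", ["a", "b"])


class TestStepwiseIndex:
    def test_index_equals_step2_linear_predictor(self, condition_data):
        res = stepwise_condition_index(condition_data)
        b = res.step2_coefficients
        phys = ["buffy_coat", "haematocrit", "cholesterol", "uric_acid",
                "corticosterone"]
        sub = condition_data.loc[res.step3_index.index]
        recomputed = (b["const"] + b["resid_mass"] * res.step1_residuals
                      + sub[phys].to_numpy() @ b[phys].to_numpy())
        assert np.allclose(res.step3_index, recomputed, atol=1e-10)

    def test_deterministic(self, condition_data):
        a = stepwise_condition_index(condition_data)
        b = stepwise_condition_index(condition_data)
        assert a.step2_coefficients.equals(b.step2_coefficients)
        assert a.step4_density_slope == b.step4_density_slope

    def test_no_confounding_limit_matches_sem(self):
        """With size and physiology uncorrelated (and mass free of the
        physiology), the stepwise slopes agree with the joint-SEM weights."""
        from condsem import TrueModel, fit_ml, simulate_dataset
        from condsem.builders import build_model
        from condsem.simulate import _condition_fixture

        tm = _condition_fixture()
        vals = dict(tm.values)
        # sever every confounding channel
        for k in list(vals):
            if " ~~ " in k:
                a, _, b = k.partition(" ~~ ")
                if a.strip() != b.strip() and not (
                        {a.strip(), b.strip()} <= {"tarsus", "head", "wing"}):
                    vals[k] = 0.0
        tm2 = TrueModel(spec=tm.spec, values=vals)
        data = simulate_dataset(tm2, 120_000, seed=77)

        res = stepwise_condition_index(data)
        fit = fit_ml(tm.spec, data)
        g = fit.estimate("survival", "~", "condition")
        sem = {c: g * fit.estimate("condition", "<~", c)
               for c in ["scm", "corticosterone"]}
        assert res.step2_coefficients["resid_mass"] == pytest.approx(
            sem["scm"], abs=0.02)
        assert res.step2_coefficients["corticosterone"] == pytest.approx(
            sem["corticosterone"], abs=0.02)
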