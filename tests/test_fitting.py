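import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from statsmodels.multivariate.manova import MANOVA

from anthrocomp import (
    SingularDesignError,
    collinearity_ratio,
    fit_multivariate_least_squares,
    pillai_trace,
    pillai_trace_test,
    select_common_predictors,
)
from conftest import random_problem


class TestMultivariateLeastSquares:
    def test_noise_free_identity(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame(rng.normal(size=(12, 3)), columns=list("abc"))
        fit = fit_multivariate_least_squares(X, X.copy())
        np.testing.assert_allclose(fit.beta_hat.to_numpy(), np.eye(3), atol=1e-12)
        np.testing.assert_allclose(fit.residuals.to_numpy(), 0, atol=1e-12)
        np.testing.assert_allclose(fit.r2.to_numpy(), 1.0, atol=1e-12)

    def test_single_column_closed_form(self, toy_xy):
        X, Y = toy_xy
        fit = fit_multivariate_least_squares(X, Y)
        # no-intercept slope = sum(xy)/sum(x^2) = 28/30
        assert fit.beta_hat.iloc[0, 0] == pytest.approx(28 / 30, abs=1e-12)

    @pytest.mark.parametrize("seed", range(10))
    def test_columnwise_equivalence(self, seed):
        X, Y = random_problem(seed)
        fit = fit_multivariate_least_squares(X, Y)
        for j, col in enumerate(Y.columns):
            uni, *_ = np.linalg.lstsq(X.to_numpy(), Y[col].to_numpy(), rcond=None)
            np.testing.assert_allclose(
                fit.beta_hat[col].to_numpy(), uni, rtol=0, atol=1e-10
            )

    @pytest.mark.parametrize("seed", range(5))
    def test_normal_equations_agree_with_qr(self, seed):
        X, Y = random_problem(seed)
        fit = fit_multivariate_least_squares(X, Y)
        qr_beta, *_ = np.linalg.lstsq(X.to_numpy(), Y.to_numpy(), rcond=None)
        np.testing.assert_allclose(fit.beta_hat.to_numpy(), qr_beta, rtol=1e-8)

    def test_matches_statsmodels_with_intercept(self):
        X, Y = random_problem(3)
        fit = fit_multivariate_least_squares(X, Y, include_intercept=True)
        sm_fit = sm.OLS(Y["y0"], sm.add_constant(X)).fit()
        np.testing.assert_allclose(
            fit.beta_hat["y0"].to_numpy(), sm_fit.params.to_numpy(), rtol=1e-9
        )
        assert fit.r2["y0"] == pytest.approx(sm_fit.rsquared, abs=1e-12)
        assert fit.adj_r2["y0"] == pytest.approx(sm_fit.rsquared_adj, abs=1e-12)

    def test_no_intercept_r2_uses_uncentered_tss(self):
        # R convention for no-intercept fits: R^2 = 1 - SSE / sum(y^2)
        X, Y = random_problem(4)
        fit = fit_multivariate_least_squares(X, Y)
        sm_fit = sm.OLS(Y["y1"], X).fit()
        assert fit.r2["y1"] == pytest.approx(sm_fit.rsquared, abs=1e-12)
        assert fit.adj_r2["y1"] == pytest.approx(sm_fit.rsquared_adj, abs=1e-12)
        assert fit.see_residual["y1"] == pytest.approx(
            np.sqrt(sm_fit.ssr / sm_fit.df_resid), abs=1e-12
        )

    @pytest.mark.parametrize("seed", range(5))
    def test_hat_diagonals_sum_to_p(self, seed):
        X, Y = random_problem(seed)
        fit = fit_multivariate_least_squares(X, Y)
        h = fit.hat_diagonals.to_numpy()
        assert np.all(h >= -1e-12) and np.all(h <= 1 + 1e-12)
        assert h.sum() == pytest.approx(fit.p, abs=1e-9)

    def test_rank_deficiency_names_column(self):
        rng = np.random.default_rng(1)
        X = pd.DataFrame(rng.normal(size=(20, 2)), columns=["a", "b"])
        X["b_copy"] = X["b"]
        Y = pd.DataFrame(rng.normal(size=(20, 3)))
        with pytest.raises(SingularDesignError, match="b_copy"):
            fit_multivariate_least_squares(X, Y)

    def test_requires_more_rows_than_columns(self):
        X = pd.DataFrame(np.eye(3))
        with pytest.raises(ValueError, match="observations"):
            fit_multivariate_least_squares(X, X)


class TestPillai:
    def test_trace_kernel_trivial(self):
        assert pillai_trace(np.zeros((2, 2)), np.eye(2)) == pytest.approx(0.0)
        assert pillai_trace(np.eye(2), np.eye(2)) == pytest.approx(1.0)

    def test_no_effect_noise_free(self):
        rng = np.random.default_rng(5)
        X = pd.DataFrame(rng.normal(size=(30, 3)), columns=["a", "b", "c"])
        beta = np.zeros((3, 2))
        beta[:2] = rng.normal(size=(2, 2))  # c has exactly no effect
        Y = pd.DataFrame(X.to_numpy() @ beta, columns=["u", "v"])
        fit = fit_multivariate_least_squares(X, Y)
        test = pillai_trace_test(fit, ["c"])
        assert test.statistic == pytest.approx(0.0, abs=1e-9)

    def test_statistic_bounded_by_s(self):
        X, Y = random_problem(11, n=40, p=4)
        fit = fit_multivariate_least_squares(X, Y)
        terms = list(X.columns[:2])
        test = pillai_trace_test(fit, terms)
        assert 0 <= test.statistic <= test.s + 1e-12

    def test_matches_statsmodels_manova(self):
        rng = np.random.default_rng(7)
        n = 40
        X = pd.DataFrame(rng.normal(size=(n, 2)), columns=["x1", "x2"])
        Y = pd.DataFrame(
            X.to_numpy() @ rng.normal(size=(2, 3)) + rng.normal(size=(n, 3)),
            columns=["y1", "y2", "y3"],
        )
        fit = fit_multivariate_least_squares(X, Y, include_intercept=True)
        mine = pillai_trace_test(fit, ["x2"])
        df = pd.concat([Y, X], axis=1)
        mv = MANOVA.from_formula("y1 + y2 + y3 ~ x1 + x2", data=df)
        ref = mv.mv_test().results["x2"]["stat"].loc["Pillai's trace"]
        assert mine.statistic == pytest.approx(ref["Value"], abs=1e-9)
        assert mine.f_value == pytest.approx(ref["F Value"], rel=1e-9)
        assert mine.p_value == pytest.approx(ref["Pr > F"], abs=1e-12)

    def test_empty_terms_rejected(self):
        X, Y = random_problem(2)
        fit = fit_multivariate_least_squares(X, Y)
        with pytest.raises(ValueError):
            pillai_trace_test(fit, [])


class TestCollinearity:
    def test_orthonormal_is_weak(self):
        X = np.eye(4)
        report = collinearity_ratio(X)
        assert report.lambda_ratio == pytest.approx(1.0, abs=1e-12)
        assert report.category == "weak"

    def test_scaled_diagonal_ratio(self):
        X = np.diag([1.0, 2.0])
        report = collinearity_ratio(X)
        assert report.lambda_ratio == pytest.approx(4.0, abs=1e-12)
        assert report.category == "weak"

    @pytest.mark.parametrize(
        "scale,category",
        [(10.0, "moderate"), (np.sqrt(1000.0), "moderate"), (40.0, "severe")],
    )
    def test_band_boundaries(self, scale, category):
        # eigenvalue ratio = scale^2; 100 and 1000 classify as moderate
        X = np.diag([1.0, scale])
        assert collinearity_ratio(X).category == category

    def test_duplicated_column_flags_singular(self):
        rng = np.random.default_rng(3)
        col = rng.normal(size=12)
        X = np.column_stack([col, col])
        report = collinearity_ratio(X)
        assert report.category == "severe"
        assert report.singular


class TestSelection:
    def test_generating_columns_recovered(self):
        rng = np.random.default_rng(10)
        n = 500
        X = pd.DataFrame(
            rng.normal(size=(n, 6)), columns=[f"x{j}" for j in range(6)]
        )
        beta = np.array([[1.0, -0.8, 0.5], [0.7, 1.2, -0.9]])
        Y = pd.DataFrame(
            X[["x1", "x4"]].to_numpy() @ beta + rng.normal(scale=0.3, size=(n, 3)),
            columns=["u", "v", "w"],
        )
        trace = select_common_predictors(X, Y)
        assert set(trace.final) == {"x1", "x4"}
        # oracle: exhaustive scoring over all 2-subsets picks the same pair
        from itertools import combinations
        def sse(cols):
            arr = X[list(cols)].to_numpy()
            _, res, *_ = np.linalg.lstsq(arr, Y.to_numpy(), rcond=None)
            return res.sum()
        best = min(combinations(X.columns, 2), key=sse)
        assert set(best) == set(trace.final)

    def test_pure_noise_selects_nothing_much(self):
        rng = np.random.default_rng(11)
        X = pd.DataFrame(rng.normal(size=(200, 5)),
                         columns=[f"x{j}" for j in range(5)])
        Y = pd.DataFrame(rng.normal(size=(200, 3)), columns=["u", "v", "w"])
        trace = select_common_predictors(X, Y, entry_alpha=0.01, removal_alpha=0.01)
        assert len(trace.final) <= 1

    def test_single_strong_candidate_retained(self):
        rng = np.random.default_rng(12)
        X = pd.DataFrame(
            {"signal": rng.normal(size=300), "noise": rng.normal(size=300)}
        )
        Y = pd.DataFrame(
            np.outer(X["signal"], [1.0, 0.5, -0.7]) + rng.normal(scale=0.2, size=(300, 3)),
            columns=["u", "v", "w"],
        )
        trace = select_common_predictors(X, Y)
        assert trace.final == ("signal",)

    def test_trace_is_replayable(self):
        rng = np.random.default_rng(13)
        X = pd.DataFrame(rng.normal(size=(150, 4)),
                         columns=[f"x{j}" for j in range(4)])
        Y = pd.DataFrame(
            X[["x0"]].to_numpy() @ np.array([[1.0, 1.0, 1.0]])
            + rng.normal(scale=0.5, size=(150, 3))
        )
        trace = select_common_predictors(X, Y)
        assert set(trace.final) <= set(trace.candidates)
        # final set reproducible by replaying the logged actions
        model = set()
        for step in trace.steps:
            if step["phase"] == "intersection":
                model = set(step["model"])
            elif step["phase"] == "joint" and step["action"] == "remove":
                model.discard(step["variable"])
        assert model == set(trace.final)

    def test_requires_two_candidates(self):
        X = pd.DataFrame({"only": np.arange(10.0)})
        Y = pd.DataFrame(np.random.default_rng(0).normal(size=(10, 3)))
        with pytest.raises(ValueError):
            select_common_predictors(X, Y)
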