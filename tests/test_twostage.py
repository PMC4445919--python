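"""Stage I / Stage II estimators, collinearity guards, and role handling."""

import numpy as np
import pandas as pd
import pytest

from scorebias import (
    CollinearityError,
    EstimationError,
    RoleSpec,
    RoleSpecError,
    SchemaError,
    StageIFit,
    check_collinearity,
    fit_cox,
    fit_linear,
    predict_score,
    run_two_stage,
)
from scorebias.twostage import SCORE_TERM


class TestFitLinear:
    def test_three_point_closed_form(self):
        fit = fit_linear(pd.DataFrame({"x": [0.0, 1.0, 2.0]}), [1.0, 2.0, 3.0])
        assert fit.params["const"] == pytest.approx(1.0)
        assert fit.params["x"] == pytest.approx(1.0)
        assert fit.r2 == pytest.approx(1.0)

    def test_noiseless_exact_recovery(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame(rng.standard_normal((50, 3)), columns=list("abc"))
        y = 2.0 - 1.5 * X["a"] + 0.25 * X["b"] + 4.0 * X["c"]
        fit = fit_linear(X, y)
        np.testing.assert_allclose(
            fit.params[["const", "a", "b", "c"]], [2.0, -1.5, 0.25, 4.0],
            atol=1e-10)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(1)
        X = pd.DataFrame(rng.standard_normal((5, 2)), columns=["u", "v"])
        y = rng.standard_normal(5)
        fit = fit_linear(X, y)
        # brute-force normal equations, built without statsmodels
        A = np.column_stack([np.ones(5), X.to_numpy()])
        beta = np.linalg.solve(A.T @ A, A.T @ y)
        np.testing.assert_allclose(fit.params.to_numpy(), beta, rtol=1e-10)

    def test_rank_deficient_design_names_columns(self):
        X = pd.DataFrame({"a": [1.0, 2.0, 3.0, 4.0, 5.0]})
        X["b"] = 2 * X["a"]
        X["c"] = np.random.default_rng(2).standard_normal(5)
        with pytest.raises(CollinearityError) as exc:
            fit_linear(X, np.arange(5.0))
        assert {"a", "b"} <= set(exc.value.columns)

    def test_too_few_rows(self):
        with pytest.raises(EstimationError):
            fit_linear(pd.DataFrame({"x": [1.0, 2.0]}), [0.0, 1.0])


class TestCheckCollinearity:
    def test_score_as_linear_combination_names_all_three(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame({"x": rng.standard_normal(40),
                           "z": rng.standard_normal(40)})
        df["score"] = 0.4 * df["x"] + 0.2 * df["z"]
        with pytest.raises(CollinearityError) as exc:
            check_collinearity(df)
        assert set(exc.value.columns) == {"x", "z", "score"}

    def test_orthonormal_design_passes(self):
        q, _ = np.linalg.qr(np.random.default_rng(4).standard_normal((30, 4)))
        check_collinearity(pd.DataFrame(q, columns=list("abcd")))

    def test_duplicated_column_names_the_pair(self):
        rng = np.random.default_rng(5)
        df = pd.DataFrame({"a": rng.standard_normal(20)})
        df["b"] = df["a"]
        df["c"] = rng.standard_normal(20)
        with pytest.raises(CollinearityError) as exc:
            check_collinearity(df)
        assert set(exc.value.columns) == {"a", "b"}


class TestPredictScore:
    def _fit(self, params, predictors):
        names = ["const", *predictors]
        return StageIFit(params=pd.Series(params, index=names),
                         bse=pd.Series(0.0, index=names),
                         resid_var=1.0, r2=0.5, n_used=10,
                         predictors=tuple(predictors))

    def test_constant_model(self):
        fit = self._fit([3.5, 0.0, 0.0], ["x", "z"])
        cov = pd.DataFrame({"x": [1.0, -2.0], "z": [0.0, 5.0]})
        np.testing.assert_allclose(predict_score(fit, cov), [3.5, 3.5])

    def test_linear_combination_arithmetic(self):
        fit = self._fit([0.0, 0.4, 0.2], ["x", "z"])
        cov = pd.DataFrame({"x": [1.0], "z": [2.0]})
        assert predict_score(fit, cov)[0] == pytest.approx(0.8)

    def test_missing_predictor_is_schema_error(self):
        fit = self._fit([0.0, 1.0], ["x"])
        with pytest.raises(SchemaError, match="x"):
            predict_score(fit, pd.DataFrame({"z": [1.0]}))

    def test_fitted_values_average_to_measured_mean(self, cohort_5000):
        fit = fit_linear(cohort_5000[["x", "z1"]], cohort_5000["D"])
        scores = predict_score(fit, cohort_5000)
        # OLS fitted values share the response mean on the fitting rows
        assert scores.mean() == pytest.approx(cohort_5000["D"].mean(),
                                              abs=1e-10)


class TestRoleSpec:
    def test_instruments_are_stage1_minus_stage2(self):
        spec = RoleSpec(outcome_kind="survival",
                        stage1_predictors=("x", "z1", "z2"),
                        stage2_covariates=("x", "y"))
        assert spec.instruments == ("z1", "z2")

    def test_empty_instruments_rejected(self):
        with pytest.raises(RoleSpecError, match="instrument"):
            RoleSpec(outcome_kind="survival",
                     stage1_predictors=("x",),
                     stage2_covariates=("x", "y"))

    def test_exposure_among_predictors_rejected(self):
        with pytest.raises(RoleSpecError):
            RoleSpec(outcome_kind="survival",
                     stage1_predictors=("x", "D"),
                     stage2_covariates=("x",), exposure_col="D")

    def test_bad_outcome_kind_and_fraction(self):
        with pytest.raises(RoleSpecError):
            RoleSpec(outcome_kind="logistic", stage1_predictors=("z",))
        with pytest.raises(RoleSpecError):
            RoleSpec(outcome_kind="survival", stage1_predictors=("z",),
                     stage1_subset_fraction=0.0)


class TestRunTwoStage:
    def test_survival_pipeline_scores_and_terms(self, cohort_5000):
        spec = RoleSpec(outcome_kind="survival",
                        stage1_predictors=("x", "z1", "z2"),
                        stage2_covariates=("x", "y", "z1"))
        res = run_two_stage(cohort_5000, spec)
        assert len(res.scores) == len(cohort_5000)
        assert list(res.stage2.index) == ["x", "y", "z1", SCORE_TERM]
        # valid instrument (z2): score coefficient near the true theta=0.5
        row = res.stage2.loc[SCORE_TERM]
        assert abs(row["coef"] - 0.5) < 3 * row["se"]

    def test_invalid_instrument_biases_score(self, cohort_5000):
        spec = RoleSpec(outcome_kind="survival",
                        stage1_predictors=("x", "z1"),
                        stage2_covariates=("x", "y"))
        res = run_two_stage(cohort_5000, spec)
        # delta1/d1 = 2 pushes the estimate far from theta=0.5
        assert res.score_estimate > 2.0

    def test_continuous_pipeline(self, applied_params):
        from scorebias import simulate_applied_cohort

        data = simulate_applied_cohort(applied_params, 4002, seed=10)
        spec = RoleSpec(outcome_kind="continuous",
                        stage1_predictors=("age", "male", "overweight"),
                        stage2_covariates=("age", "male"),
                        response_col="sbp")
        res = run_two_stage(data, spec)
        assert SCORE_TERM in res.stage2.index
        assert res.stage1.n_used == 4002

    def test_exposure_missingness_restricts_stage1_not_scores(self,
                                                              cohort_5000):
        data = cohort_5000.copy()
        data.loc[data.index[2000:], "D"] = np.nan
        spec = RoleSpec(outcome_kind="survival",
                        stage1_predictors=("x", "z1", "z2"),
                        stage2_covariates=("x", "y", "z1"))
        res = run_two_stage(data, spec)
        assert res.stage1.n_used == 2000
        assert len(res.scores) == 5000 and np.isfinite(res.scores).all()

    def test_subset_fraction_uses_fewer_rows_same_estimate(self,
                                                           cohort_5000):
        spec_full = RoleSpec(outcome_kind="survival",
                             stage1_predictors=("x", "z1", "z2"),
                             stage2_covariates=("x", "y", "z1"))
        spec_half = RoleSpec(outcome_kind="survival",
                             stage1_predictors=("x", "z1", "z2"),
                             stage2_covariates=("x", "y", "z1"),
                             stage1_subset_fraction=0.5)
        full = run_two_stage(cohort_5000, spec_full)
        half = run_two_stage(cohort_5000, spec_half, seed=0)
        assert half.stage1.n_used == 2500
        # halving Stage I data inflates Stage I uncertainty ...
        assert (half.stage1.bse > full.stage1.bse).all()
        # ... but leaves the score estimate consistent within joint noise
        se = np.hypot(half.stage2.loc[SCORE_TERM, "se"],
                      full.stage2.loc[SCORE_TERM, "se"])
        assert abs(half.score_estimate - full.score_estimate) < 4 * se

    def test_missing_columns_is_schema_error(self, cohort_5000):
        spec = RoleSpec(outcome_kind="survival",
                        stage1_predictors=("x", "nope"),
                        stage2_covariates=("x", "y"))
        with pytest.raises(SchemaError, match="nope"):
            run_two_stage(cohort_5000, spec)


def test_fit_cox_rejects_constant_column(cohort_5000):
    df = cohort_5000[["x", "y"]].copy()
    df["flat"] = 0.0
    with pytest.raises(EstimationError):
        fit_cox(df, cohort_5000["time"], cohort_5000["event"])
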