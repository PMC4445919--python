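"""The two-stage predicted-exposure-score estimator.

Stage I regresses the measured exposure (serum 25(OH)D) on its determinants
by ordinary least squares within the subset of subjects where the exposure
was measured.  The fitted values — the "predicted 25(OH)D score" — are then
computed for *every* subject, including those with measured values, and
Stage II fits the outcome model (Cox proportional hazards for survival
outcomes, OLS for continuous ones) on the declared Stage II covariates plus
the score.

Stage I predictors that do not appear in Stage II are the *instruments*.
At least one instrument is required: if every Stage I predictor also sits in
Stage II, the score is an exact linear combination of Stage II columns and
the design is collinear.  The estimator refuses to drop a column silently;
it raises :class:`~scorebias.exceptions.CollinearityError` naming the
dependent columns instead.

Stage II standard errors are conventional (Wald) and do not propagate the
sampling uncertainty of the Stage I coefficients.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .coxph import fit_cox_breslow
from .exceptions import (
    CollinearityError,
    EstimationError,
    RoleSpecError,
    SchemaError,
)
from .simulate import as_rng

__all__ = [
    "RoleSpec",
    "StageIFit",
    "TwoStageResult",
    "SCORE_TERM",
    "fit_linear",
    "fit_cox",
    "predict_score",
    "check_collinearity",
    "run_two_stage",
]

#: name under which the predicted score appears in Stage II estimate tables
SCORE_TERM = "score"

#: columns of every per-term estimate table produced here
ESTIMATE_COLUMNS = ("coef", "se", "ci_low", "ci_high", "p")


@dataclass(frozen=True)
class RoleSpec:
    """Variable-role assignment defining one two-stage analysis.

    Parameters
    ----------
    outcome_kind : {"survival", "continuous"}
        Chooses the Stage II model: Cox proportional hazards or OLS.
    stage1_predictors : tuple of str
        Determinants of the exposure used in the Stage I regression.
    stage2_covariates : tuple of str
        Covariates entering the Stage II outcome model alongside the score.
    exposure_col : str
        Column holding the (possibly partially missing) measured exposure.
    time_col, event_col : str
        Survival outcome columns (used when ``outcome_kind == "survival"``).
    response_col : str
        Continuous outcome column (used when ``outcome_kind == "continuous"``).
    stage1_subset_fraction : float
        Fraction of the measured-exposure rows used to fit Stage I
        (default 1.0, i.e. all rows with a measured exposure).
    """

    outcome_kind: str
    stage1_predictors: tuple = ()
    stage2_covariates: tuple = ()
    exposure_col: str = "D"
    time_col: str = "time"
    event_col: str = "event"
    response_col: str = "sbp"
    stage1_subset_fraction: float = 1.0

    def __post_init__(self):
        if self.outcome_kind not in ("survival", "continuous"):
            raise RoleSpecError(
                f"outcome_kind must be 'survival' or 'continuous', "
                f"got {self.outcome_kind!r}"
            )
        object.__setattr__(self, "stage1_predictors",
                           tuple(self.stage1_predictors))
        object.__setattr__(self, "stage2_covariates",
                           tuple(self.stage2_covariates))
        if len(set(self.stage1_predictors)) != len(self.stage1_predictors):
            raise RoleSpecError("duplicate names in stage1_predictors")
        if not self.instruments:
            raise RoleSpecError(
                "no instruments: every Stage I predictor also appears in "
                "Stage II, so the predicted score would be collinear with "
                "the Stage II covariates"
            )
        forbidden = {self.exposure_col} & (
            set(self.stage1_predictors) | set(self.stage2_covariates)
        )
        if forbidden:
            raise RoleSpecError(
                f"exposure column {sorted(forbidden)} may not appear among "
                "the predictors or Stage II covariates"
            )
        if not 0.0 < self.stage1_subset_fraction <= 1.0:
            raise RoleSpecError(
                "stage1_subset_fraction must be in (0, 1], got "
                f"{self.stage1_subset_fraction}"
            )

    @property
    def instruments(self) -> tuple:
        """Stage I predictors excluded from Stage II."""
        s2 = set(self.stage2_covariates)
        return tuple(p for p in self.stage1_predictors if p not in s2)


@dataclass
class StageIFit:
    """OLS fit of the exposure on its determinants.

    ``params``/``bse`` are indexed by ``const`` plus the predictor names.
    """

    params: pd.Series
    bse: pd.Series
    resid_var: float
    r2: float
    n_used: int
    predictors: tuple = ()

    @property
    def coefficients(self) -> pd.Series:
        """Slope coefficients only (no intercept)."""
        return self.params.drop("const")


@dataclass
class TwoStageResult:
    """Everything produced by one two-stage analysis."""

    stage1: StageIFit
    scores: np.ndarray
    stage2: pd.DataFrame  # index: term names incl. SCORE_TERM; ESTIMATE_COLUMNS
    spec: RoleSpec = None

    @property
    def score_estimate(self) -> float:
        return float(self.stage2.loc[SCORE_TERM, "coef"])


def check_collinearity(design: pd.DataFrame, tol: float = 1e-8) -> None:
    """Raise :class:`CollinearityError` if the design is rank deficient.

    The implicated columns are read off the right singular vector belonging
    to the smallest singular value, so the error names the actual dependent
    set (e.g. ``{x, z, score}`` when the score is a linear combination of x
    and z) rather than an arbitrary dropped column.
    """
    X = design.to_numpy(dtype=float)
    if X.shape[1] == 0:
        return
    # scale columns to unit norm so the tolerance is relative
    norms = np.linalg.norm(X, axis=0)
    norms[norms == 0] = 1.0
    _, s, vt = np.linalg.svd(X / norms, full_matrices=False)
    if s[-1] > tol * max(s[0], 1.0):
        return
    null = vt[-1]
    implicated = [
        c for c, v in zip(design.columns, null) if abs(v) > 1e-6
    ]
    constant = [c for c, nz in zip(design.columns, np.linalg.norm(X, axis=0))
                if nz == 0]
    raise CollinearityError(implicated or constant or list(design.columns))


def fit_linear(design: pd.DataFrame, response) -> StageIFit:
    """Ordinary least squares with an intercept.

    Raises :class:`CollinearityError` on a rank-deficient design and
    :class:`EstimationError` when there are not more rows than parameters.
    """
    y = np.asarray(response, dtype=float)
    n, p = design.shape
    if n <= p + 1:
        raise EstimationError(
            f"need n > {p + 1} rows to fit {p} predictors plus an "
            f"intercept, got n={n}"
        )
    check_collinearity(design)
    X = sm.add_constant(design.to_numpy(dtype=float), has_constant="add")
    res = sm.OLS(y, X).fit()
    names = ["const", *design.columns]
    return StageIFit(
        params=pd.Series(res.params, index=names),
        bse=pd.Series(res.bse, index=names),
        resid_var=float(res.mse_resid),
        r2=float(res.rsquared),
        n_used=n,
        predictors=tuple(design.columns),
    )


def _estimate_table(names, coef, se, pvals) -> pd.DataFrame:
    coef = np.asarray(coef, dtype=float)
    se = np.asarray(se, dtype=float)
    return pd.DataFrame(
        {
            "coef": coef,
            "se": se,
            "ci_low": coef - 1.959963984540054 * se,
            "ci_high": coef + 1.959963984540054 * se,
            "p": np.asarray(pvals, dtype=float),
        },
        index=pd.Index(names, name="term"),
    )


def fit_cox(covariates: pd.DataFrame, time, event) -> pd.DataFrame:
    """Cox proportional hazards fit; per-term (coef, se, ci_low, ci_high, p).

    Partial likelihood is maximized by Newton-Raphson with Breslow handling
    of ties; confidence limits and p-values are Wald.
    """
    event = np.asarray(event)
    if int(np.sum(event != 0)) == 0:
        raise EstimationError("no events in the data; Cox model unidentified")
    degenerate = [c for c in covariates.columns
                  if covariates[c].nunique() <= 1]
    if degenerate:
        raise EstimationError(
            f"constant covariate column(s) {degenerate}: not identifiable "
            "in a Cox model (absorbed by the baseline hazard)"
        )
    check_collinearity(covariates)
    res = fit_cox_breslow(
        covariates.to_numpy(dtype=float),
        np.asarray(time, dtype=float),
        event,
        names=list(covariates.columns),
    )
    return _estimate_table(res.names, res.params, res.bse, res.pvalues)


def _fit_continuous(covariates: pd.DataFrame, response) -> pd.DataFrame:
    fit = fit_linear(covariates, response)
    X = sm.add_constant(covariates.to_numpy(dtype=float), has_constant="add")
    res = sm.OLS(np.asarray(response, dtype=float), X).fit()
    names = ["const", *covariates.columns]
    return _estimate_table(names, res.params, res.bse, res.pvalues)


def predict_score(fit: StageIFit, cov: pd.DataFrame) -> np.ndarray:
    """Predicted exposure score: intercept + sum of coefficient * column.

    Applied to every row handed in — the score replaces the measured
    exposure even where a measurement exists.
    """
    missing = [c for c in fit.predictors if c not in cov.columns]
    if missing:
        raise SchemaError(
            f"cannot predict scores: column(s) {missing} absent from data"
        )
    score = np.full(len(cov), float(fit.params["const"]))
    for name in fit.predictors:
        score = score + float(fit.params[name]) * cov[name].to_numpy(dtype=float)
    return score


def _stage1_rows(data: pd.DataFrame, spec: RoleSpec, seed):
    measured = data.index[data[spec.exposure_col].notna()]
    if len(measured) == 0:
        raise EstimationError(
            f"no rows with a measured exposure ({spec.exposure_col!r}); "
            "Stage I cannot be fitted"
        )
    if spec.stage1_subset_fraction >= 1.0:
        return measured
    k = max(int(round(spec.stage1_subset_fraction * len(measured))), 1)
    rng = as_rng(seed)
    chosen = rng.choice(len(measured), size=k, replace=False)
    return measured[np.sort(chosen)]


def run_two_stage(data: pd.DataFrame, spec: RoleSpec, seed=None) -> TwoStageResult:
    """Run the full two-stage pipeline on one dataset.

    Stage I is fitted on the rows with a measured exposure (optionally a
    random ``stage1_subset_fraction`` of them, drawn with ``seed``); scores
    are predicted for all rows; Stage II regresses the outcome on
    ``stage2_covariates`` plus the score.  The measured exposure never
    enters Stage II.
    """
    required = set(spec.stage1_predictors) | set(spec.stage2_covariates)
    required.add(spec.exposure_col)
    if spec.outcome_kind == "survival":
        required |= {spec.time_col, spec.event_col}
    else:
        required.add(spec.response_col)
    missing = sorted(required - set(data.columns))
    if missing:
        raise SchemaError(f"data lacks required column(s) {missing}")

    rows = _stage1_rows(data, spec, seed)
    stage1 = fit_linear(
        data.loc[rows, list(spec.stage1_predictors)],
        data.loc[rows, spec.exposure_col],
    )
    scores = predict_score(stage1, data)

    design = data[list(spec.stage2_covariates)].copy()
    design[SCORE_TERM] = scores
    # hard guard: no instrument may leak into the Stage II design
    leaked = set(spec.instruments) & set(design.columns)
    assert not leaked, f"instrument(s) {sorted(leaked)} leaked into Stage II"

    if spec.outcome_kind == "survival":
        stage2 = fit_cox(design, data[spec.time_col], data[spec.event_col])
    else:
        stage2 = _fit_continuous(design, data[spec.response_col])
    return TwoStageResult(stage1=stage1, scores=scores, stage2=stage2,
                          spec=spec)
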