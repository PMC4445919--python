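"""Synthetic cohort generators.

Two families of cohorts are produced:

* an abstract survival cohort in which serum 25(OH)D concentration ``D`` is a
  linear function of standard-normal determinants (one common covariate ``x``
  and two candidate instruments ``z1``, ``z2``) plus uniform noise, and the
  hazard of the outcome depends on ``x``, an outcome-only covariate ``y``,
  ``z1`` and the true ``D``; and

* an "applied" blood-pressure cohort mimicking a national health survey:
  age, sex and overweight status generate 25(OH)D (ng/mL) and systolic blood
  pressure (mmHg) through two linear structural equations.

Event times come from a constant baseline hazard, so the inverse-transform
draw ``T = -log(U) / (h0 * exp(lp))`` is exact, and no censoring is applied:
every subject's event is observed.  All generators are deterministic given
``(params, n, seed)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import SchemaError

__all__ = [
    "VitDModelParams",
    "HazardModelParams",
    "AppliedModelParams",
    "draw_covariates",
    "simulate_vitd",
    "simulate_survival_times",
    "simulate_cohort",
    "simulate_applied_cohort",
]

#: canonical covariate columns of the abstract simulation
COVARIATE_COLUMNS = ("x", "z1", "z2", "y")


def as_rng(seed) -> np.random.Generator:
    """Coerce an integer seed or an existing Generator to a Generator.

    Passing a Generator lets composed operations consume one stream
    sequentially, which keeps a whole cohort reproducible from a single seed.
    """
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass(frozen=True)
class VitDModelParams:
    """Structural equation for 25(OH)D: D = a0 + a1*x + d1*z1 + d2*z2 + e.

    ``e`` is uniform on ``(noise_low, noise_high)``.  Defaults are the
    canonical simulation setting: a0=0.1, a1=0.4, d1=0.2, d2=0.3 with
    noise uniform on (-0.5, 0.5).
    """

    a0: float = 0.1
    a1: float = 0.4
    d1: float = 0.2
    d2: float = 0.3
    noise_low: float = -0.5
    noise_high: float = 0.5

    def __post_init__(self):
        # equality is allowed: a zero-width interval means noiseless D,
        # useful for closed-form checks
        if self.noise_low > self.noise_high:
            raise ValueError(
                f"noise_low ({self.noise_low}) must be <= noise_high "
                f"({self.noise_high})"
            )


@dataclass(frozen=True)
class HazardModelParams:
    """Proportional-hazards outcome model H(t) = h0 * exp(alpha1*x + beta*y +
    delta1*z1 + theta*D).

    ``delta1`` is the direct effect of the candidate instrument ``z1`` on the
    outcome; ``z1`` is a valid instrument only when ``delta1 == 0``.  ``z2``
    never enters the hazard, so it is always valid.  Defaults: alpha1=0.1,
    beta=0.3, delta1=0.4, theta=0.5, h0=1.
    """

    alpha1: float = 0.1
    beta: float = 0.3
    delta1: float = 0.4
    theta: float = 0.5
    h0: float = 1.0

    def __post_init__(self):
        if not self.h0 > 0:
            raise ValueError(f"baseline hazard h0 must be > 0, got {self.h0}")


@dataclass(frozen=True)
class AppliedModelParams:
    """Structural coefficients of the applied blood-pressure cohort.

    25(OH)D (ng/mL) and systolic blood pressure (mmHg) are generated as

        D   = d_const + d_age*age + d_male*male + d_overweight*overweight
              + Normal(0, d_resid_sd)
        sbp = sbp_const + sbp_age*age + sbp_male*male
              + sbp_overweight*overweight + sbp_d*D + Normal(0, sbp_resid_sd)

    so that large-sample regressions of sbp on (age, male, overweight, D)
    and of D on (age, male, overweight) recover the two coefficient sets.
    Age is normal truncated below at ``age_min`` years; male and overweight
    are independent Bernoulli.  Defaults are calibrated to a published
    NHANES 2005-06 analysis of 4,002 adults (overweight prevalence
    2717/4002, male 1941/4002); the residual SDs reproduce Stage I /
    outcome-model adjusted R^2 of roughly 0.02 / 0.24 and affect precision
    only, not the bias decomposition.
    """

    # sbp structural equation (mmHg)
    sbp_const: float = 102.63
    sbp_age: float = 0.42
    sbp_male: float = 3.71
    sbp_overweight: float = 3.13
    sbp_d: float = -0.16
    sbp_resid_sd: float = 15.5
    # 25(OH)D structural equation (ng/mL)
    d_const: float = 22.89
    d_age: float = 0.02
    d_male: float = -0.28
    d_overweight: float = -3.16
    d_resid_sd: float = 8.0
    # covariate distributions
    p_male: float = 0.485
    p_overweight: float = 0.679
    age_mean: float = 44.6
    age_sd: float = 18.8
    age_min: float = 18.0

    def __post_init__(self):
        for name in ("p_male", "p_overweight"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        for name in ("sbp_resid_sd", "d_resid_sd", "age_sd"):
            s = getattr(self, name)
            if s < 0:
                raise ValueError(f"{name} must be >= 0, got {s}")


def draw_covariates(n: int, seed) -> pd.DataFrame:
    """Draw ``n`` iid standard-normal values for each of x, z1, z2, y.

    ``x``, ``z1`` and ``z2`` are determinants of 25(OH)D; ``y`` is an
    outcome-only covariate, independent of the rest.
    """
    if n < 0:
        raise ValueError(f"n must be non-negative, got {n}")
    rng = as_rng(seed)
    draws = rng.standard_normal((int(n), len(COVARIATE_COLUMNS)))
    return pd.DataFrame(draws, columns=list(COVARIATE_COLUMNS))


def simulate_vitd(cov: pd.DataFrame, params: VitDModelParams, seed) -> np.ndarray:
    """Generate the exposure D = a0 + a1*x + d1*z1 + d2*z2 + e.

    The noise ``e`` is uniform on ``(noise_low, noise_high)``.
    """
    missing = [c for c in ("x", "z1", "z2") if c not in cov.columns]
    if missing:
        raise SchemaError(f"covariate table lacks required column(s) {missing}")
    rng = as_rng(seed)
    n = len(cov)
    e = rng.uniform(params.noise_low, params.noise_high, size=n)
    return (
        params.a0
        + params.a1 * cov["x"].to_numpy()
        + params.d1 * cov["z1"].to_numpy()
        + params.d2 * cov["z2"].to_numpy()
        + e
    )


def simulate_survival_times(linear_predictor, h0: float, seed):
    """Draw event times under a constant baseline hazard.

    With H(t) = h0 * exp(lp) constant in t, the survival time is exponential
    and the inverse-transform draw ``T = -log(U) / (h0 * exp(lp))`` is exact.

    Returns
    -------
    (time, event) : pair of ndarray
        ``event`` is identically 1: no censoring mechanism is simulated.
    """
    lp = np.asarray(linear_predictor, dtype=float)
    if not np.all(np.isfinite(lp)):
        raise ValueError("linear predictor contains non-finite values")
    if not h0 > 0:
        raise ValueError(f"baseline hazard h0 must be > 0, got {h0}")
    rng = as_rng(seed)
    u = rng.uniform(size=lp.shape[0])
    time = -np.log(u) / (h0 * np.exp(lp))
    return time, np.ones(lp.shape[0], dtype=int)


def simulate_cohort(
    vitd: VitDModelParams,
    hazard: HazardModelParams,
    n: int,
    seed,
) -> pd.DataFrame:
    """Generate a full survival cohort (columns x, z1, z2, y, D, time, event).

    The hazard uses the TRUE exposure D, so a Cox fit on (x, y, z1, D)
    is correctly specified and recovers the preset coefficients.  One RNG
    stream derived from ``seed`` is threaded through the three component
    draws, so the cohort is reproducible from the single seed.
    """
    rng = as_rng(seed)
    cov = draw_covariates(n, rng)
    d = simulate_vitd(cov, vitd, rng)
    lp = (
        hazard.alpha1 * cov["x"].to_numpy()
        + hazard.beta * cov["y"].to_numpy()
        + hazard.delta1 * cov["z1"].to_numpy()
        + hazard.theta * d
    )
    time, event = simulate_survival_times(lp, hazard.h0, rng)
    out = cov.copy()
    out["D"] = d
    out["time"] = time
    out["event"] = event
    return out


def _truncated_normal(mean, sd, lower, n, rng):
    """Normal(mean, sd) truncated below at ``lower``; degenerate sd allowed."""
    if sd == 0:
        return np.full(n, max(mean, lower), dtype=float)
    a = (lower - mean) / sd
    return stats.truncnorm.rvs(a, np.inf, loc=mean, scale=sd,
                               size=n, random_state=rng)


def simulate_applied_cohort(
    params: AppliedModelParams, n: int, seed
) -> pd.DataFrame:
    """Generate the applied cohort (columns age, male, overweight, D, sbp).

    Covariates are mutually independent: age truncated-normal, male and
    overweight Bernoulli.  D and sbp follow the structural equations in
    :class:`AppliedModelParams`.
    """
    if n <= 0:
        raise ValueError(f"n must be positive, got {n}")
    rng = as_rng(seed)
    age = _truncated_normal(params.age_mean, params.age_sd, params.age_min,
                            n, rng)
    male = (rng.uniform(size=n) < params.p_male).astype(int)
    overweight = (rng.uniform(size=n) < params.p_overweight).astype(int)
    d = (
        params.d_const
        + params.d_age * age
        + params.d_male * male
        + params.d_overweight * overweight
        + (rng.standard_normal(n) * params.d_resid_sd if params.d_resid_sd > 0
           else 0.0)
    )
    sbp = (
        params.sbp_const
        + params.sbp_age * age
        + params.sbp_male * male
        + params.sbp_overweight * overweight
        + params.sbp_d * d
        + (rng.standard_normal(n) * params.sbp_resid_sd
           if params.sbp_resid_sd > 0 else 0.0)
    )
    return pd.DataFrame(
        {"age": age, "male": male, "overweight": overweight, "D": d,
         "sbp": sbp}
    )
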