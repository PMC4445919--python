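# Methods

## The estimator

`run_two_stage` implements the predicted-exposure-score design. Stage I is
OLS of the measured exposure on the declared predictors, fitted on the rows
where the exposure is non-missing (optionally a seeded random
`stage1_subset_fraction` of them). Stage I includes an intercept: although
the score is sometimes written without one, a constant shift of the score
is absorbed by the Cox baseline hazard or the OLS intercept, so slope
inference is identical and the applied convention (an explicit constant) is
matched. Scores are predicted for *all* rows, including those with a
measured exposure, which never enters Stage II.

Stage II is a Cox proportional-hazards model (survival outcomes) or OLS
(continuous outcomes) on the declared Stage II covariates plus the score.
The Stage I predictors absent from Stage II are the instruments; the
`RoleSpec` constructor rejects configurations with no instrument, because
the score would then be an exact linear combination of Stage II columns.
`check_collinearity` detects any remaining exact dependence via the SVD
null vector (relative singular-value tolerance 1e-8) and raises an error
naming the implicated columns — nothing is dropped silently.

Stage II standard errors are conventional Wald errors from the observed
information (Cox) or the OLS covariance; they do **not** propagate Stage I
estimation uncertainty. This matches common applied practice, and the
Monte Carlo summaries report the empirical replicate spread alongside so
the understatement is visible.

## The Cox fitter

`fit_cox_breslow` maximises the Breslow partial likelihood by
Newton–Raphson: data are sorted by time once, risk-set sums S0/S1/S2 are
suffix cumulative sums (O(n·p²) per iteration), tied times share a risk
set, the linear predictor is centred before exponentiation, steps are
halved whenever the likelihood would decrease, and convergence requires a
relative log-partial-likelihood change below 1e-9 within 100 iterations.
Wald SEs come from the inverse observed information at the optimum.
Breslow ties were chosen because simulated times are continuous (ties have
probability zero) and Breslow is the simplest convention to state for real
rounded data; the tests cross-check tied data against an independent
implementation and tie-free data against lifelines (which uses Efron —
identical without ties).

## The bias theory

For one invalid instrument with direct outcome effect δ and Stage I
exposure coefficient d, the score coefficient converges to θ + δ/d. The
package treats this as *exact for a linear Stage II* and as a *first-order
approximation for a Cox Stage II*: the Stage I residual θ·e and any
exposure determinants omitted from Stage I act as unmodelled heterogeneity
(frailty) in the hazard and attenuate all log-hazard coefficients slightly
toward zero. At the canonical simulation parameters the attenuation is
about 3% (Monte Carlo mean ≈ 2.42 against the prediction 2.5), and the
test suite asserts the empirical estimate lies between θ and θ + δ/d
rather than exact equality.

`multi_instrument_bias_linear` generalises the ratio to several mutually
independent instruments in the linear case:
Σⱼ δⱼdⱼVar(zⱼ) / Σⱼ dⱼ²Var(zⱼ) — the projection of the omitted direct
effects onto the instrument-driven variation of the score. It is verified
against a large-n two-stage regression rather than derived symbolically.

Ratios with |d| < 1e-8 are reported as non-finite (`finite=False`) instead
of raising, so batch sweeps can skip the divergence; sensitivity curves
additionally skip grid points with |d| below 0.05, where the Monte Carlo
estimate is dominated by the near-singular Stage I projection.

## Synthetic cohorts

**Abstract survival cohort.** Determinants x, z1, z2 and the outcome-only
covariate y are iid standard normal; the exposure is
D = 0.1 + 0.4·x + 0.2·z1 + 0.3·z2 + e with e ~ Uniform(−0.5, 0.5); the
hazard is H(t) = h0·exp(0.1·x + 0.3·y + 0.4·z1 + 0.5·D) with h0 = 1. z1
has a direct outcome effect (δ1 = 0.4), so it is an invalid instrument
unless δ1 is set to 0; z2 is always valid. With a constant baseline
hazard, survival times are drawn exactly by inverse transform,
T = −ln(U)/(h0·e^lp). No censoring is generated (`event ≡ 1`) — the
estimator accepts censored data, but the study design observes every
event, and the event column exists so real data can flow through
unchanged.

**Specifications.** Spec I uses z1 as the only instrument (Stage I
{x, z1}, Stage II {x, y}); Spec II uses z1 and z2 (Stage I {x, z1, z2},
Stage II {x, y}); Spec III uses z2 only, with z1 kept as a Stage II
covariate (Stage I {x, z1, z2}, Stage II {x, y, z1}). Spec III is the
correct analysis. The Spec III reading with z1 present in both stages is
the one consistent with the benchmark estimates this package reproduces
(in particular the z1 coefficient ≈ 0.39, the direct effect alone, not
δ1 + θ·d1 = 0.5).

**Applied cohort.** Age ~ Normal(44.6, 18.8²) truncated at 18 years;
male ~ Bernoulli(0.485); overweight ~ Bernoulli(0.679); covariates mutually
independent (their correlations in the source survey are not published).
25(OH)D (ng/mL) and systolic blood pressure (mmHg) follow the two
structural equations in `AppliedModelParams`, with coefficients calibrated
to a published NHANES 2005–06 analysis of 4,002 adults (e.g. overweight:
−3.16 ng/mL on 25(OH)D, +3.13 mmHg on blood pressure; true exposure effect
−0.16 mmHg per ng/mL). Residual SDs default to 8 ng/mL (Stage I) and
15.5 mmHg (outcome), chosen so the adjusted R² of the two regressions are
of the published order (≈0.02 and ≈0.24); they affect precision only, not
the bias decomposition, and are configurable. Residual SDs of exactly 0
are permitted to expose the noiseless closed-form subject used in tests.

**Randomness.** Every generator accepts an integer seed or a NumPy
`Generator`; composed generators thread a single stream, so a cohort is a
deterministic function of `(params, n, seed)`. Monte Carlo replicate r
uses `root_seed + r`, making any replicate reproducible in isolation. The
experiment harness reuses one root seed across the three specifications,
so all three analyses see the same sequence of cohorts, and sweep levels
redraw cohorts independently.

## Monte Carlo scale and numerical choices

The reference experiment is 1,000 replicates of n = 5,000 per
specification (the scale used by `scripts/acceptance.py`; about 50 s total
with the vectorised Cox fitter). The test suite runs the same comparisons
at 200 replicates, which leaves the Monte Carlo standard error of each
mean near 0.005–0.008 — small against the effects being measured (bias of
~1.9 on a coefficient of 0.5) — and sizes its tolerances as 3 combined
Monte Carlo SEs plus the benchmark's printed rounding. Replicate-level
estimation failures are logged, skipped and counted; an experiment aborts
if more than 5% of replicates fail. Summary tables report both the
empirical 2.5–97.5 percentile interval of the replicate estimates and the
average per-fit Wald interval, since the two answer different questions
(spread of the estimator vs. the typical reported CI).

## Dichotomised scores

`dichotomization_experiment` replaces the score in Stage II by the
deficiency indicator `1{score < threshold}`. No analytic benchmark is
claimed for the resulting coefficient — the distortion depends on the
score distribution and the threshold, and its direction is not determined
by δ/d — so the experiment reports only the empirical distribution, and
the tests assert qualitative facts (sign, and sensitivity to instrument
validity).

## Known limitations

* Stage II inference ignores Stage I uncertainty (naive SEs).
* The applied generator draws covariates independently and residuals
  Gaussian; real survey data have correlated covariates, skewed exposure
  distributions, design weights and missingness mechanisms that are not
  emulated. Passing tests demonstrate the estimator and the bias algebra,
  not robustness to those features.
* No censoring, time-varying effects, stratification, competing risks or
  robust/sandwich errors; the multi-instrument bias formula assumes
  mutually independent instruments and a linear Stage II.
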