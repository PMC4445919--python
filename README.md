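# scorebias

Two-stage "predicted exposure score" estimation — and the bias it suffers
when an instrument is itself a risk factor for the outcome.

## The problem

Large health surveys often cannot measure an exposure such as serum
25-hydroxyvitamin D (25(OH)D) on every participant. A common workaround is
a two-stage analysis:

* **Stage I** — on the subset with measured exposure, fit an ordinary
  least-squares model `D = a·x + d·z + e`, where `x` are covariates shared
  with the outcome model and `z` are extra determinants.
* **Stage II** — compute the predicted score `D̂ = â·x + d̂·z` for everyone
  and fit the outcome model (Cox proportional hazards
  `H(t) = h0(t)·exp(α·x + β·y + θ·D̂)`, or OLS for continuous outcomes)
  using the score in place of the exposure.

The variables `z`, used in Stage I but excluded from Stage II, act as
**instrumental variables** — they must be excluded, because `D̂` is an exact
linear combination of the Stage I predictors. If an instrument has a direct
effect `δ` on the outcome (it violates the exclusion restriction), its
direct path is misattributed to the exposure, and the Stage II coefficient
on the score converges to

```
θ̂  →  θ + δ / d
```

where `d` is the instrument's Stage I coefficient. The bias `δ/d` grows
with the instrument's outcome effect and shrinks with its exposure effect;
it is unbounded as `d → 0`, and with several independent instruments
(linear Stage II) it generalises to `Σ δⱼdⱼVar(zⱼ) / Σ dⱼ²Var(zⱼ)`.

`scorebias` provides, for epidemiologists and methodologists studying this
design:

* the two-stage estimator (Cox or OLS Stage II) with variable-role
  declarations and hard collinearity guards (`scorebias.twostage`),
* a fast Newton–Raphson Cox partial-likelihood fitter, Breslow ties
  (`scorebias.coxph`),
* the analytic bias machinery: `δ/d`, the expected distorted estimate, the
  multi-instrument linear generalisation, and sensitivity curves
  (`scorebias.bias`),
* seeded synthetic-cohort generators, including a blood-pressure cohort
  calibrated to a published NHANES 2005–06 analysis (`scorebias.simulate`),
* a Monte Carlo harness comparing instrument configurations and sweeping
  instrument strength (`scorebias.montecarlo`),
* CSV/YAML I/O with run manifests, and a CLI (`scorebias.io`,
  `scorebias.cli`).

## Worked example

An end-to-end applied run (one synthetic cohort of 4,002 adults; systolic
blood pressure as outcome; overweight status as the — invalid — sole
instrument):

```bash
$ scorebias applied-demo --seed 1
(1) measured-exposure model: exposure coef -0.1418, overweight coef +2.5189
(2) Stage I: overweight coef -2.9604, R^2 0.0330
(3) two-stage score coef -0.9927
analytic bias delta/d = -0.8509; expected distorted estimate = -0.9927
```

Line (1) is the benchmark: regressing blood pressure on the *measured*
exposure gives −0.14 mmHg per ng/mL, while overweight independently raises
blood pressure by +2.52 mmHg. Line (2) shows overweight lowers 25(OH)D by
2.96 ng/mL in Stage I. Because overweight affects the outcome directly, the
two-stage score coefficient (line 3) is distorted to −0.99 — and the
analytic decomposition `θ + δ/d = −0.14 + 2.52/(−2.96)` predicts exactly
that. The bias ratio alone:

```bash
$ scorebias bias --delta 3.13 --d -3.16 --theta -0.16
bias: -0.990506
expected biased estimate: -1.15051
```

The Monte Carlo comparison of instrument configurations (Specification I:
invalid instrument only; II: invalid + valid; III: valid only, the correct
analysis):

```bash
$ scorebias table2 --reps 200 --n 5000 --seed 1 --out runs/table2
Monte Carlo two-stage estimates (200 reps x n=5000)
variable    preset  estimate            95% CI
Specification I
  x           0.10     -0.68   (-0.75, -0.62)
  y           0.30      0.29   (0.26, 0.32)
  D           0.50      2.43   (2.28, 2.58)
Specification II
  x           0.10     -0.13   (-0.17, -0.09)
  y           0.30      0.27   (0.25, 0.30)
  D           0.50      1.01   (0.93, 1.09)
Specification III
  x           0.10      0.10   (0.05, 0.15)
  y           0.30      0.30   (0.27, 0.33)
  z1          0.40      0.39   (0.36, 0.43)
  D           0.50      0.49   (0.40, 0.59)
```

With the invalid instrument the exposure effect (preset θ = 0.5) is
estimated near 2.4 — almost five-fold — and even the sign of the `x`
coefficient flips; only the valid-instrument analysis recovers every
preset. Other subcommands: `simulate`, `two-stage`, `bias-curve`, `sweep`
(see `scorebias --help`).

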