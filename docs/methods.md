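# Methods

## Estimands and identification

For a binary treatment A (1 = index level, 0 = reference) and binary
outcome Y, each unit carries two potential outcomes Y₁ and Y₀ — the
outcomes that would occur under each intervention — of which only the one
matching the received treatment is observed. The package estimates three
marginal contrasts of their means:

- **ATE** = E(Y₁ − Y₀): effect in the whole population;
- **ATT** = E(Y₁ − Y₀ | A = 1): effect among those actually treated;
- **ATU** = E(Y₁ − Y₀ | A = 0): effect among the untreated.

ATE is a weighted average of the other two, ATE = p·ATT + (1−p)·ATU with
p = P(A = 1), and all three coincide when the covariate distribution is the
same in both treatment arms and there is no effect modification by the
covariates.

Under consistency (the observed outcome equals the potential outcome for
the received treatment), conditional exchangeability given the covariates C
(no unmeasured confounding), and positivity (every covariate pattern can
receive either treatment), the estimands are identified by standardization:

- ATE = Σ_c [E(Y|A=1,c) − E(Y|A=0,c)] P(c)
- ATT = E(Y|A=1) − Σ_c E(Y|A=0,c) P(c|A=1)
- ATU = Σ_c E(Y|A=1,c) P(c|A=0) − E(Y|A=0)

`nonparametric_standardization` evaluates these sums directly from
empirical cell means and stratum frequencies. It needs discrete covariates
and a unit in the conditioning arm of every required stratum (otherwise it
raises a positivity error naming the stratum), and it serves as the exact
oracle against which the model-based routes are tested.

## The g-computation algorithm

**Step 1 — outcome model.** A maximum-likelihood logistic regression of Y
on A and C. The default specification includes every covariate main
effect, the treatment main effect, all treatment-by-covariate 2-way
products and all treatment-by-covariate-by-covariate 3-way products — a
deliberately flexible model, since g-computation leans entirely on the
outcome model — but *not* covariate-by-covariate products without the
treatment. Fully saturated and user-specified term lists are supported.

**Step 2 — counterfactual stack.** The data are resampled with replacement
K times (default K = 200) into a pooled dataset, which is duplicated into
an "intervene A = 1" copy and an "intervene A = 0" copy. Potential
outcomes are then filled in: where the intervention matches the received
treatment, the observed outcome is copied exactly (consistency); where it
does not, the outcome is a Bernoulli draw at the model-predicted
probability for that arm. For ATT only the treated rows get defined
potential outcomes, for ATU only the untreated, for ATE everyone.

**Step 3 — marginal contrast.** The two arms' potential-outcome means
(over defined rows) are contrasted: risk difference p₁ − p₀, or the odds
ratio of the two marginal risks. The closed-form odds ratio equals the
exponentiated slope of a logistic regression of the potential outcome on
the arm indicator — that regression is saturated — and avoids a second
iterative fit. The marginal OR is non-collapsible (it differs from the
conditional ORs even without confounding); it is reported as-is.

### Variants

- **Standardization (default method).** The same contrast without
  simulation: the fitted model's predicted probabilities are averaged over
  the target subpopulation. ATT = observed treated risk − mean over treated
  of E(Y|A=0,C_i); ATU mirrored; ATE = mean over all units of
  E(Y|A=1,C_i) − E(Y|A=0,C_i). Deterministic and cheaper than
  simulation, which converges to it as K → ∞.
- **Restriction.** ATT/ATU as the ATE-style model contrast averaged over
  the relevant subgroup only. With a treatment-interacted model this equals
  the standardization estimate, because the MLE score equations force each
  subgroup's predicted factual risk to equal its observed risk. The same
  mechanism makes the weighted-average identity
  ATE = p̂·ATT + (1−p̂)·ATU hold to solver precision (~1e−13 at the
  IRLS tolerance of 1e−10 used here) whenever the model contains the
  treatment main effect.

### Choices where the recipe is open

- *ATT/ATU contrast sample.* Potential outcomes are defined only for the
  estimand's own subgroup, so rows with undefined values are excluded from
  the step-3 contrast (equivalently, the contrast is computed among the
  originally treated for ATT). Including other rows would contrast
  undefined quantities.
- *ATE simulation.* The step-2 recipe addresses ATT/ATU; for ATE the
  default simulates both arms for all units from the fitted model (the
  classic parametric g-formula). An `ate_mode="consistency"` sub-mode
  keeps the observed outcome in the factual arm; both converge to the same
  standardized value.
- *ATT's factual term.* The observed treated risk (not the model-predicted
  one) enters the ATT standardization formula; under a treatment-interacted
  model the two are numerically equal anyway.
- *Reference levels.* Categorical covariates use reference-cell coding
  with the most frequent level (ties broken alphabetically) as reference,
  overridable per covariate. Prediction-based estimands are invariant to
  this; fixing it keeps coefficient vectors reproducible.

## Bootstrap inference

Standard errors and confidence intervals come from J nonparametric
bootstrap replicates (default J = 500): each replicate resamples n units
with replacement and re-runs the whole pipeline — model refit and, for the
simulation method, fresh K-resampling and fresh counterfactual draws. The
SE is the sample standard deviation of the replicate estimates; the default
95% CI takes their 2.5th and 97.5th percentiles (linear interpolation
between order statistics, recorded in run metadata). Bias-corrected and
accelerated (BCa) intervals are available; the acceleration uses a
leave-one-unit-out jackknife on the original sample.

Replicates in which the refit fails (separation in a resample, a
degenerate marginal risk on the OR scale) are dropped and counted; if more
than 10% of replicates fail (configurable) the run aborts rather than
report an interval built on a censored resampling distribution.

The default bootstrap path fixes the design columns (and categorical
reference levels) at the original sample and refits by row-indexing
precomputed design matrices. A resample that loses a rare categorical
level therefore keeps the same coefficient layout instead of silently
fitting a smaller model; it also makes replicates cheap (~2–4 ms at
n = 1000). Callers who want full per-replicate re-derivation can pass
their own estimator callable to `bootstrap_estimate`.

## Randomness and reproducibility

One master `numpy` SeedSequence per run (PCG64 generator, named in the
metadata) spawns independent child streams for the point estimate, each
bootstrap replicate, and the jackknife. Within a stream, resampling
indices are drawn first, then counterfactual Bernoulli draws in (arm, row)
order. Identical (data, request, seed) yields bit-identical results,
including the machine-readable JSON document written by the CLI (sorted
keys, full-precision floats, no timestamps).

## Synthetic data and what the tests show

The generator emulates a cross-sectional health-survey structure: an
age-like standard-normal covariate Z, a gender-like Bernoulli(0.5)
covariate G, a confounded treatment A ~ Bernoulli(expit(α·[1, Z, G])) and
an outcome Y ~ Bernoulli(expit(β·[1, A, Z, G, AZ, AG])). The default
coefficients (α = (−0.4, 0.3, 0.2); β = (−1.4, −0.35, 0.4, 0.25, −0.25,
−0.15)) describe a ~43%-treated population with ~20% baseline risk and a
moderately protective treatment whose effect strengthens with age, so the
three estimands separate with |ATT| > |ATE| > |ATU| (true risk differences
≈ −0.080, −0.071, −0.064). True effects are computed by Monte Carlo
averaging of the closed-form per-unit potential-outcome probabilities —
treatment realized from α, outcomes never simulated — so the truth oracle
carries no Bernoulli noise.

The generator draws covariates independently and from the correct model
family; real survey data have correlated, mismeasured covariates, unknown
outcome-model forms, selection and nonresponse, and design weights (not
modelled here). Passing calibration tests therefore demonstrate that the
estimators are correct *given* a correctly specified outcome model and the
three identification assumptions — not that those assumptions hold in any
particular application.

A fixed 14-row fixture with one binary covariate (cell means 3/4, 1/2,
1/4, 1/4; treated fraction 6/14) gives exact rational values — ATT RD 5/12,
ATU 3/8, ATE 11/28; ORs 6, 5, 27/5 — used as hand-checkable oracles
throughout the suite.

## Problem sizes used in the checks

Calibration uses 200 datasets of n = 1000 with J = 200 bootstrap
replicates per estimate (observed: |bias| < 0.001, percentile-CI coverage
0.92–0.94 across estimands); the weighted-average identity is checked on 50
datasets of n = 500; Monte Carlo convergence of the simulation route uses
K = 2000 on the fixture across 20 seeds. The acceptance script scales the
coverage run to 100 datasets (ATT) and uses n = 5000 with J = 500 for the
single-dataset recovery check.

## Numerical notes and limitations

- IRLS with tolerance 1e−10 and up to 200 iterations; rank deficiency is
  detected by pivoted QR before fitting and reported with the collinear
  column names; separation raises an explicit error rather than returning
  divergent coefficients.
- OR-scale contrasts raise a degenerate-odds error when a marginal risk is
  exactly 0 or 1.
- Percentile equivariance (OR bounds = exponentials of log-OR bounds) is
  exact when the percentile lands on an order statistic (e.g. J = 201),
  and holds to interpolation error otherwise.
- Missing values are rejected outright — complete-case filtering must be
  done, visibly, upstream. Positivity violations warn and are recorded in
  the result metadata, but do not abort.
- Out of scope: survey weights, continuous outcomes, risk ratios,
  IPTW/doubly-robust estimators, and time-varying treatments.
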