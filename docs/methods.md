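# Methods

## Model

One-compartment disposition after an IV bolus with first-order
elimination: `C(t) = (Dose/V) exp(-(CL/V) t)`. All quantities are per kg
of body weight (doses mg/kg, converted internally to ug/kg so that
dose/volume is in ug/mL); no absolute body weights are modelled because
only per-kg quantities are reported for this kind of study. Between-animal
variability is lognormal on CL and V with independent random effects (no
covariance term is estimated; the analysis this package emulates reported
none). Dose enters clearance through a power covariate
`CL_i = CL_pop (Dose_i/3)^beta exp(eta_CL)` with the reference dose fixed
at 3 mg/kg. Residual error is `y = f + (a + b f) eps` with `eps ~ N(0,1)`;
the combined form uses the SD parameterisation `a + b f` (the simplest of
the usual conventions; the fitted model is purely proportional, so the
choice does not affect headline results).

Parameter conventions worth stating explicitly: the proportional error
`b = 0.51` is a fraction (51% CV), and the IIV magnitudes `omega_cl =
0.058`, `omega_v = 0.25` are SDs of the log-scale random effects (5.8% and
25% when quoted as CV%). These are the readings consistent with the
bootstrap scales reported alongside them.

## Likelihood and estimation

The observed-data likelihood integrates the conditional Gaussian
likelihood over each animal's `(eta_CL, eta_V)`. Three evaluation routes
are implemented in `poppk.likelihood`:

* **Posterior modes** are found by a Levenberg-damped Newton iteration
  vectorised across all animals, using the analytic gradient and the exact
  observed Hessian of the joint deviance (closed forms for this model).
  Damping keeps the step a descent direction where the observed Hessian is
  indefinite, which happens for one-observation animals far from their
  mode.
* **Adaptive Gauss–Hermite quadrature (default)** evaluates the integral
  on a tensor grid centred at the mode and scaled by the inverse
  *expected-information* (Gauss–Newton) Hessian. The expected form is
  always positive definite and varies smoothly with the population
  parameters; the observed Hessian's determinant can swing by factors of
  two under parameter changes of 1e-4 for tail animals, which makes a
  Laplace objective jagged and un-optimisable. Nine nodes per dimension
  are the default: with a 51% proportional error the integrand is visibly
  skewed and the single-node Laplace value is ~2.5% off, while AGQ-9 is
  within ~0.2% of a 20,000-draw importance-sampling estimate and AGQ is
  node-wise convergent. Estimates moved by <0.5% between 9 and 21 nodes on
  probe datasets.
* **Importance sampling** with a multivariate-t (df 5) proposal at the
  mode/expected-information scale provides the seeded final OFV
  (1000 nodes per animal by default) and, at high node counts, an oracle
  for testing the deterministic approximations.

An `omega` of exactly zero removes that dimension from the integral; with
both omegas zero the OFV is the closed-form Gaussian deviance.

Fixed effects are estimated on the log scale and variability parameters on
the log-SD scale (positivity without bound constraints); `beta` is
unconstrained. The outer optimiser is Nelder–Mead with three restarts from
jittered starts (fixed jitter seeds; sweep utilities use one restart —
on probe data the restart spread was <0.1 OFV and estimates unchanged).
Initial values come from pooled per-dose log-linear regression (slope →
k, intercept → V, power regression of the group CLs on dose), with
`omega = 0.3` and `b = 0.3`; for additive models `a` starts at 20% of the
median concentration. Convergence is judged by the final-simplex objective
spread (a boundary omega leaves a flat direction that can never satisfy a
parameter-space tolerance) plus agreement of restarts within one OFV unit.

Standard errors come from a central finite-difference Hessian of the
objective at the optimum (`cov = 2 H^-1` since the objective is −2 log L),
with RSE% = 100·SE(log p) for log-scale parameters. When a variability
parameter sits at its boundary the corresponding direction is flat or
indefinite; the flattest directions are dropped iteratively and the
well-conditioned submatrix inverted, reporting NaN for the degenerate
parameters.

Empirical Bayes estimates are the per-animal joint posterior modes;
eta-shrinkage is `100 (1 − SD(eta_hat)/omega)` by default, with the
variance-based convention available (`method="var"`). Nested models are
compared by `OFV(base) − OFV(final) ≥ 3.84` (chi-square, 1 df, p < 0.05,
boundary inclusive).

## Synthetic data

The generator reproduces the study conditions: 70 female mice in five dose
groups (0.3, 1, 3, 5, 10 mg/kg), 121 observations, mixed serial and
terminal sampling. The per-group breakdown and sampling times are not in
the available study text, so the package fixes: 14 animals per group, 5
serial animals sampled at 0.083, 0.5 and 2 h, 9 terminal animals sampled
once at times cycling through 0.25, 1, 3, 6, 8 h, and one extra 4-h sample
for a serial animal in the 3 mg/kg group (totals forced to 70/121). The
window spans ~8.5 elimination half-lives at the reference dose. Simulated
concentrations that fall non-positive under the proportional error are
redrawn rather than truncated (no point mass, all records positive; no
quantification limit is simulated). Redrawing truncates the error
distribution at −1/b ≈ −1.96 SD, which biases recovered `b` a few percent
low — visible in the replicate experiments and accepted as a property of
the stated generative rule.

What the generator does not emulate: assay error drift or quantification
limits, body-weight variation, covariates other than dose, multiple
dosing, and any misspecification of the structural model. Passing recovery
tests therefore demonstrate the estimator's correctness under the model's
own assumptions, not robustness of the published analysis to violations of
them.

## Diagnostics and evaluation

Population residuals use Monte-Carlo decorrelation rather than first-order
linearisation: per animal, `n_sim` observation vectors are simulated under
the full model and PWRES = `L^-1 (y − mean)` with `L` the Cholesky factor
of the simulated covariance (default `n_sim = 1000`; the no-IIV case is
handled analytically). NPDE decorrelates observed and simulated vectors
with the same mean/Cholesky and maps the tie-adjusted rank
`(r + 1/2)/(n_sim + 1)` through the standard-normal quantile. IWRES =
`(y − IPRED)/(a + b·IPRED)` at the EBE modes. All stochastic diagnostics
require and record seeds.

The bootstrap resamples animals (not observations) with replacement,
stratified by dose group so each replicate keeps the design's dose
balance, and refits the model; failed replicates are logged, excluded and
counted. VPCs simulate under the exact original design, bin by nominal
design times (the synthetic times are exact, so no data-driven binning),
and report prediction bands of the observation distribution (5th/50th/95th
percentiles) with observations overlaid.

The NCA module verifies dose-exposure nonlinearity on simulated cohorts:
per dose, `n_virtual` animals are simulated on a 50-point grid spanning
ten of each animal's own half-lives, AUC is lin-up/log-down trapezoidal
with a `C_last/lambda_z` tail, and `lambda_z` is the log-linear slope of
the terminal points (3 by default for generic profiles; the dense-grid
cohort uses 10 points ≈ two half-lives, under a 51% CV three near-adjacent
points frequently yield no negative slope). Under the power model
`AUC = Dose/CL ∝ Dose^(1−beta)`, so dose-normalised AUC rises with dose
for `beta < 0`; Fig.-style summaries report medians with 5th/95th
percentiles (the convention adopted for "upper/lower limits").

## Problem sizes and numerical choices

Replicate experiments in the test suite use 20 recovery replicates
(medians of fixed effects), 100 type-I-error replicates, 50 NPDE
calibration replicates and 20 VPC replicates; the acceptance script uses
50 recovery replicates. Inner Newton tolerance is 1e-6 on the gradient
(relative to the deviance scale); Nelder–Mead tolerances are 1e-4 with a
budget of 900 iterations per restart. Ties in NPDE ranks get half weight.
Degenerate inputs raise: zero residual SD, singular simulated covariance,
non-finite structural predictions (reported with the offending subject and
time), observations before dosing records, missing values.

## Known limitations

* The true per-dose allocation and sampling times of the emulated study
  are unknown; shrinkage and precision statistics inherit that
  uncertainty. In particular the SD-based clearance shrinkage of a single
  replicate is strongly bimodal under this design (the clearance IIV
  estimate collapses to its boundary in roughly a third of replicates,
  giving 100%), so single-replicate shrinkage comparisons carry wide
  error bars.
* The estimation contract is on the marginal likelihood, not on any
  specific algorithm; a stochastic EM (SAEM) route is not implemented.
* Only the one-compartment, first-order-elimination structural model is
  supported — no two-compartment or Michaelis–Menten variants, no
  absorption models, no covariates beyond dose, no interoccasion
  variability, no random-effect correlation.
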