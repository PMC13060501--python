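# poppk

Population pharmacokinetics of a one-compartment IV-bolus model with
dose-dependent clearance, built for the sparse serial + terminal
(destructive) sampling designs typical of mouse PK studies. The package
bundles everything such an analysis needs in one place: a synthetic-data
generator for the study design, nonlinear mixed-effects (NLME) estimation,
likelihood-ratio model selection, empirical-Bayes/shrinkage and residual
diagnostics (PWRES, IWRES, NPDE), a subject-resampling bootstrap, visual
predictive checks, and simulation-based noncompartmental exposure analysis.

It is aimed at pharmacometricians and quantitative pharmacologists who want
a scriptable, fully reproducible desk-scale counterpart to tools like
Monolix or NONMEM for this model family.

## The model

Plasma concentration after an IV bolus dose follows one-compartment
kinetics with first-order elimination,

    C(t) = (Dose / V) * exp(-(CL / V) * t),

with per-kg units throughout (dose mg/kg, V mL/kg, CL mL/h/kg,
concentrations ug/mL). Between-animal variability is lognormal,

    P_i = P_pop * exp(eta_i),      eta_i ~ N(0, omega^2),

on clearance and volume, and clearance depends on dose through a power
covariate with reference dose 3 mg/kg:

    CL_i = CL_pop * (Dose_i / 3)^beta * exp(eta_CL,i).

A negative exponent beta means clearance falls — and exposure rises more
than proportionally — as the dose increases. Residual error is
additive/proportional/combined, SD(y | f) = a + b * f; the fitted model is
purely proportional. The marginal likelihood integrates the two random
effects per animal; the package evaluates it by adaptive Gauss–Hermite
quadrature centred on each animal's posterior mode (importance sampling is
available as an oracle) and maximises it with a multi-start Nelder–Mead
search. Nested models are compared by the drop in OFV (−2 log L) against
the chi-square(1) cutoff 3.84.

## Worked example

```python
import poppk

truth = poppk.published_parameters()          # published final estimates
design = poppk.default_design()            # 70 mice, 121 observations
data = poppk.simulate_dataset(design, truth, seed=1)

model = poppk.OneCompartmentModel(data, dose_covariate=True)
fit = model.fit(settings=poppk.FitSettings(n_restarts=1))
print(fit.summary())
```

prints

```
One-compartment IV-bolus population PK model
  subjects: 70   observations: 121
  dose covariate on CL: True
  OFV: 711.958 (objective 712.044)
  converged: True

parameter  estimate      se  rse_pct  rse_acceptable
   cl_pop     40.71   1.948    4.787            True
    v_pop     55.05   3.654    6.638            True
     beta   -0.3007 0.02838     9.44            True
 omega_cl 3.715e-05     NaN      NaN           False
  omega_v    0.2698  0.0587    21.76            True
  error_b    0.4441 0.03956    8.908            True

  eta-shrinkage (SD-based): CL 100.0%  V 43.5%
```

The typical clearance (40.7 mL/h/kg at the 3 mg/kg reference dose), volume
(55.1 mL/kg), dose exponent (−0.30) and proportional error (0.44) recover
the generative values within the precision the sparse design allows; the
single-digit RSEs on the fixed effects mirror the precision the study
reported. The clearance IIV collapses to the boundary on this replicate —
with 121 observations, mostly one per animal, and a 51% residual CV there
is almost no individual clearance information, which is also why its
shrinkage is extreme. A base model without the covariate fits ~58 OFV
units worse (`poppk.likelihood_ratio`), far beyond the 3.84 cutoff.

Model evaluation hangs off the results object:

```python
fit.residuals(n_sim=1000, seed=2)       # PWRES / IWRES / NPDE table
fit.vpc(n_sim=1000, seed=3)             # dose-stratified predictive check
fit.bootstrap(B=1000, seed=4)           # stratified subject resampling
poppk.exposure_vs_dose(fit.params, seed=5)   # virtual-cohort NCA
```

The same pipeline is scriptable from the shell:

```
poppk all --seed 1 --out run1          # simulate -> fit -> LRT -> diagnostics
poppk vpc --seed 1 --out run1 --nsim 1000
```

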