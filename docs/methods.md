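# Methods

`sertpk` implements a population-pharmacokinetic (PPK) analysis of
sertraline in pediatric major depressive disorder and the downstream
model-informed precision dosing (MIPD) workflow: structural model,
mixed-effects estimation, stepwise covariate selection, bootstrap/VPC
qualification, and Monte Carlo initial-dose optimization against the
10–150 ng/mL therapeutic trough window.

## Structural and statistical model

One-compartment disposition with first-order oral absorption. Because the
data are sparse pre-dose troughs, bioavailability F and absorption lag
are not identifiable; all parameters are apparent (CL/F, V/F) and the
absorption rate constant Ka is fixed at 0.5 /h (the trough-only OFV is
nearly flat in Ka over 0.4–2.0 /h — see `covstep.ka_sweep` and
`analysis/03_covariate_search.py`).

Typical values with allometric weight scaling (reference 70 kg; exponents
fixed at 0.75 for clearance and 1 for volume) and a binary zopiclone
co-medication effect on clearance:

    CL/F_i = 74 · (WT_i/70)^0.75 · (1 − 0.547·ZOP_i) · exp(η_i)   [L/h]
    V/F_i  = 874 · (WT_i/70)                                      [L]

η_i ~ N(0, ω²) is the only inter-individual random effect (exponential,
so clearance stays positive structurally). Observations follow the
combined residual model B = C·(1+ε₁) + ε₂ with independent zero-mean
Gaussian ε (Gaussian is the conventional choice for a "symmetric"
residual; the proportional term is evaluated at the individual
prediction, i.e. with interaction).

### The ω/σ convention (`interpretation_mode`)

The reference parameter table prints ω_CL/F = 0.391, σ₁ = 0.159,
σ₂ = 9.803 while the model equations define variances ω², σ². This
package treats the printed values as **standard deviations** (≈39% CV on
clearance, 15.9% proportional error, 9.8 ng/mL additive error), because
forward simulation of the final model under the sd reading reproduces
the published attainment probabilities (≈96–99% at the recommended
doses) while the variance reading gives ≈77–83%. Both conventions are
supported via `interpretation_mode` on `RandomEffects`/`ResidualModel`,
and every fit report and pipeline manifest records the mode used.

## Estimation

OFV = −2·log of the approximate marginal likelihood, including ln 2π
constants, so that with ω = 0 and additive-only error it reduces to the
exact Gaussian least-squares expression. With a single η per subject the
inner problem is one-dimensional; the empirical-Bayes modes of all
subjects are found simultaneously by a damped, vectorized Newton
iteration (finite-difference curvature, backtracking, gradient tolerance
1e−9). The marginal is then the Laplace/FOCE-I approximation at the
mode: `approx="foce"` uses the Gauss–Newton curvature
Σ(∂f/∂η)²/v + 1/ω² (interaction-aware), `approx="laplace"` the full
numerical second derivative.

The outer problem optimizes the free fixed effects and variability
parameters (log scale for positive parameters; the zopiclone coefficient
bounded below by −0.99 so clearance stays positive) with L-BFGS-B
followed by a Nelder–Mead polish. The polish matters: trough-only data
induce a strongly curved CL–V likelihood ridge on which
finite-difference quasi-Newton steps stall; the simplex pass reliably
walks the ridge (observed OFV improvements of ~7 points on stalled
fits). Standard errors come from the numerically differentiated outer
Hessian of the OFV (Cov = 2·H⁻¹) and are reported only when that matrix
is positive definite. Non-convergence never raises: the best state seen
is returned flagged.

Ka and the allometric exponents are fixed by default (`FitSpec.free`
controls this), matching the reference analysis.

## Stepwise covariate selection

Forward: every remaining candidate is fit on top of the current model
(power form on the dataset median for continuous covariates, linear for
binary); the largest OFV drop > 3.84 (χ²₁, p<0.05) enters, greedily,
ties to the larger drop then candidate order. Backward: effects whose
removal raises OFV by ≤ 6.63 (p<0.01) are deleted, iterating to
stability. Effects are tested on clearance by default (the final model
has covariates on CL/F only); the trace records every tried model and is
sufficient to replay the decisions. Under the null, the 3.84 criterion
admits a spurious binary covariate at ≈5%, verified by simulation in the
test suite.

## Synthetic cohorts

The study's TDM database is not available; `cohort` generates virtual
cohorts with its demographic structure. Weights follow a log-normal
truncated to [35, 117] kg whose truncated mean/SD are moment-matched to
56.58/15.01 kg (log-normal chosen for positivity and the right skew
implied by median 52.5 < mean 56.58; the match is solved once by root
finding on the closed-form truncated moments). The zopiclone flag is
Bernoulli(3/111) by default. Maintenance doses are uniform over 0.5–5.0
mg/kg/day, once or twice daily with equal probability (the real dosing
mix is unpublished); each subject contributes 1–3 (default; 2 in the
headline analyses) steady-state troughs on weekly visits starting at day
14 — far beyond ten half-lives, so the analytic steady state applies.
True η values ride along on the dataset for recovery testing only.

What the generator does **not** emulate: adherence gaps, dose titration,
assay quantification limits, covariate correlations (weight–age etc.),
and any real residual-error misspecification. Passing recovery tests
therefore show the estimator is consistent under the stated model, not
that the model is correct for real patients.

## Dose optimization

For each (weight, dose, schedule, zopiclone) cell, `dosing` draws
n_virtual η values, computes each virtual patient's steady-state trough
(evaluated exactly at t = τ, the TDM sampling convention), and reports
the fraction inside [10, 150] ng/mL inclusive. Residual error is **off**
by default: the published attainment probabilities and the printed
4.0-at-30-kg value are reproduced by model-predicted (individual)
concentrations, not observed-scale ones (adding residual noise drops the
once-daily-with-zopiclone minimum from ≈96% to ≈92%, well below the
published 96.7%); `include_residual=True` is available and tested.
Cell-level generators derive deterministically from the scenario seed,
so grids are reproducible and extensible.

The attainment metric is the trough (`metric="trough"`), the quantity
TDM measures and the one the window references. A `metric="average"`
option (steady-state average dose/(CL·τ)) exists mainly to state clean
invariants: the average is a pure function of dose/CL, so a clearance
covariate is exactly equivalent to a dose rescaling under it, whereas
the trough is not — clearance also reshapes the profile through ke, and
the with/without-zopiclone grids genuinely differ beyond any dose
rescaling (by up to tens of percentage points at low doses).

`recommend` scores each dose by its minimum attainment over the grid
weights inside a band and picks the best (maximin). Exact ties have
probability zero under Monte Carlo, so the safety tie rule is
statistical: any lower dose within 2 pooled MC standard errors of the
best is preferred, and the resolution is logged in the output. Band
endpoints (e.g. the 38.5 kg split for once-daily dosing without
zopiclone) are inputs; `derive_breakpoints` separately reports the
weights where the per-weight argmax dose switches.

## Qualification

Bootstrap resamples subjects (with all their rows) with replacement to
the original count — the field-standard unit that respects within-subject
correlation — refits each replicate warm-started at the point estimates,
and summarizes median, 2.5–97.5th percentiles (type-7 interpolation) and
bias = (median − estimate)/estimate × 100%. More than 20% failed
replicates flags the result unreliable. The VPC re-simulates the
original design (only η and ε re-drawn), bins observations by
population-prediction quantiles (6 bins by default; prediction-corrected
VPC is out of scope), and reports observed 2.5/50/97.5 percentiles with
the simulated 95% envelope of each percentile. GOF tables carry PRED,
IPRED (empirical-Bayes), iWRES = (DV − IPRED)/sd(IPRED) and a
first-order population weighted residual; zero-sd rows are flagged, not
dropped.

## Problem sizes and numerical choices

Headline analyses use n = 111 subjects with 2 troughs each; dose grids
use 3,000 virtual patients per cell (MC SE ≤ 0.9 percentage points at
p ≈ 0.97); the bootstrap uses 200 replicates and recovery checks 20
replicate cohorts. The ka = ke removable singularity in the closed forms
switches to the analytic limit within a relative window of 1e−8;
concentrations convert to ng/mL (1 mg/L = 1000 ng/mL) only at the
reporting boundary; all internal units are mg, L, h.

## Known limitations

- V/F is weakly identified from troughs alone (the reference analysis
  itself reports 36.6% SE and a bootstrap CI of roughly 215–2013 L);
  clearance is the reliable quantity, and recovery of V/F requires a
  richer sampling design (configurable via `CohortSpec`).
- The model's true minimum attainment for 0.5 mg/kg/day twice daily with
  zopiclone is ≈97.9% at 30 kg, ~0.6 points below the low end of the
  published range (98.5–99.6%) — within the publication's own n = 1000
  Monte Carlo noise, but a persistent small gap under this model.
- Printed OFV values of the original fit are not reproducible without
  the raw data and NONMEM's exact estimator; only OFV *differences* and
  orderings are used here.
- No inter-occasion variability, mixture models, or TDM-feedback
  (Bayesian) dose adjustment; the scope is initial-dose optimization.
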