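# sertpk

Population pharmacokinetics and model-informed precision dosing (MIPD)
of **sertraline in pediatric major depressive disorder**, with a focus on
the drug–drug interaction with **zopiclone**.

Sertraline has a trough-referenced therapeutic window of 10–150 ng/mL,
wide between-patient kinetic variability, and no TDM feedback available
when therapy starts — so the *initial* dose must come from a model. This
package implements the full workflow a pharmacometrician would run:

1. a one-compartment oral population-PK model with allometric weight
   scaling and a zopiclone effect on clearance,

       CL/F_i = 74 · (WT_i/70)^0.75 · (1 − 0.547·ZOP_i) · e^{η_i}   L/h
       V/F_i  = 874 · (WT_i/70)                                     L
       Ka     = 0.5 h⁻¹ (fixed),   B = C(1+ε₁) + ε₂

   with η ~ N(0, ω²) on clearance (ω = 0.391) and combined residual
   error (σ_prop = 0.159, σ_add = 9.803 ng/mL);
2. nonlinear mixed-effects estimation (FOCE-I/Laplace) with stepwise
   covariate selection (ΔOFV > 3.84 in, > 6.63 out) and a fixed-Ka
   sensitivity sweep;
3. model qualification by subject-level bootstrap, visual predictive
   check and goodness-of-fit diagnostics;
4. Monte Carlo initial-dose optimization: probability that the
   steady-state trough falls in 10–150 ng/mL per (weight, dose,
   schedule, zopiclone) cell, and a maximin dose recommendation per
   weight band.

Because the underlying TDM database is not public, a synthetic-cohort
generator reproduces the study's demographic structure (n = 111, weight
56.58 ± 15.01 kg in 35–117, 3/111 on zopiclone, sparse steady-state
troughs) so every estimation claim is validated by parameter recovery.
See `docs/methods.md` for the model, conventions and limitations.

## Worked example

```python
import sertpk as sp

# typical patient: 70 kg, with vs without zopiclone
fe = sp.FixedEffects()
cl0 = sp.typical_params(fe, sp.Subject(id=1, weight_kg=70)).cl
cl1 = sp.typical_params(fe, sp.Subject(id=2, weight_kg=70, zop=1)).cl
print(f"CL/F {cl0:.0f} vs {cl1:.1f} L/h -> ratio {cl1/cl0:.3f}")

# steady-state trough under 1.0 mg/kg/day once daily with zopiclone
p = sp.StructuralParams(cl=cl1, v=874.0, ka=0.5)
print(f"trough {sp.trough_at_steady_state(p, sp.Regimen(70.0, 24.0)):.1f} ng/mL")

# probability that the trough is inside 10-150 ng/mL (3000 virtual patients)
sc = sp.SimulationScenario(zop=1, tau_h=24.0, n_virtual=3000, seed=0)
pta, se, n = sp.simulate_pta(sp.FINAL_MODEL, sc, weight=70.0, dose_per_kg_day=1.0)
print(f"attainment {100*pta:.1f}% (MC SE {100*se:.2f}%)")
```

prints

```
CL/F 74 vs 33.5 L/h -> ratio 0.453
trough 57.4 ng/mL
attainment 96.4% (MC SE 0.34%)
```

i.e. zopiclone co-administration cuts clearance to 0.453 of its value at
the same weight, and 1.0 mg/kg/day once daily then keeps ~96% of
patients inside the window.

## The analysis

Numbered drivers under `analysis/` run the study end to end on the
synthetic cohort and write their tables under `results/`:

```sh
python analysis/01_simulate_cohort.py    # cohort + sparse TDM dataset
python analysis/02_fit_model.py          # mixed-effects fit (Table-style report)
python analysis/03_covariate_search.py   # stepwise covariates + Ka sweep
python analysis/04_validate_model.py     # bootstrap, VPC, GOF
python analysis/05_dose_optimization.py  # PTA grids + dose recommendations
```

Step 2 on the default seed recovers CL/F = 74.3 L/h (generating value
74); step 4's 200-replicate bootstrap shows |bias| < 2.4% on every
estimated parameter with 200/200 converged replicates; step 5 recommends
1.0 mg/kg/day (once daily) and 0.5 mg/kg/day (twice daily) across
30–80 kg when zopiclone is co-administered, and 2.0 mg/kg/day twice
daily without it — 2–4× lower doses under the interaction.

The same pipeline is scriptable from one config (`sertpk run config.yaml
--out outdir`) or per stage via the `sertpk` CLI (`simulate`, `fit`,
`covstep`, `kasweep`, `bootstrap`, `vpc`, `gof`, `pta`, `recommend`).

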