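# popkarc

Population pharmacokinetics of **cefathiamidine in infants with augmented
renal clearance (ARC)** — a tested, reusable implementation of the full
analysis pipeline: nonlinear mixed-effects estimation, covariate selection,
model evaluation, and Monte Carlo dose optimization.

Cefathiamidine is a first-generation cephalosporin widely prescribed in
Chinese pediatric hospitals. It is cleared renally, so infants with ARC
(estimated GFR ≥ 130 mL/min/1.73 m², Schwartz formula) eliminate it faster
than usual and are at risk of subtherapeutic exposure under standard
dosing. `popkarc` packages the published infant-ARC model and everything
needed to reproduce, stress-test, and extend the analysis — including a
synthetic-trial generator, since the original concentration data are not
publicly deposited.

## The model

One-compartment disposition with zero-order intravenous infusion and
first-order elimination. Fixed effects (reference covariates are the
cohort medians, 10.25 kg and 1.25 years):

```
CL_i = θ₁ · (WT_i/10.25)^0.75 · (AGE_i/1.25)^θ₃ · exp(η_CL,i)   [L/h]
V_i  = θ₂ · (WT_i/10.25)           · exp(η_V,i)                 [L]
```

with η ~ N(0, ω²) (diagonal Ω) and an exponential residual error handled
exactly as additive Gaussian noise on log concentration:
log y = log f + ε, ε ~ N(0, σ²). Published estimates: θ₁ = 2.20 L/h,
θ₂ = 3.36 L, θ₃ = 0.662, ω_CL = 25.6 %, ω_V = 22.4 %, σ = 22.6 %.

The estimation engine minimizes the FOCE-I objective (−2 log marginal
likelihood, Laplacian integration correction at the per-subject
conditional modes, exact η–ε interaction on the log scale), runs stepwise
forward-inclusion (ΔOFV > 3.84) / backward-deletion (ΔOFV > 6.635)
covariate selection, and evaluates fits by SIR (sampling importance
resampling) parameter uncertainty, NPDE (normalized prediction
distribution errors), shrinkage, and CWRES.

Dosing is optimized by Monte Carlo simulation of virtual infants against
the pharmacodynamic target **70 % fT>MIC** (free drug above the MIC for at
least 70 % of a steady-state dosing interval; unbound fraction 0.77), with
a regimen judged adequate when ≥ 70 % of infants attain the target.

## Worked example

```python
from popkarc import (PopulationModel, Regimen, generate_population,
                     simulate_pta, recommend_regimens, fit, simulate_trial)

model = PopulationModel.infant_arc_reference()

# dose optimization: 1000 virtual ARC infants
pop = generate_population(1000, seed=1)
pta = simulate_pta(model, pop,
                   regimens=(Regimen(100, 12), Regimen(50, 8),
                             Regimen(75, 6), Regimen(100, 6)),
                   seed=2)
print(pta.table[pta.table.regimen == "100 mg/kg/day q12h"])
for mic, reg in recommend_regimens(pta).items():
    print(f"MIC {mic:g} mg/L -> {reg.label if reg else 'none adequate'}")
```

Output:

```
              regimen  daily_dose  interval   mic  attainment  adequate
0  100 mg/kg/day q12h         100        12  0.25       0.701      True
1  100 mg/kg/day q12h         100        12  0.50       0.581     False
2  100 mg/kg/day q12h         100        12  2.00       0.295     False
3  100 mg/kg/day q12h         100        12  8.00       0.041     False
MIC 0.25 mg/L -> 100 mg/kg/day q12h
MIC 0.5 mg/L -> 50 mg/kg/day q8h
MIC 2 mg/L -> 75 mg/kg/day q6h
MIC 8 mg/L -> none adequate
```

Read: at the prescribed 100 mg/kg/day q12h, 70.1 % of simulated infants
reach 70 % fT>MIC against a MIC of 0.25 mg/L, but only 58.1 % against
0.5 mg/L — so more frequent dosing (50 mg/kg/day q8h) is needed there, and
no explored regimen is adequate at MIC 8 mg/L (a different antibiotic is
indicated).

Fitting works the same way on any NONMEM-style dataset:

```python
trial = simulate_trial(generate_population(20, seed=10), model, seed=11)
result = fit(trial, model)
print(round(result.ofv, 2), round(result.model.theta1, 3))
# -24.88 2.355   <- OFV and estimated typical clearance (truth 2.20)
```

A `popkarc` command-line tool wraps the same functionality
(`popkarc simulate/validate/fit/evaluate/pta --help`).

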