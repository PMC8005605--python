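# Methods

## Scope and data situation

The package implements a population pharmacokinetic (PK) analysis of
intravenous cefathiamidine in infants (0.35–1.86 y) with augmented renal
clearance (ARC, eGFR ≥ 130 mL/min/1.73 m²), and the dosing simulations
built on it. The original plasma concentrations (36 samples from 20
infants) are not publicly deposited, so the package ships a synthetic-trial
generator that reproduces the cohort's covariate distributions and sampling
sparseness. Everything that depends only on printed quantities (the final
parameter estimates, the covariate distributions, the simulation settings)
is reproduced directly; everything that depends on the raw data (OFV drops,
shrinkage values, NPDE test statistics of the real fit) is covered by
simulation-based calibration instead: we verify that the machinery recovers
known truth under the study's own conditions.

## Structural and statistical model

One-compartment disposition, zero-order infusion input, first-order
elimination. A dose with infusion rate R₀ = amount/duration contributes

    C(s) = (R₀/CL) · (1 − e^(−ke·min(s, D))) · e^(−ke·max(0, s−D)),

at elapsed time s (D = infusion duration, ke = CL/V); profiles are
superpositions of these terms. Steady state under repeated dosing is the
geometric-series accumulation in closed form; the many-dose superposition
is retained in the test suite as an oracle only.

Covariate model (final form):

    CL = θ₁ · (WT/10.25)^0.75 · (AGE/1.25)^θ₃,    V = θ₂ · (WT/10.25),

with allometric exponents fixed at 0.75 (CL) and 1 (V). Reference
covariates (10.25 kg, 1.25 y — the cohort medians) are stored on the model
object, never hard-coded in formulas. Between-subject variability is
exponential, θᵢ = θ·e^η, η ~ N(0, ω²) with diagonal Ω (the source analysis
reports only per-parameter IIV; correlated random effects are out of
scope).

Residual error is exponential and is represented exactly as additive
Gaussian noise on the natural-log concentration: log y = log f + ε,
ε ~ N(0, σ²). This makes the FOCE "interaction" term exact for the
residual part and is numerically stable across the 4-order-of-magnitude
concentration range. Additive and combined error forms are available as a
configuration choice (compared by OFV); they work on the natural scale with
the variance frozen at the conditional mode (classic FOCE-I).

Default parameter values (the published estimates) are exposed as
`PopulationModel.infant_arc_reference()`: θ₁ = 2.20 L/h, θ₂ = 3.36 L,
θ₃ = 0.662, ω_CL = 0.256, ω_V = 0.224, σ = 0.226 (SDs on the log scale;
the printed percentages are read as approximate CV%).

## Estimation (FOCE-I)

The marginal likelihood of each subject integrates the joint density over
η. We use the FOCE-I approximation: per subject, damped Newton iterations
with the analytic gradient of the infusion solution and the Gauss–Newton
curvature locate the conditional mode η̂ (gradient tolerance 1e-8; a
Newton-decrement acceptance terminates the slow linear-convergence tail
once the remaining objective improvement is bounded below ~1e-11 relative;
Levenberg damping handles near-singular curvature, and a subject whose
damped step can no longer improve at float precision is frozen as
numerically stationary; ≤ 100 iterations, all subjects iterated
simultaneously as array operations). The integration correction
log det(I + Ω·J′WJ) uses the same Gauss–Newton (expected) curvature, the
classic FOCE-I form.

The exact Hessian (with the residual-curvature term) is deliberately not
used. In the log-det correction a full Laplacian objective is more
accurate at fixed parameters, but its determinant can be driven towards
zero by the outer optimizer on sparse subjects — log det → −∞ creates a
spurious unbounded minimum, and any hard floor just parks the optimizer on
the resulting cliff. The Gauss–Newton determinant is always ≥ 1, keeping
the outer problem smooth and bounded; this robustness is why
expected-curvature FOCE is the field's standard. The price is
approximation error: on
subjects with one or two observations and two random effects the
conditional posterior can have a nearly flat curved direction, and the
mode-based correction then misses exact quadrature by several tenths of an
OFV unit (we verified on such instances that the inner mode is global, that
a 64-node adaptive Gauss–Hermite reference agrees with brute-force
integration to 1e-10, and that an independently coded mode+Hessian
computation reproduces the engine's value — the discrepancy is the
approximation itself, not the implementation). Likelihood-ratio
differences between nested models on the same data, which drive covariate
selection and SIR weights, are much less affected than absolute values.

The reported OFV is −2 log marginal likelihood minus N·log(2π) (the
customary additive constant), so likelihood-ratio differences are
unaffected.

All per-subject quantities (concentrations, gradients, Newton steps) are
computed as flat vectorized array operations across the whole population;
this keeps a 200-subject fit at a few seconds and makes replicate
calibration studies affordable.

Outer estimation minimizes the OFV over log-transformed positive
parameters (covariate exponents and proportional shifts stay linear):
Nelder–Mead (fatol 1e-5) followed by an L-BFGS-B polish (ftol 1e-10,
finite-difference gradients). A `fast` mode with relaxed tolerances
(fatol 2e-3, no polish) is used inside covariate screening, where only
ΔOFV at the ~0.1 level matters. Standard errors come from the central
finite-difference Hessian of the OFV at the optimum; the relative step
(1e-3) is set well above the objective's numerical noise floor — the inner
mode search resolves the OFV to roughly 1e-10 relative — so curvature in
low-information directions stays stable. Covariance = 2·H⁻¹; RSE% is
reported on the natural scale via the delta method. A non-positive-definite
Hessian yields "covariance unavailable" (SIR then falls back to an inflated
diagonal proposal).

Observations below the assay LLOQ (0.03 mg/L) are excluded with a warning;
the study reported none, and censored-likelihood handling is out of scope.

## Covariate selection

Candidates: age and eGFR as power functions of the covariate normalized by
its cohort median, and sex as a proportional shift, each on CL and on V
(weight enters the base model through the fixed allometric exponents and is
not re-screened). Forward inclusion requires an OFV drop strictly greater
than 3.84 (χ²₁, p < 0.05), best candidate first; backward deletion removes
any covariate whose deletion raises the OFV by at most 6.635 (χ²₁,
p < 0.01), smallest rise first. The trace of every tested ΔOFV is
returned. A selected age-power-on-CL effect is folded into the θ₃ slot of
the final model. Candidate fits that fail are skipped with a warning and
never abort the search.

## Model evaluation

**SIR.** Parameter vectors are drawn from a multivariate-normal proposal on
the internal (log) scale, weighted by exp(−dOFV/2)/q(x) where dOFV is the
FOCE OFV of the sampled vector minus the OFV at the estimates (the same
objective as estimation, not a linearization), resampled without
replacement, and the proposal is refit to each resample's mean and
covariance. Default schedule M = (5000, 2000, 2000, 1000),
m = (1000, 1000, 1000, 500). The proposal covariance carries a default
inflation factor of 1.5 so that it stays deliberately wider than the
posterior — its dOFV distribution then sits above the χ²(df) reference, as
a well-placed proposal should; the importance weights correct for the
inflation. Convergence is declared when the dOFV distributions of the last
two resamples overlap (two-sample KS p > 0.05) and the proposal dOFV
quantiles sit above the χ²(df) reference at ≥ 80 % of deciles (the source
analysis states these conditions graphically without numeric criteria; the
numbers here are this package's choice). Reported per parameter: resample
median and percentile 95 % CI on the natural scale.

**NPDE.** The design is simulated K = 1000 times (IIV + residual error).
Per subject, observed and simulated vectors are decorrelated with the lower
Cholesky factor of the empirical simulated covariance (identity fallback
with a warning if singular); the prediction discrepancy
pd = (#{sim < obs} + ½·#ties)/K is clipped to [1/(2K), 1 − 1/(2K)] and
mapped through Φ⁻¹. Tests: t-test on the mean (Wilcoxon available by
option), χ² variance test against 1, Shapiro–Wilk normality; global
p = min(1, 3·min p) (Bonferroni; the source prints a "global adjusted
p-value" without naming a method).

**Diagnostics.** η-shrinkage = 100·(1 − SD(η̂)/ω) (sample SD, ddof 1),
ε-shrinkage = 100·(1 − SD(IWRES)) with IWRES on the residual-model scale.
CWRES linearize the model about η̂: mean f(η̂) − Jη̂, covariance
JΩJ' + residual variance, standardized by the Cholesky factor.

## Dosing simulation (PTA)

Pharmacodynamic target: free concentration above the MIC for ≥ 70 % of a
steady-state dosing interval, with a fixed unbound fraction of 0.77;
a regimen is adequate for a MIC when ≥ 70 % of simulated infants attain
the target. Steady state is the pharmacodynamic convention adopted for
repeated dosing (the source does not state first-dose vs steady state).
The steady-state profile rises monotonically from trough (infusion start)
to peak (infusion end) and decays monotonically back — provable from the
closed form — so the two MIC crossings are solved exactly by logarithms;
a 0.001-h grid oracle cross-checks this in the tests.

Per virtual subject one η pair is drawn and reused across all regimens and
MICs (lower Monte Carlo variance for regimen comparisons; whether the
source redrew per regimen is unstated). Residual (assay) error is excluded
— PTA concerns true exposure, and residual error is measurement noise.
Doses are computed per kg on each subject's simulated weight; all simulated
regimens use 0.5-h infusions. Regimen recommendation per MIC picks the
adequate regimen with the longest dosing interval first (frequency is
escalated only when needed, mirroring the clinical escalation logic), then
the lowest daily dose; this ordering reproduces the published choices
(100 mg/kg/day q12h at MIC 0.25, 50 q8h at 0.5, 75 q6h at 2, none at 8).

## Synthetic data

The generator emulates the published cohort: weight ~ N(10.33, 1.57²) kg
truncated to [8.00, 13.00], age ~ N(1.20, 0.43²) y truncated to
[0.35, 1.86], serum creatinine ~ N(18, 6²) µmol/L truncated to [10, 26],
balanced sex. Marginals are drawn by inverse-CDF from truncated normals
whose underlying location is shifted so that the *truncated* mean equals
the printed cohort mean (the printed numbers are sample moments of a
bounded cohort, so treating them as untruncated parameters would bias the
simulated means by ~0.07 kg and ~0.03 y). Matching the SD as well is
impossible for weight — no truncated normal on [8, 13] has SD 1.57 (the
wide-σ uniform limit gives 1.44) — so the printed SD is used for the
underlying scale and the realized SD is slightly smaller. A Gaussian
copula induces a weight–age correlation of 0.6 (typical of infant cohorts,
and deliberately confounding the allometric and age effects as real data
would; set it to 0 for clean recovery experiments).

Height, needed only for the Schwartz eGFR, is not reported in the cohort
table; it is generated from a piecewise-linear length-for-age curve
(66 cm at 0.35 y, 75 cm at 1 y, 87 cm at 2 y) plus N(0, 2 cm) noise. The
ARC criterion is enforced by redrawing creatinine and height (never weight
or age, which the PK model uses) until eGFR ≥ 130.

Trials mimic the scavenged-sampling design: 1–3 samples per subject
(probabilities 0.4/0.4/0.2, mean 1.8, so 20 subjects give ~36 samples),
taken a random dose occasion into a 3-day q12h course plus a draw from
post-dose windows 0.5–2 h, 2–8 h, 8–12 h with weights 0.3/0.4/0.3. The
real sampling-time distribution is unreported; the window scheme is an
assumption isolated in `SamplingDesign` for sensitivity analysis.
Concentrations are model predictions times e^ε; draws below the LLOQ are
redrawn at a new time (the study observed none below the LLOQ).

What passing tests therefore show: the estimation and evaluation machinery
is correct and well calibrated *under the stated distributional
assumptions*. What they cannot show: fidelity to features of the real
cohort the generator does not model — the true sampling-time pattern,
covariate distribution shape beyond first moments and bounds, assay error
structure beyond a lognormal, or model misspecification in the real data.

## Problem sizes and numerical choices

Calibration studies use sizes chosen to make the checks sharp while
keeping the full suite quick on one CPU: parameter recovery at 200
subjects × 6 samples; selection calibration at 20 replicates × 100
subjects per arm; SIR coverage at 20 replicates with a reduced schedule
M = (500, 200), m = (100, 50); NPDE self-consistency at 20 runs × ~500
observations; quadrature agreement on 20 seeded instances of ≤ 3 subjects
with 64-node adaptive Gauss–Hermite quadrature per η dimension.

Degenerate inputs are handled explicitly: concentrations that underflow to
zero are floored at 1e-300 before logs; a zero Ω entry pins the
corresponding η at 0 (the log-det correction remains exact in the limit);
a zero-covariance SIR proposal collapses to the point estimates; subjects
without observations take η̂ = 0 (the prior mode); singular NPDE simulated
covariances fall back to identity decorrelation with a warning; ties in
the NPDE ranks count one half.

## Known limitations

- One-compartment structure only; a two-compartment comparison would need
  an external structural plugin (the source rejected two-compartment).
- Diagonal Ω; no M3-type handling of censored observations; no SAEM or
  importance-sampling estimators; no bootstrap (SIR is the uncertainty
  method); no visual predictive check; no cumulative fraction of response
  (no MIC distribution data).
- The FOCE/Laplacian OFV is an approximation; its error against exact
  quadrature grows with ω above ~0.5 on very sparse designs.
- Published percentages are reproduced from truncated-normal covariates,
  not the (unavailable) real cohort; the residual discrepancy is largest
  for tail probabilities (high-MIC, long-interval cells).
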