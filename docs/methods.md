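# Methods

This note records the models, the calibration choices behind the packaged
defaults, and what the synthetic-data validation does and does not
demonstrate.

## Population-PK engine

**Structure.** Two-compartment disposition with zero-order IV infusion into
the central compartment and linear elimination. The central concentration
for one infusion is the standard biexponential closed form in the hybrid
rate constants (α, β); multi-dose profiles are superpositions of shifted
single-infusion solutions, and the steady-state profile is the exact
infinite-superposition limit obtained by summing each exponential tail as a
geometric series. Units are days, mg, L, so concentrations are natively
µg/mL. When Q or V₂ is zero the engine degenerates exactly to the
one-compartment closed form. Correctness is tested against an independent
adaptive-step ODE integration (relative error < 0.1% over 100 random
parameter sets) and against superposition/dose-linearity identities at
machine precision.

**Default parameters.** The published summary pharmacokinetics constrain
the model three ways — CL 0.2 L/day, V_ss = V₁+V₂ = 6.9 L, terminal
half-life ≈ 27 days — which under-determines the four structural
parameters. The packaged default fixes V₁ = 3.28 L, Q = 0.546 L/day,
V₂ = 3.62 L, honouring all three constraints simultaneously (t½ = 26.5 d).
Substitute full published phase-1 estimates via the YAML config if
available.

**Covariate model and variability.** Covariate effects use conventional
popPK forms: power functions of weight (ref 77 kg), albumin (ref 40 g/L)
and baseline tumor size (ref 63 mm), and fold-changes for female sex and
ADA-positive status on clearance. The exponents, fold-changes and the
log-scale random-effect covariance Ω in `default_atezolizumab.yaml` were
never published at full precision: they are **calibration constants**,
chosen once so that the simulated 500-patient reference population
reproduces realistic IgG1 exposure spans (≈ 26% CV on CL, ≈ 24% on V₁,
CL–V₁ correlation 0.48). With these defaults the simulated geometric-mean
summaries for 1200 mg q3w land within a few percent of the published
summary table (e.g. cycle-1 trough 85 µg/mL, steady-state trough
211 vs 194 µg/mL). They are defaults to be overridden, not estimates.

**Infusion duration** is not stated in the source summaries; the default
is 1 hour (1/24 day), configurable per regimen. Cmax is modestly sensitive
to this choice; troughs and AUCs are not.

## Regimen simulation

The reference population is deterministic in its covariates (1:1 sex at
85/64 kg, albumin 40 g/L, tumor size 63 mm, ADA negative); only the random
effects are sampled. For odd n the extra patient is male. Weight-quartile
cohorts sample weight from a normal distribution truncated to the quartile
bounds (36.5–63.7, 63.7–77.0, 77.0–90.9, 90.9–168.0 kg); the location
(77.0 kg) and scale (20.2 kg = IQR/1.349) are chosen to match the printed
overall quartiles, and the female fraction per quartile is 80/50/25/10%.

Exposure metrics per patient: cycle-1 AUC is a trapezoid integral on a
0.05-day grid fixed to 0–21 days for cross-regimen comparability (grids
coarser than 0.25 day are rejected); the cycle-1 trough is the
concentration at the end of the first dosing interval (14/21/28 days by
regimen); steady-state interval AUC is dose/CL exactly; weekly AUC divides
the interval AUC by interval/7. Summaries are geometric means with
empirical 5th/95th percentiles (no parametric assumption). 20 mg/kg q3w
uses the sex-specific printed doses (1700/1280 mg) in the reference
population and true weight × 20 mg/kg in weight-sampled cohorts.

Regimen comparison supports both **common random numbers** (same virtual
patients under both regimens — the steady-state weekly-AUC ratio is then
exactly weekly-dose ratios, e.g. 1.05 for 840 q2w vs 1200 q3w) and
**independent replicates** (separate seeds per regimen, which reproduces
the published style of single-replicate comparisons whose realised
percentages scatter around the analytic value).

## Exposure–response analysis

Binary endpoints vs continuous exposure by maximum-likelihood logistic
regression; the Wald two-sided P on the slope is the reported test.
Complete or quasi-complete separation is detected and raised rather than
reported. Quartile summaries use empirical 25/50/75 edges with ties
assigned to the lower quartile (deterministic), and exact Clopper–Pearson
95% CIs — chosen for conservatism at small quartile event counts since the
interval method was not specified. Stratum pooling ("similar frequencies")
is made explicit as a configurable absolute-difference threshold,
default 5 percentage points.

## Tumor-growth model and fits

SLD(t) = BSLD·(e^(−KS·t) + e^(KG·t) − 1). Patients are TGI-evaluable with
a baseline (t ≤ 0) plus ≥ 1 post-treatment assessment; exclusions are
logged with reasons. Individual parameters are estimated by penalised
least squares on log SLD with log-normal priors on (BSLD, KS, KG) — a MAP
approximation to the empirical-Bayes individual estimates a population
mixed-effects fit would give, chosen to keep estimation per-patient and
dependency-light. With ≥ 4 informative observations and vague priors this
reduces to ordinary nonlinear least squares (noise-free recovery to
< 10⁻⁶ relative error). Observed SLD is floored at 2 mm before the log
transform; fits use actual (irregular) visit times; a small multi-start
over (KS, KG) guards against local minima; non-convergence falls back to
the prior means and is flagged, as is prior domination when fewer than two
post-baseline points exist. The residual model is proportional
(log-scale), with σ fixed at 0.2 by default in the penalty weighting.

## TGI-OS model

Accelerated failure time on log survival time with covariates log(KG),
ECOG > 0 (binarised), log baseline tumor size (centred at 63 mm), log
albumin (centred at 40 g/L), log LDH and log ALP (relative to reference),
PD-L1 and tumor-type indicators. Log-normal is the default family
(standard in the TGI-OS literature); Weibull and log-logistic are
available with AIC-based selection. Fitting is two-stage (tumor fits, then
survival) — a sequential approximation to a joint longitudinal–survival
model. Exposure metrics are tested one at a time on the final model (Wald
and likelihood-ratio), with significance at α = 0.01 and no multiplicity
adjustment, matching the analysis convention.

**HR validation by simulation.** Per replicate, event times for a treated
arm (resampling estimated KG within group, baseline covariates fixable to
medians) and a control arm (covariates and TGI metrics supplied by config
or the generator — never hard-coded) are drawn from the fitted AFT
distribution and the HR re-estimated by Cox regression (Efron ties).
Reported per exposure quartile as the median and 2.5/97.5 percentiles
across replicates (default 1000); groups under 10 patients are flagged.
Under a flat ER structure the quartile HR intervals mutually overlap.

## pcVPC

Population predictions (PRED, zero random effects) are computed per
observation under actual dosing and covariates; the prediction-corrected
value is DV · median(PRED_bin)/PRED. The same correction is applied to
every simulated replicate (individual parameters redrawn from Ω, residual
error applied). Default binning treats each distinct nominal time as an
occasion when there are ≤ 24 of them, else 10 quantile bins; explicit
edges are accepted. Observations with PRED = 0 (pre-first-dose) or below
the LLOQ are excluded and logged; bins with < 5 observations are flagged.
Reported per bin: observed 5th/50th/95th pc-percentiles and the 90%
interval of each percentile across replicates.

## Synthetic-trial generator

The generator emulates the statistical structure the analysis assumes, not
any particular trial's data: sex-specific log-normal weight (medians 80/64
kg, log-SD 0.18, truncated to 36.5–168 kg, consistent with the printed
weight quartiles), normal albumin (40 ± 5 g/L), log-normal tumor size
(median 63 mm), categorical ADA (10%), ECOG > 0 (60%), PD-L1 (55%);
biexponential SLD with proportional noise (default 10%, 6-weekly visits
over 48 weeks); log-normal AFT survival with uniform-accrual
administrative censoring plus exponential dropout; binary endpoints with a
logistic exposure slope per SD of log exposure, **default zero** (the flat
ER null). log KG loads on log baseline tumor size (coefficient 0.3), and
clearance also depends on tumor size, so exposure and survival are
confounded exactly the way the TGI-OS adjustment is meant to handle.

Preset arms are calibrated so the NSCLC-like arm (n 425, 91% evaluable)
has median OS ≈ 467 days and the UC-like arm (n 467, 82% evaluable)
≈ 344 days — calibration constants for realism, not reproduction targets.
The optional time-varying clearance uses CL(t) = CL₀(1 − I_max·t/(T₅₀+t))
with I_max default 0.17 when enabled; T₅₀ = 60 days is an invented default
(not a published value). Time-varying-clearance profiles are integrated
numerically segment-by-segment; static profiles use the closed form.

What passing closed-loop tests show: the pipeline recovers the effects the
generator encodes (type-I error of the ER test at nominal level, AFT
coefficient coverage, log KG recovery, pcVPC self-consistency, directional
trough underprediction under a clearance decline). What they do not show:
behaviour under real-data artifacts the generator omits — dose
interruptions, unscheduled visits, informative censoring, non-lognormal PK
variability, model misspecification beyond the clearance-decline scenario.

## Problem sizes and numerics

Default simulation sizes in the test suite (500-patient populations,
200-replicate coverage studies, 300-replicate VPCs, 1000 outcome
replicates for the type-I check) were chosen to make Monte Carlo error
comfortably smaller than the tolerances being checked while keeping the
suite quick to run. Stochastic checks use fixed seeds and tolerance bands
derived from binomial or 3σ arguments stated inline. Exposure grids are
0.05 day; trapezoid AUC against the analytic dose/CL is accurate to
< 0.5% over 10 half-lives; coincident disposition roots (α = β) are
perturbed by a relative 10⁻⁹ to keep the closed form well-defined.

## Known limitations

- No mixed-effects estimation of PK parameters from data: the popPK model
  is simulation-only, configured, not fitted.
- The TGI MAP fit is a per-patient approximation; it understates shrinkage
  relative to a true population empirical-Bayes fit when data are sparse.
- Sequential (two-stage) TGI→OS fitting ignores uncertainty propagation
  from the tumor fits into the survival coefficients.
- The default covariate exponents and Ω are calibrated, not estimated;
  conclusions sensitive to them should be re-run with study-specific
  configurations.
- The time-varying clearance model in the generator is a single Imax/T₅₀
  Michaelis-type decline; the engine itself remains static, which is
  exactly what the pcVPC misspecification check exploits.
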