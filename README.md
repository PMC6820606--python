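# dosematch

Model-informed **exposure matching** for monoclonal-antibody dosing
regimens, built around the atezolizumab example: justify alternative flat
dosing schedules (840 mg q2w, 1680 mg q4w) against an approved regimen
(1200 mg q3w) and the maximum assessed dose (20 mg/kg q3w) by showing that
their predicted exposures fall within the established range, given a flat
exposure–response (ER) relationship.

The package is aimed at pharmacometricians and clinical pharmacologists who
want a scriptable, fully reproducible version of this workflow, and it
ships a synthetic-trial generator so every stage can be exercised and
validated closed-loop without access to patient-level data.

## What it computes

**Population PK.** A closed-form two-compartment IV-infusion model with
linear kinetics. Individual parameters follow the conventional population
parameterisation

    P_i = P_typ · ∏_k (cov_ik / ref_k)^θ_k · ∏_j FC_j · exp(η_i),   η_i ~ N(0, Ω)

with power-form continuous covariates (body weight, albumin, baseline
tumor size) and fold-changes for categoricals (sex, ADA status). Multi-dose
profiles use superposition; steady state is the exact geometric-series
limit. The packaged default model is calibrated to the published summary
pharmacokinetics (CL 0.2 L/day, V_ss 6.9 L, terminal t½ ≈ 27 days).

**Regimen simulation.** Monte Carlo virtual populations (a 1:1 male/female
reference cohort at 85/64 kg, or body-weight-quartile cohorts with
truncated-normal weights and the observed sex mix), per-patient exposure
metrics (cycle-1 Cmax, Cmin, AUC₀–21d by trapezoid; steady-state Cmax,
Cmin, AUC = dose/CL; weekly AUC), geometric-mean summaries with empirical
90% prediction intervals, and percent-difference regimen comparisons.

**Exposure–response.** Univariate logistic regression of binary endpoints
(objective response, grade ≥ 3 AEs, AEs of special interest) on continuous
cycle-1 exposure with Wald tests; event proportions with exact
Clopper–Pearson CIs by exposure quartile; stratum-pooling checks and
subgroup safety summaries.

**TGI–OS.** A biexponential tumor-size model
SLD(t) = BSLD·(e^(−KS·t) + e^(KG·t) − 1) fit per patient by MAP with
log-normal priors, and a parametric accelerated-failure-time model of
overall survival on log(KG) plus baseline prognostic factors (log-normal
default; Weibull / log-logistic with AIC selection). The fitted model is
validated by simulating treated-vs-control hazard ratios (Cox re-estimation
per replicate, notably by exposure quartile), and drug exposure is tested
on the final model at the α = 0.01 convention.

**pcVPC.** A prediction-corrected visual predictive check of a popPK model
against an event-record dataset (NONMEM-dialect CSV), with
nominal-occasion or quantile binning.

## Worked example

```python
from dosematch import PopPKModel, build_reference_population, exposure_table, \
    compare_regimens, standard_regimens, target_attainment
from dosematch.simulate import summarize_exposure

model = PopPKModel.default()
pop = build_reference_population(model, n=500, seed=1)
regs = standard_regimens()
ref = summarize_exposure(exposure_table(pop, regs["1200mg_q3w"]), "1200mg_q3w")
q2w = summarize_exposure(exposure_table(pop, regs["840mg_q2w"]), "840mg_q2w")
print(compare_regimens(ref, q2w, metrics=["cmin_c1", "cmin_ss", "weekly_auc_ss"]))
```

prints (seed 1):

```
       metric  reference     test  pct_diff  pct_diff_1dp  pct_diff_int
      cmin_c1     85.218   72.568   -14.844         -14.8           -15
      cmin_ss    211.237  245.334    16.141          16.1            16
weekly_auc_ss   2190.317 2299.833     5.000           5.0             5
```

Read: relative to 1200 mg q3w, the 840 mg q2w schedule trades a ~15% lower
cycle-1 trough for a ~16% higher steady-state trough, and (because the
same patients are used for both regimens) its steady-state weekly AUC is
exactly 5% higher — the analytic (840/2)/(1200/3) ratio, since weekly
AUC_ss = weekly dose / CL. The geometric-mean cycle-1 trough of 85 µg/mL
sits mid-range of the published 90% interval (55–133 µg/mL), and

```python
target_attainment(exposure_table(pop, regs["1200mg_q3w"]), "cmin_c1", 6.0)
# -> 100.0
```

shows every simulated patient above the 6 µg/mL target trough.

The same stages are available from the shell:

```bash
dosematch simulate-regimen --dose 1200 --interval-days 21 --n 500 --seed 1 --out q3w.csv
dosematch generate-data --preset oak-like --seed 1 --out trial/
dosematch er-logistic --data trial/endpoints.csv --metric auc_c1 --outcome orr --out quartiles.csv
dosematch fit-tgi --data trial/sld.csv --out tgi.csv
dosematch pcvpc --data trial/pk.csv --n-reps 1000 --seed 1 --out vpc.csv --plot vpc.png
```

Every command writes a JSON run manifest (seed, config hash, package
version) next to its output.

## Layout

- `src/dosematch/pk.py` — closed-form PK engine and population model
- `src/dosematch/simulate.py` — virtual populations, exposure metrics, comparisons
- `src/dosematch/published.py` — published summary tables used as comparison inputs
- `src/dosematch/er.py` — exposure–response logistic analysis
- `src/dosematch/tgi.py` — biexponential tumor-size fits
- `src/dosematch/survival.py` — TGI-OS AFT model, screening, HR simulation
- `src/dosematch/pcvpc.py` — prediction-corrected VPC
- `src/dosematch/synthetic.py` — virtual-trial generator
- `src/dosematch/eventio.py`, `cli.py` — event-record I/O, manifests, CLI
- `docs/methods.md` — modelling assumptions, calibration and limitations
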