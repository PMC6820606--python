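"""Virtual-trial generator.

Generates complete synthetic oncology trials carrying the statistical
structure the analysis pipeline assumes, so that every stage — PK
estimation inputs, exposure-response, TGI fitting, TGI-OS modelling,
pcVPC — can be exercised and validated closed-loop without any external
data:

- covariates: sex-specific log-normal body weight (consistent with the
  phase-1 weight quartiles), normal albumin, log-normal baseline tumor
  size, categorical ADA / ECOG / PD-L1 / tumor type;
- PK: individual parameters from the population model (log-normal
  between-patient variability, covariate effects), sparse peak/trough
  sampling, proportional + additive residual error on observations, and an
  optional time-varying clearance decline CL(t) = CL0 * (1 - Imax*t/(T50+t));
- tumor dynamics: biexponential SLD trajectories with proportional noise,
  baseline visit, and a configurable evaluable fraction (dropout before the
  first post-baseline scan);
- survival: log-normal AFT truth driven by log(KG) and baseline prognostic
  factors, with uniform-accrual administrative censoring plus exponential
  dropout;
- binary endpoints: Bernoulli with a logistic dependence on cycle-1
  exposure whose slope defaults to zero (the flat exposure-response null).

All outputs are plain DataFrames; ground-truth parameter tables are
returned alongside so recovery can be scored exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from dosematch.pk import DosingRegimen, PopPKModel
from dosematch.simulate import _exposure_arrays
from dosematch.tgi import sld_model

WEIGHT_TRUNCATION = (36.5, 168.0)


@dataclass
class TrialConfig:
    """Configuration of one synthetic trial arm.

    The OS coefficients are on the log-time (AFT) scale; exposure slopes
    for the binary endpoints are per standard deviation of log exposure
    (default 0 — no exposure-response relationship).
    """

    n_patients: int = 400
    tumor_type: str = "NSCLC"
    regimen: DosingRegimen = field(
        default_factory=lambda: DosingRegimen(dose_mg=1200, interval_days=21,
                                              n_doses=16, name="1200mg_q3w"))
    # covariate distributions
    female_fraction: float = 0.40
    weight_median: dict = field(default_factory=lambda: {"M": 80.0, "F": 64.0})
    weight_log_sd: float = 0.18
    albumin_mean: float = 40.0
    albumin_sd: float = 5.0
    tumor_size_median: float = 63.0
    tumor_size_log_sd: float = 0.55
    ada_positive_fraction: float = 0.10
    ecog_gt0_fraction: float = 0.60
    ldh_log_sd: float = 0.40
    alp_log_sd: float = 0.35
    pdl1_fraction: float = 0.55
    # PK sampling: (dose number, peak and trough) occasions
    pk_sample_doses: tuple = (1, 2, 4, 6, 14)
    cl_decline_imax: float = 0.0   # optional clearance decline, fraction
    cl_decline_t50: float = 60.0   # days; invented default, configurable
    # TGI truth
    ks_median: float = 0.025
    ks_log_sd: float = 0.60
    kg_median: float = 0.0035
    kg_log_sd: float = 0.70
    kg_tumor_size_coef: float = 0.30   # loading of log(KG) on log(size/63)
    sld_noise: float = 0.10
    visit_interval_days: float = 42.0
    n_visits: int = 8
    evaluable_fraction: float = 0.91
    # OS truth (log-normal AFT)
    os_intercept: float = 4.04
    os_coefs: dict = field(default_factory=lambda: {
        "log_kg": -0.40, "ecog_gt0": -0.35, "log_tumor_size": -0.30,
        "log_albumin": 0.90, "log_ldh": -0.30, "log_alp": -0.20,
        "pdl1": 0.20,
    })
    os_scale: float = 0.85
    study_length_days: float = 1100.0
    accrual_days: float = 365.0
    dropout_rate: float = 5e-5   # 1/day exponential dropout hazard
    # binary endpoint truth
    endpoint_rates: dict = field(default_factory=lambda: {
        "orr": 0.157, "ae_grade3plus": 0.170, "aesi": 0.243})
    exposure_slopes: dict = field(default_factory=lambda: {
        "orr": 0.0, "ae_grade3plus": 0.0, "aesi": 0.0})
    exposure_metric: str = "auc_c1"
    model: PopPKModel | None = None

    def with_(self, **kw) -> "TrialConfig":
        return replace(self, **kw)

    def validate(self) -> None:
        if self.n_patients <= 0:
            raise ValueError("n_patients must be positive")
        for frac in (self.female_fraction, self.ada_positive_fraction,
                     self.ecog_gt0_fraction, self.pdl1_fraction,
                     self.evaluable_fraction):
            if not 0 <= frac <= 1:
                raise ValueError("fractions must lie in [0, 1]")
        for sd in (self.weight_log_sd, self.tumor_size_log_sd, self.sld_noise,
                   self.ks_log_sd, self.kg_log_sd, self.os_scale):
            if sd < 0:
                raise ValueError("spreads must be nonnegative")
        if not 0 <= self.cl_decline_imax < 1:
            raise ValueError("cl_decline_imax must lie in [0, 1)")


@dataclass
class SyntheticTrial:
    """One generated trial: analysis tables plus ground truth."""

    patients: pd.DataFrame     # covariates per patient
    pk: pd.DataFrame           # event records (doses + noisy observations)
    sld: pd.DataFrame          # longitudinal SLD (long format)
    survival: pd.DataFrame     # id, time_days, event
    endpoints: pd.DataFrame    # binary endpoints + exposure metrics
    truth_pk: pd.DataFrame     # individual PK parameters + etas
    truth_tgi: pd.DataFrame    # individual BSLD/KS/KG
    config: TrialConfig

    def to_dir(self, path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        for name in ("patients", "pk", "sld", "survival", "endpoints",
                     "truth_pk", "truth_tgi"):
            getattr(self, name).to_csv(path / f"{name}.csv", index=False)


def _draw_covariates(cfg: TrialConfig, rng: np.random.Generator) -> pd.DataFrame:
    n = cfg.n_patients
    sex = np.where(rng.uniform(size=n) < cfg.female_fraction, "F", "M")
    med = np.where(sex == "F", cfg.weight_median["F"], cfg.weight_median["M"])
    weight = np.exp(rng.normal(np.log(med), cfg.weight_log_sd))
    weight = np.clip(weight, *WEIGHT_TRUNCATION)
    albumin = np.maximum(rng.normal(cfg.albumin_mean, cfg.albumin_sd, n), 20.0)
    tumor_size = np.exp(rng.normal(np.log(cfg.tumor_size_median),
                                   cfg.tumor_size_log_sd, n))
    tumor_size = np.clip(tumor_size, 10.0, 350.0)
    return pd.DataFrame({
        "id": np.arange(n),
        "sex": sex,
        "weight": weight,
        "albumin": albumin,
        "tumor_size": tumor_size,
        "ada": np.where(rng.uniform(size=n) < cfg.ada_positive_fraction,
                        "positive", "negative"),
        "ecog": (rng.uniform(size=n) < cfg.ecog_gt0_fraction).astype(int),
        "ldh": np.exp(rng.normal(0.0, cfg.ldh_log_sd, n)),
        "alp": np.exp(rng.normal(0.0, cfg.alp_log_sd, n)),
        "pdl1": (rng.uniform(size=n) < cfg.pdl1_fraction).astype(int),
        "tumor_type": cfg.tumor_type,
    })


def _realise_pk(cfg: TrialConfig, patients: pd.DataFrame,
                rng: np.random.Generator) -> pd.DataFrame:
    model = cfg.model or PopPKModel.default()
    etas = model.draw_etas(len(patients), rng)
    rows = []
    for (_, p), eta in zip(patients.iterrows(), etas):
        cov = {"weight": p.weight, "sex": p.sex, "albumin": p.albumin,
               "tumor_size": p.tumor_size, "ada": p.ada}
        pk = model.individual_params(cov, eta)
        rows.append({"id": p.id, "CL": pk.CL, "V1": pk.V1, "Q": pk.Q,
                     "V2": pk.V2, "eta_cl": eta[0], "eta_v1": eta[1],
                     "eta_q": eta[2], "eta_v2": eta[3]})
    return pd.DataFrame(rows)


def _ode_concentrations(CL, V1, Q, V2, dose_times, amounts, durations,
                        obs_times, imax, t50):
    """Central concentrations with time-varying clearance, by segment-wise
    ODE integration of the two-compartment infusion system."""
    breaks = sorted({0.0, *dose_times, *(dt + du for dt, du in
                                         zip(dose_times, durations)),
                     *obs_times, max(obs_times) + 1e-9})
    rate_of = np.zeros(len(breaks))
    for dt, amt, du in zip(dose_times, amounts, durations):
        for i, b in enumerate(breaks[:-1]):
            if dt - 1e-12 <= b < dt + du - 1e-12:
                rate_of[i] += amt / du

    def rhs(t, y, rate):
        cl_t = CL * (1.0 - imax * t / (t50 + t))
        a1, a2 = y
        da1 = rate - (cl_t / V1) * a1 - (Q / V1) * a1 + (Q / V2) * a2
        da2 = (Q / V1) * a1 - (Q / V2) * a2
        return [da1, da2]

    y = np.zeros(2)
    out = {}
    for i in range(len(breaks) - 1):
        t0, t1 = breaks[i], breaks[i + 1]
        if t1 - t0 < 1e-12:
            continue
        wanted = [t for t in obs_times if t0 < t <= t1]
        t_eval = sorted(set(wanted + [t1]))
        sol = solve_ivp(rhs, (t0, t1), y, args=(rate_of[i],), t_eval=t_eval,
                        rtol=1e-8, atol=1e-10, method="LSODA")
        for t, a1 in zip(sol.t, sol.y[0]):
            out[round(t, 9)] = a1 / V1
        y = sol.y[:, -1]
    c0 = 0.0 if 0.0 not in obs_times else out.get(0.0, 0.0)
    return np.array([out.get(round(t, 9), c0) if t > 0 else 0.0
                     for t in obs_times])


def generate_pk_only(cfg: TrialConfig, seed: int | None = None,
                     patients: pd.DataFrame | None = None,
                     truth_pk: pd.DataFrame | None = None) -> pd.DataFrame:
    """Generate an event-record PK dataset (doses + noisy observations).

    Sampling occasions: for each dose number in ``cfg.pk_sample_doses``, a
    pre-dose trough (at the dose time) and an end-of-infusion peak.  With
    ``cl_decline_imax > 0`` the observations come from the time-varying
    clearance model; otherwise from the static closed form.
    """
    cfg.validate()
    rng = np.random.default_rng(seed)
    model = cfg.model or PopPKModel.default()
    if patients is None:
        patients = _draw_covariates(cfg, rng)
    if truth_pk is None:
        truth_pk = _realise_pk(cfg, patients, rng)

    reg = cfg.regimen
    tinf = reg.infusion_duration_days
    n_doses = reg.n_doses
    sample_doses = [d for d in cfg.pk_sample_doses if d <= n_doses]
    rows = []
    from dosematch.pk import profile_from_events

    for (_, p), (_, ind) in zip(patients.iterrows(), truth_pk.iterrows()):
        dose = reg.dose_for(sex=p.sex, weight=p.weight)
        dose_times = np.arange(n_doses) * reg.interval_days
        amounts = np.full(n_doses, dose)
        durations = np.full(n_doses, tinf)
        obs_times = []
        for d in sample_doses:
            td = (d - 1) * reg.interval_days
            if d > 1:
                obs_times.append(td)          # pre-dose trough
            obs_times.append(td + tinf)       # end-of-infusion peak
        obs_times.append(reg.interval_days)   # end of first interval
        obs_times = np.array(sorted(set(obs_times)))

        if cfg.cl_decline_imax > 0:
            conc = _ode_concentrations(ind.CL, ind.V1, ind.Q, ind.V2,
                                       dose_times, amounts, durations,
                                       obs_times, cfg.cl_decline_imax,
                                       cfg.cl_decline_t50)
        else:
            from dosematch.pk import PKParameters
            conc = profile_from_events(
                PKParameters(ind.CL, ind.V1, ind.Q, ind.V2),
                dose_times, amounts, durations, obs_times)

        dv = conc * (1.0 + model.sigma_prop * rng.standard_normal(len(conc)))
        dv = np.maximum(dv + model.sigma_add * rng.standard_normal(len(conc)), 0.0)

        cov_cols = {"WT": p.weight, "SEX": p.sex, "ALB": p.albumin,
                    "TUMSZ": p.tumor_size, "ADA": p.ada}
        events = []
        for t, c in zip(obs_times, dv):
            events.append({"ID": p.id, "TIME": t, "AMT": 0.0, "RATE": 0.0,
                           "DV": c, "EVID": 0, "MDV": 0, "_k": 0, **cov_cols})
        for td in dose_times:
            events.append({"ID": p.id, "TIME": td, "AMT": dose,
                           "RATE": dose / tinf, "DV": 0.0, "EVID": 1,
                           "MDV": 1, "_k": 1, **cov_cols})
        events.sort(key=lambda r: (r["TIME"], r["_k"]))
        rows.extend(events)
    df = pd.DataFrame(rows).drop(columns="_k")
    return df


def _exposure_metrics(cfg: TrialConfig, patients: pd.DataFrame,
                      truth_pk: pd.DataFrame) -> pd.DataFrame:
    doses = np.array([cfg.regimen.dose_for(sex=s, weight=w)
                      for s, w in zip(patients.sex, patients.weight)])
    arr = _exposure_arrays(truth_pk.CL.to_numpy(), truth_pk.V1.to_numpy(),
                           truth_pk.Q.to_numpy(), truth_pk.V2.to_numpy(),
                           doses, cfg.regimen)
    out = pd.DataFrame({"id": patients.id})
    for k in ("auc_c1", "cmin_c1", "cmax_c1"):
        out[k] = arr[k]
    return out


def generate_trial(cfg: TrialConfig, seed: int | None = None,
                   include_pk_dataset: bool = True) -> SyntheticTrial:
    """Generate a complete synthetic trial arm (see module docstring).

    ``include_pk_dataset=False`` skips the event-record PK table (the
    slowest part) for replicate studies that need only the derived
    exposure, SLD, survival and endpoint tables.
    """
    cfg.validate()
    rng = np.random.default_rng(seed)
    patients = _draw_covariates(cfg, rng)
    truth_pk = _realise_pk(cfg, patients, rng)
    n = cfg.n_patients

    # --- tumor dynamics ---------------------------------------------------
    bsld = patients.tumor_size.to_numpy()
    log_ts = np.log(bsld / cfg.tumor_size_median)
    ks = np.exp(rng.normal(np.log(cfg.ks_median), cfg.ks_log_sd, n))
    kg = np.exp(np.log(cfg.kg_median) + cfg.kg_tumor_size_coef * log_ts
                + rng.normal(0.0, cfg.kg_log_sd, n))
    truth_tgi = pd.DataFrame({"id": patients.id, "bsld": bsld, "ks": ks,
                              "kg": kg, "log_kg": np.log(kg)})

    evaluable = rng.uniform(size=n) < cfg.evaluable_fraction
    visit_times = np.arange(cfg.n_visits + 1) * cfg.visit_interval_days
    sld_rows = []
    for i in range(n):
        times = visit_times if evaluable[i] else visit_times[:1]
        clean = sld_model(times, bsld[i], ks[i], kg[i])
        noisy = clean * np.exp(rng.normal(0.0, cfg.sld_noise, len(times)))
        for t, v in zip(times, noisy):
            sld_rows.append({"id": patients.id.iloc[i], "time_days": float(t),
                             "sld_mm": float(v)})
    sld = pd.DataFrame(sld_rows)

    # --- survival ---------------------------------------------------------
    lp = (cfg.os_intercept
          + cfg.os_coefs.get("log_kg", 0.0) * np.log(kg)
          + cfg.os_coefs.get("ecog_gt0", 0.0) * (patients.ecog > 0)
          + cfg.os_coefs.get("log_tumor_size", 0.0) * log_ts
          + cfg.os_coefs.get("log_albumin", 0.0) * np.log(patients.albumin / 40.0)
          + cfg.os_coefs.get("log_ldh", 0.0) * np.log(patients.ldh)
          + cfg.os_coefs.get("log_alp", 0.0) * np.log(patients.alp)
          + cfg.os_coefs.get("pdl1", 0.0) * patients.pdl1)
    t_event = np.exp(lp + cfg.os_scale * rng.standard_normal(n))
    admin_cens = cfg.study_length_days - rng.uniform(0, cfg.accrual_days, n)
    if cfg.dropout_rate > 0:
        dropout = rng.exponential(1.0 / cfg.dropout_rate, n)
    else:
        dropout = np.full(n, np.inf)
    cens = np.minimum(admin_cens, dropout)
    time_obs = np.maximum(np.minimum(t_event, cens), 0.5)
    survival = pd.DataFrame({
        "id": patients.id, "time_days": time_obs,
        "event": (t_event <= cens).astype(int),
    })

    # --- binary endpoints vs exposure --------------------------------------
    exposure = _exposure_metrics(cfg, patients, truth_pk)
    x = np.log(exposure[cfg.exposure_metric].to_numpy())
    z = (x - x.mean()) / x.std() if x.std() > 0 else np.zeros(n)
    endpoints = exposure.copy()
    for name, rate in cfg.endpoint_rates.items():
        beta0 = np.log(rate / (1.0 - rate))
        slope = cfg.exposure_slopes.get(name, 0.0)
        p = 1.0 / (1.0 + np.exp(-(beta0 + slope * z)))
        endpoints[name] = (rng.uniform(size=n) < p).astype(int)
    endpoints["tumor_type"] = cfg.tumor_type

    if include_pk_dataset:
        pk = generate_pk_only(cfg, patients=patients, truth_pk=truth_pk,
                              seed=int(rng.integers(2**31 - 1)))
    else:
        pk = pd.DataFrame(columns=["ID", "TIME", "AMT", "RATE", "DV",
                                   "EVID", "MDV"])

    return SyntheticTrial(patients=patients, pk=pk, sld=sld,
                          survival=survival, endpoints=endpoints,
                          truth_pk=truth_pk, truth_tgi=truth_tgi, config=cfg)


# ---------------------------------------------------------------------------
# presets
# ---------------------------------------------------------------------------

def oak_like(**kw) -> TrialConfig:
    """NSCLC arm: ~425 patients, ~91% TGI-evaluable, median OS near 467 days."""
    cfg = TrialConfig(n_patients=425, tumor_type="NSCLC",
                      evaluable_fraction=0.91, os_intercept=4.04)
    return cfg.with_(**kw)


def imvigor_like(**kw) -> TrialConfig:
    """UC arm: ~467 patients, ~82% TGI-evaluable, median OS near 344 days."""
    cfg = TrialConfig(n_patients=467, tumor_type="UC",
                      evaluable_fraction=0.82, os_intercept=3.71)
    return cfg.with_(**kw)


def impassion_like(**kw) -> TrialConfig:
    """q2w-dosed arm with rich trough sampling for pcVPC exercises."""
    cfg = TrialConfig(
        n_patients=200, tumor_type="TNBC", female_fraction=1.0,
        regimen=DosingRegimen(dose_mg=840, interval_days=14, n_doses=30,
                              name="840mg_q2w"),
        pk_sample_doses=(1, 2, 4, 6, 14, 30),
    )
    return cfg.with_(**kw)

PRESETS = {"oak-like": oak_like, "imvigor-like": imvigor_like,
           "impassion-like": impassion_like}
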