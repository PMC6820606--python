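"""Parametric TGI-OS model: screening, AFT fits, exposure tests, HR
simulation."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from dosematch.survival import (
    TGIOSModel,
    exposure_significant,
    prepare_os_covariates,
    screen_covariates,
    simulate_os_hr,
)


def _lognormal_aft_data(rng, n=300, beta=-0.4, scale=0.8, censor_at=None):
    x = rng.standard_normal(n)
    logt = 6.0 + beta * x + scale * rng.standard_normal(n)
    t = np.exp(logt)
    if censor_at is None:
        return pd.DataFrame({"time_days": t, "event": 1, "x": x})
    event = (t <= censor_at).astype(int)
    return pd.DataFrame({"time_days": np.minimum(t, censor_at),
                         "event": event, "x": x})


class TestScreening:
    def test_cox_estimate_recovers_known_exponential_log_hazard(self, rng):
        """Exponential survival with log-hazard b on a binary covariate."""
        n, b = 600, 0.7
        x = rng.integers(0, 2, n)
        t = rng.exponential(1.0 / (0.002 * np.exp(b * x)))
        df = pd.DataFrame({"time_days": t, "event": 1, "x": x})
        out = screen_covariates(df, ["x"]).iloc[0]
        assert abs(out.coef - b) < 2 * out.se
        assert out.km_median_low > out.km_median_high

    def test_null_covariate_p_values_uniform(self, rng):
        """P values for a covariate independent of survival are uniform."""
        ps = []
        for _ in range(150):
            df = pd.DataFrame({
                "time_days": rng.exponential(500, 120),
                "event": 1,
                "x": rng.standard_normal(120),
            })
            ps.append(screen_covariates(df, ["x"]).iloc[0].p)
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_too_few_events_rejected(self, rng):
        df = pd.DataFrame({"time_days": rng.exponential(500, 50),
                           "event": 0, "x": rng.standard_normal(50)})
        with pytest.raises(ValueError, match="events"):
            screen_covariates(df, ["x"])


class TestAFTFit:
    def test_no_covariate_lognormal_closed_form(self, rng):
        """Without covariates or censoring the log-normal AFT intercept and
        scale equal the sample mean and SD of log survival time."""
        df = _lognormal_aft_data(rng, n=250, beta=0.0)
        res = TGIOSModel(df, []).fit()
        logt = np.log(df.time_days)
        assert res.params["Intercept"] == pytest.approx(logt.mean(), abs=1e-4)
        assert res.scale == pytest.approx(logt.std(ddof=0), rel=1e-3)

    def test_coefficient_recovery_with_censoring(self, rng):
        df = _lognormal_aft_data(rng, n=800, beta=-0.4, censor_at=2000.0)
        res = TGIOSModel(df, ["x"]).fit()
        assert abs(res.params["x"] + 0.4) < 3 * res.bse["x"]

    def test_family_selection_by_aic(self, rng):
        df = _lognormal_aft_data(rng, n=400)
        res = TGIOSModel(df, ["x"], family="auto").fit()
        assert res.family in ("lognormal", "weibull", "loglogistic")
        explicit = TGIOSModel(df, ["x"], family=res.family).fit()
        assert res.aic == pytest.approx(explicit.aic)

    def test_rank_deficient_covariates_rejected(self, rng):
        df = _lognormal_aft_data(rng, n=100)
        df["x2"] = 2.0 * df.x
        with pytest.raises(ValueError, match="rank"):
            TGIOSModel(df, ["x", "x2"])

    def test_all_censored_rejected(self):
        df = pd.DataFrame({"time_days": np.full(50, 100.0), "event": 0,
                           "x": np.arange(50.0)})
        with pytest.raises(ValueError, match="events"):
            TGIOSModel(df, ["x"])

    def test_covariate_preparation_codes_standard_factors(self):
        raw = pd.DataFrame({
            "id": [1, 2], "kg": [0.004, 0.002], "ecog": [0, 1],
            "tumor_size": [63.0, 126.0], "albumin": [40.0, 30.0],
            "ldh": [1.0, 2.0], "alp": [1.0, 0.5], "pdl1": [1, 0],
            "tumor_type": ["NSCLC", "UC"],
        })
        cov = prepare_os_covariates(raw)
        assert cov.ecog_gt0.tolist() == [0.0, 1.0]
        assert cov.log_tumor_size.iloc[1] == pytest.approx(np.log(2))
        assert cov.tumor_type_uc.tolist() == [0.0, 1.0]
        assert cov.log_kg.iloc[0] == pytest.approx(np.log(0.004))


class TestExposureTest:
    def test_alpha_boundary_rule(self):
        assert not exposure_significant(0.011)
        assert exposure_significant(0.009)

    def test_direct_exposure_effect_detected(self, rng):
        n = 500
        x = rng.standard_normal(n)
        expo = rng.standard_normal(n)
        logt = 6.0 - 0.4 * x + 0.5 * expo + 0.7 * rng.standard_normal(n)
        df = pd.DataFrame({"time_days": np.exp(logt), "event": 1, "x": x})
        res = TGIOSModel(df, ["x"]).fit()
        out = res.test_exposure(expo)
        assert out.significant and out.lrt_p < 0.01

    def test_constant_exposure_rejected(self, rng):
        df = _lognormal_aft_data(rng, n=100)
        res = TGIOSModel(df, ["x"]).fit()
        with pytest.raises(ValueError, match="constant"):
            res.test_exposure(np.ones(len(df)))


class TestHRSimulation:
    def test_identical_arms_give_hr_near_one(self, rng):
        df = _lognormal_aft_data(rng, n=200)
        res = TGIOSModel(df, ["x"]).fit()
        cov = df[["x"]]
        out = simulate_os_hr(res, cov, cov, n_reps=80, seed=3,
                             resample_cols=("x",))
        row = out.iloc[0]
        assert row.hr_pi_lo < 1.0 < row.hr_pi_hi
        assert abs(row.hr_median - 1.0) < 0.15

    def test_exponential_special_case_matches_analytic_hr(self, rng):
        """For the exponential family (Weibull shape 1) the AFT coefficient
        maps to a proportional-hazards HR of exp(-rho * b)."""
        n = 800
        x = rng.integers(0, 2, n)
        b = 0.5  # AFT log-time effect
        t = rng.exponential(np.exp(6.0 + b * x))
        df = pd.DataFrame({"time_days": t, "event": 1, "x": x})
        res = TGIOSModel(df, ["x"], family="weibull").fit()
        assert res.scale == pytest.approx(1.0, abs=0.1)  # shape ~ 1
        treated = pd.DataFrame({"x": np.ones(300)})
        control = pd.DataFrame({"x": np.zeros(300)})
        out = simulate_os_hr(res, treated, control, n_reps=100, seed=9,
                             resample_cols=())
        analytic = np.exp(-res.scale * res.params["x"])
        assert out.iloc[0].hr_median == pytest.approx(analytic, rel=0.12)

    def test_hr_invariant_to_time_unit_rescaling(self, rng):
        df = _lognormal_aft_data(rng, n=150)
        res_d = TGIOSModel(df, ["x"]).fit()
        df_m = df.assign(time_days=df.time_days / 30.4375)
        res_m = TGIOSModel(df_m, ["x"]).fit()
        cov = df[["x"]]
        hr_d = simulate_os_hr(res_d, cov, cov, n_reps=40, seed=5,
                              resample_cols=("x",))
        hr_m = simulate_os_hr(res_m, cov, cov, n_reps=40, seed=5,
                              resample_cols=("x",))
        assert hr_m.iloc[0].hr_median == pytest.approx(hr_d.iloc[0].hr_median,
                                                       rel=1e-6)

    def test_small_quartile_groups_flagged(self, rng):
        df = _lognormal_aft_data(rng, n=24)
        res = TGIOSModel(df, ["x"]).fit()
        treated = df[["x"]].assign(expo=rng.lognormal(size=24))
        out = simulate_os_hr(res, treated, df[["x"]], n_reps=10, seed=1,
                             quartile_col="expo", resample_cols=("x",))
        assert out.small_group.all()
        assert len(out) == 4
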