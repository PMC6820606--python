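"""Exposure-response analysis of binary endpoints.

Binary endpoints (objective response, grade >= 3 adverse events, adverse
events of special interest) are modelled against a continuous cycle-1
exposure metric by univariate logistic regression, with the Wald test on
the exposure slope as the significance criterion.  Descriptive summaries
report event proportions with exact (Clopper-Pearson) 95% confidence
intervals by exposure quartile.  Strata (e.g. tumor types) are pooled when
their event frequencies are similar; the informal "similar" criterion is
made explicit as a configurable absolute-difference threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.stats.proportion import proportion_confint
from statsmodels.tools.sm_exceptions import PerfectSeparationError


class SeparationError(RuntimeError):
    """Complete separation: the slope is unbounded, no Wald P is reported."""


@dataclass
class ERLogitResults:
    """Results of a univariate exposure-response logistic fit.

    Slope and its Wald test are per unit of the exposure metric; the Wald
    two-sided P value is 2 * Phi(-|beta1 / SE|).
    """

    intercept: float
    slope: float
    intercept_se: float
    slope_se: float
    wald_z: float
    wald_p: float
    converged: bool
    n: int
    events: int
    exposure_name: str = "exposure"
    _sm_results: object | None = None

    def predict(self, exposure) -> np.ndarray:
        """Event probability at the given exposure values."""
        x = np.asarray(exposure, dtype=float)
        lp = self.intercept + self.slope * x
        return 1.0 / (1.0 + np.exp(-lp))

    def summary(self) -> str:
        lines = [
            "Exposure-response logistic regression",
            f"  exposure metric : {self.exposure_name}",
            f"  n / events      : {self.n} / {self.events}",
            f"  intercept       : {self.intercept: .4g} (SE {self.intercept_se:.3g})",
            f"  slope           : {self.slope: .4g} (SE {self.slope_se:.3g})",
            f"  Wald z / P      : {self.wald_z: .3f} / {self.wald_p:.4g}",
            f"  converged       : {self.converged}",
        ]
        return "\n".join(lines)


class ExposureResponseLogit:
    """Univariate logistic model of a binary endpoint vs continuous exposure.

    Parameters
    ----------
    endog : array-like of {0, 1}
        Binary outcome per patient.
    exposure : array-like
        Continuous exposure metric per patient (must be positive).
    exposure_name : str
        Label used in summaries.
    """

    def __init__(self, endog, exposure, exposure_name: str = "exposure"):
        self.endog = np.asarray(endog, dtype=float)
        self.exposure = np.asarray(exposure, dtype=float)
        self.exposure_name = exposure_name
        if self.endog.shape != self.exposure.shape:
            raise ValueError("endog and exposure must have the same length")
        if not np.all(np.isin(self.endog, [0.0, 1.0])):
            raise ValueError("outcome must be binary (0/1)")
        if len(np.unique(self.exposure)) < 2:
            raise ValueError("need >= 2 distinct exposure values")
        if self.endog.min() == self.endog.max():
            raise ValueError("all outcomes identical: logistic fit undefined")

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, exposure: str, outcome: str
                       ) -> "ExposureResponseLogit":
        sub = df[[exposure, outcome]].dropna()
        return cls(sub[outcome].to_numpy(), sub[exposure].to_numpy(),
                   exposure_name=exposure)

    def fit(self) -> ERLogitResults:
        import warnings

        from statsmodels.tools.sm_exceptions import PerfectSeparationWarning

        X = sm.add_constant(self.exposure)
        model = sm.Logit(self.endog, X)
        try:
            with np.errstate(all="ignore"), warnings.catch_warnings():
                warnings.simplefilter("ignore")
                warnings.simplefilter("error", PerfectSeparationWarning)
                res = model.fit(disp=False, maxiter=200)
        except (PerfectSeparationError, PerfectSeparationWarning) as exc:
            raise SeparationError("complete separation detected") from exc
        params = np.asarray(res.params)
        bse = np.asarray(res.bse)
        # statsmodels may converge to a huge slope instead of raising
        if not np.all(np.isfinite(bse)) or np.abs(params).max() > 1e6:
            raise SeparationError("complete or quasi-complete separation")
        z = params[1] / bse[1]
        from scipy.stats import norm
        p = 2.0 * norm.sf(abs(z))
        return ERLogitResults(
            intercept=float(params[0]), slope=float(params[1]),
            intercept_se=float(bse[0]), slope_se=float(bse[1]),
            wald_z=float(z), wald_p=float(p),
            converged=bool(res.mle_retvals.get("converged", False)),
            n=len(self.endog), events=int(self.endog.sum()),
            exposure_name=self.exposure_name, _sm_results=res,
        )


def fit_logistic(df: pd.DataFrame, exposure: str, outcome: str) -> ERLogitResults:
    """Convenience wrapper: fit the univariate ER logistic model."""
    return ExposureResponseLogit.from_dataframe(df, exposure, outcome).fit()


# ---------------------------------------------------------------------------
# descriptive summaries
# ---------------------------------------------------------------------------

def assign_quartiles(exposure: np.ndarray) -> np.ndarray:
    """Quartile index (1-4) by the empirical 25/50/75 percentiles.

    Values tied with an edge are assigned to the lower quartile.
    """
    exposure = np.asarray(exposure, dtype=float)
    edges = np.percentile(exposure, [25, 50, 75])
    return np.searchsorted(edges, exposure, side="left") + 1


def quartile_summary(df: pd.DataFrame, exposure: str, outcome: str,
                     alpha: float = 0.05) -> pd.DataFrame:
    """Event proportions with exact 95% CIs per exposure quartile.

    The last row ("pooled") gives the overall proportion.
    """
    sub = df[[exposure, outcome]].dropna()
    if len(sub) < 4:
        raise ValueError("need at least 4 observations for quartiles")
    x = sub[exposure].to_numpy()
    y = sub[outcome].to_numpy().astype(int)
    q = assign_quartiles(x)
    rows = []
    for k in (1, 2, 3, 4):
        mask = q == k
        n_k, ev_k = int(mask.sum()), int(y[mask].sum())
        lo, hi = (proportion_confint(ev_k, n_k, alpha=alpha, method="beta")
                  if n_k > 0 else (np.nan, np.nan))
        rows.append({"quartile": str(k), "n": n_k, "events": ev_k,
                     "proportion": ev_k / n_k if n_k else np.nan,
                     "ci_lo": lo, "ci_hi": hi})
    n, ev = len(y), int(y.sum())
    lo, hi = proportion_confint(ev, n, alpha=alpha, method="beta")
    rows.append({"quartile": "pooled", "n": n, "events": ev,
                 "proportion": ev / n, "ci_lo": lo, "ci_hi": hi})
    return pd.DataFrame(rows)


def pooled_proportion(events: int, n: int) -> float:
    """Pooled event percentage, reported at one decimal (printed convention)."""
    if n <= 0:
        raise ValueError("n must be positive")
    return round(100.0 * events / n, 1)


def pool_check(df: pd.DataFrame, stratum: str, outcome: str,
               threshold_pct: float = 5.0) -> pd.DataFrame:
    """Decide whether strata may be pooled for the ER analysis.

    Computes per-stratum event frequencies; pooling is recommended when the
    maximum absolute difference between stratum frequencies is below
    ``threshold_pct`` percentage points.
    """
    groups = df.groupby(stratum)[outcome]
    freqs = {}
    for name, g in groups:
        if len(g) == 0:
            raise ValueError(f"empty stratum {name!r}")
        freqs[name] = 100.0 * g.mean()
    if len(freqs) < 2:
        raise ValueError("need >= 2 strata for a pooling check")
    vals = np.array(list(freqs.values()))
    max_diff = float(vals.max() - vals.min())
    out = pd.DataFrame({
        "stratum": list(freqs), "n": groups.size().reindex(list(freqs)).to_numpy(),
        "frequency_pct": vals,
    })
    out.attrs["max_difference_pct"] = max_diff
    out.attrs["pooled"] = max_diff < threshold_pct
    return out


def subgroup_safety_summary(df: pd.DataFrame, group: str | pd.Series,
                            event_cols: list[str]) -> pd.DataFrame:
    """Per-subgroup n and event frequencies for each AE category.

    ``group`` is either a column name or a precomputed label per patient
    (e.g. observed Cmax above/below a predicted reference, or lowest vs
    upper-3 body-weight quartiles).  Empty subgroups are reported with
    n = 0 and undefined frequencies.
    """
    labels = df[group] if isinstance(group, str) else pd.Series(group, index=df.index)
    rows = []
    for name, idx in labels.groupby(labels).groups.items():
        sub = df.loc[idx]
        row = {"subgroup": name, "n": len(sub)}
        for col in event_cols:
            row[f"{col}_events"] = int(sub[col].sum())
            row[f"{col}_pct"] = 100.0 * sub[col].mean() if len(sub) else np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def weight_quartile_groups(weight: np.ndarray,
                           bounds=None) -> np.ndarray:
    """Label patients as 'lowest' vs 'upper3' body-weight quartile.

    Default split uses the phase-1 quartile bound (63.7 kg); pass explicit
    ``bounds=(q1_upper,)`` to override.
    """
    from dosematch.simulate import WEIGHT_QUARTILE_BOUNDS
    cut = bounds[0] if bounds else WEIGHT_QUARTILE_BOUNDS[0][1]
    weight = np.asarray(weight, dtype=float)
    return np.where(weight <= cut, "lowest", "upper3")
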