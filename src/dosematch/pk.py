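"""Closed-form two-compartment population-PK engine for IV-infused antibodies.

The structural model is a linear two-compartment disposition model with
zero-order (constant-rate) infusion into the central compartment.  Because
the kinetics are linear, multi-dose profiles are obtained by superposition of
time-shifted single-infusion solutions, and steady state has an exact
geometric-series closed form.  Units are fixed throughout the package:
time in days, doses in mg, volumes in L, clearances in L/day — so central
concentrations are natively ug/mL.

Between-patient variability is log-normal on each structural parameter
(multivariate eta on the log scale) and covariate effects are the
conventional population-PK forms: power functions of continuous covariates
normalised to a reference value, and multiplicative fold-changes for
categorical covariates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import yaml

PARAM_NAMES = ("CL", "V1", "Q", "V2")

#: covariates every patient record must carry
REQUIRED_COVARIATES = ("weight", "sex", "albumin", "tumor_size", "ada")


class CovariateError(ValueError):
    """Raised when a covariate vector is incomplete or invalid."""


@dataclass(frozen=True)
class PKParameters:
    """Individual disposition parameters (post-covariate, post-random-effect).

    CL : clearance, L/day
    V1 : central volume, L
    Q  : inter-compartmental clearance, L/day
    V2 : peripheral volume, L
    """

    CL: float
    V1: float
    Q: float
    V2: float

    def __post_init__(self) -> None:
        if self.CL <= 0 or self.V1 <= 0:
            raise ValueError("CL and V1 must be positive")
        if self.Q < 0 or self.V2 < 0:
            raise ValueError("Q and V2 must be nonnegative")

    @property
    def vss(self) -> float:
        """Steady-state volume of distribution, L."""
        return self.V1 + self.V2

    def hybrid_constants(self) -> tuple[float, float]:
        """Return the hybrid rate constants (alpha, beta), 1/day.

        beta is the terminal (slow) disposition rate; for a one-compartment
        degenerate model (Q == 0 or V2 == 0) alpha == beta == CL/V1.
        """
        lams, _ = _disposition(self.CL, self.V1, self.Q, self.V2)
        return float(np.max(lams)), float(np.min(lams))

    @property
    def terminal_half_life(self) -> float:
        """Terminal half-life ln(2)/beta, days."""
        _, beta = self.hybrid_constants()
        return math.log(2.0) / beta


@dataclass(frozen=True)
class DosingRegimen:
    """A repeated IV-infusion schedule.

    dose_mg may be a fixed flat dose; for weight- or sex-based dosing use
    ``mg_per_kg`` or ``sex_doses`` and resolve per patient with
    :meth:`dose_for`.  ``infusion_duration_days`` defaults to a 1-hour
    infusion.
    """

    dose_mg: float | None = None
    interval_days: float = 21.0
    infusion_duration_days: float = 1.0 / 24.0
    n_doses: int = 1
    mg_per_kg: float | None = None
    sex_doses: Mapping[str, float] | None = None
    name: str = ""

    def __post_init__(self) -> None:
        if self.interval_days <= 0:
            raise ValueError("interval_days must be positive")
        if not (0 < self.infusion_duration_days < self.interval_days):
            raise ValueError("infusion_duration_days must lie in (0, interval_days)")
        if self.n_doses < 1:
            raise ValueError("n_doses must be >= 1")
        if self.dose_mg is None and self.mg_per_kg is None and self.sex_doses is None:
            raise ValueError("one of dose_mg, mg_per_kg or sex_doses is required")
        if self.dose_mg is not None and self.dose_mg < 0:
            raise ValueError("dose_mg must be nonnegative")

    def dose_for(self, sex: str | None = None, weight: float | None = None) -> float:
        """Resolve the administered dose (mg) for a patient."""
        if self.dose_mg is not None:
            return float(self.dose_mg)
        if self.sex_doses is not None:
            if sex is None:
                raise ValueError("regimen is sex-dosed but no sex given")
            return float(self.sex_doses[sex])
        if weight is None:
            raise ValueError("regimen is mg/kg-dosed but no weight given")
        return float(self.mg_per_kg) * float(weight)

    def label(self) -> str:
        if self.name:
            return self.name
        dose = f"{self.dose_mg:g} mg" if self.dose_mg is not None else f"{self.mg_per_kg:g} mg/kg"
        return f"{dose} q{self.interval_days:g}d"


# ---------------------------------------------------------------------------
# closed-form infusion kinetics
# ---------------------------------------------------------------------------

def _disposition(CL, V1, Q, V2):
    """Eigen-decomposition of the two-compartment disposition system.

    Returns (lams, coefs) such that the central concentration during a
    constant-rate infusion at rate R0 starting at t=0 is

        C(t) = (R0 / V1) * sum_j coefs[j] * (1 - exp(-lams[j] * t))

    All arguments broadcast (numpy arrays allowed).  The identity
    sum_j coefs[j] = 1 / k10 ensures C(inf) = R0 / CL.
    """
    CL = np.asarray(CL, dtype=float)
    V1 = np.asarray(V1, dtype=float)
    Q = np.asarray(Q, dtype=float)
    V2 = np.asarray(V2, dtype=float)
    k10 = CL / V1
    one_cpt = (Q <= 0) | (V2 <= 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        k12 = np.where(one_cpt, 0.0, Q / V1)
        k21 = np.where(one_cpt, 0.0, Q / np.where(V2 > 0, V2, 1.0))
    s = k10 + k12 + k21
    disc = np.sqrt(np.maximum(s * s - 4.0 * k10 * k21, 0.0))
    alpha = 0.5 * (s + disc)
    beta = 0.5 * (s - disc)
    # guard against coincident roots (measure-zero in parameter space)
    close = np.abs(alpha - beta) < 1e-12 * alpha
    beta = np.where(close, beta * (1.0 - 1e-9) - 1e-15, beta)
    with np.errstate(divide="ignore", invalid="ignore"):
        coef_a = (k21 - alpha) / (alpha * (beta - alpha))
        coef_b = (k21 - beta) / (beta * (alpha - beta))
        coef_a = np.where(one_cpt, 0.0, coef_a)
        coef_b = np.where(one_cpt, 1.0 / k10, coef_b)
        beta = np.where(one_cpt, k10, beta)
        alpha = np.where(one_cpt, k10, alpha)
    lams = np.stack([alpha, beta], axis=-1)
    coefs = np.stack([coef_a, coef_b], axis=-1)
    return lams, coefs


def concentration_profile(
    params: PKParameters,
    regimen: DosingRegimen,
    times: Sequence[float] | np.ndarray,
    dose_mg: float | None = None,
) -> np.ndarray:
    """Concentration-time profile (ug/mL) under a repeated-dose regimen.

    Superposition of the closed-form single-infusion solution over the
    ``regimen.n_doses`` administrations.  Times before the first dose
    return 0.
    """
    times = np.asarray(times, dtype=float)
    dose = regimen.dose_for() if dose_mg is None else float(dose_mg)
    dose_times = np.arange(regimen.n_doses) * regimen.interval_days
    return profile_from_events(
        params,
        dose_times=dose_times,
        amounts=np.full(regimen.n_doses, dose),
        durations=np.full(regimen.n_doses, regimen.infusion_duration_days),
        times=times,
    )


def profile_from_events(
    params: PKParameters | tuple,
    dose_times: np.ndarray,
    amounts: np.ndarray,
    durations: np.ndarray,
    times: np.ndarray,
    param_arrays: tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray] | None = None,
) -> np.ndarray:
    """Concentration at `times` for an arbitrary infusion-event schedule.

    With ``param_arrays=(CL, V1, Q, V2)`` of shape (R,), a matrix of shape
    (R, len(times)) is returned (used to vectorise Monte Carlo replicates);
    otherwise a 1-D array over ``times``.
    """
    times = np.asarray(times, dtype=float)
    dose_times = np.asarray(dose_times, dtype=float)
    amounts = np.asarray(amounts, dtype=float)
    durations = np.asarray(durations, dtype=float)
    if param_arrays is None:
        CL, V1, Q, V2 = params.CL, params.V1, params.Q, params.V2
    else:
        CL, V1, Q, V2 = param_arrays
    lams, coefs = _disposition(CL, V1, Q, V2)  # (..., 2)
    lams = lams[..., None, :]   # (..., 1, 2)
    coefs = coefs[..., None, :]
    V1a = np.asarray(V1, dtype=float)[..., None]

    out = np.zeros(np.broadcast_shapes(np.shape(V1a), times.shape))
    for td, amt, tinf in zip(dose_times, amounts, durations):
        if amt == 0:
            continue
        rate = amt / tinf
        dt = times - td
        tt = np.clip(dt, 0.0, tinf)[..., None]        # time infused so far
        te = np.clip(dt - tinf, 0.0, None)[..., None]  # time since infusion end
        contrib = (rate / V1a) * np.sum(
            coefs * (1.0 - np.exp(-lams * tt)) * np.exp(-lams * te), axis=-1
        )
        out = out + np.where(dt >= 0, contrib, 0.0)
    return out


def steady_state_profile(
    params: PKParameters,
    regimen: DosingRegimen,
    times: Sequence[float] | np.ndarray,
    dose_mg: float | None = None,
    param_arrays=None,
) -> np.ndarray:
    """Steady-state concentration within one dosing interval.

    ``times`` are measured from the (steady-state) dose start and must lie
    in [0, interval].  Computed exactly as the infinite-superposition limit
    via the geometric series sum of the post-infusion exponential tails.
    """
    times = np.asarray(times, dtype=float)
    tau = regimen.interval_days
    tinf = regimen.infusion_duration_days
    if np.any(times < 0) or np.any(times > tau + 1e-9):
        raise ValueError("steady-state times must lie within one dosing interval")
    dose = regimen.dose_for() if dose_mg is None else float(dose_mg)
    rate = dose / tinf
    if param_arrays is None:
        CL, V1, Q, V2 = params.CL, params.V1, params.Q, params.V2
    else:
        CL, V1, Q, V2 = param_arrays
    lams, coefs = _disposition(CL, V1, Q, V2)
    lams = lams[..., None, :]
    coefs = coefs[..., None, :]
    V1a = np.asarray(V1, dtype=float)[..., None]

    tt = np.clip(times, 0.0, tinf)[..., None]
    te = np.clip(times - tinf, 0.0, None)[..., None]
    current = coefs * (1.0 - np.exp(-lams * tt)) * np.exp(-lams * te)
    # tails of all previous doses: sum_{n>=1} G_j exp(-lam (t + n*tau - tinf))
    gj = coefs * (1.0 - np.exp(-lams * tinf))
    tails = gj * np.exp(-lams * (times[..., None] + tau - tinf)) / (
        1.0 - np.exp(-lams * tau)
    )
    return (rate / V1a) * np.sum(current + tails, axis=-1)


# ---------------------------------------------------------------------------
# population model: covariates + between-patient variability
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CovariateEffect:
    """One covariate effect on one structural parameter.

    Continuous (power) form: multiplier = (value / reference) ** exponent.
    Categorical (fold) form: multiplier = fold when the covariate equals
    ``level``, else 1.
    """

    parameter: str
    covariate: str
    form: str  # "power" | "fold"
    reference: float | None = None
    exponent: float | None = None
    level: str | float | None = None
    fold: float | None = None

    def multiplier(self, covariates: Mapping[str, object]) -> float:
        value = covariates[self.covariate]
        if self.form == "power":
            value = float(value)  # type: ignore[arg-type]
            if value <= 0:
                raise CovariateError(
                    f"covariate {self.covariate!r} must be positive for a power "
                    f"effect (got {value})"
                )
            return (value / self.reference) ** self.exponent
        if self.form == "fold":
            return self.fold if value == self.level else 1.0
        raise ValueError(f"unknown covariate effect form {self.form!r}")


@dataclass
class PopPKModel:
    """Population-PK model: typical values, covariate model, variability.

    omega is the 4x4 log-scale variance-covariance matrix of the random
    effects, in parameter order (CL, V1, Q, V2).  sigma_prop / sigma_add are
    the residual-error magnitudes used only when simulating observed
    concentrations (synthetic data, VPC replicates) — individual predictions
    carry no residual error.
    """

    typical: PKParameters
    covariate_effects: list[CovariateEffect] = field(default_factory=list)
    omega: np.ndarray = field(default_factory=lambda: np.zeros((4, 4)))
    sigma_prop: float = 0.0
    sigma_add: float = 0.0
    reference_covariates: dict = field(default_factory=dict)
    name: str = "unnamed"

    def __post_init__(self) -> None:
        self.omega = np.asarray(self.omega, dtype=float)
        if self.omega.shape != (4, 4):
            raise ValueError("omega must be 4x4 in (CL, V1, Q, V2) order")
        if not np.allclose(self.omega, self.omega.T):
            raise ValueError("omega must be symmetric")
        eig = np.linalg.eigvalsh(self.omega)
        if eig.min() < -1e-10:
            raise ValueError("omega must be positive semidefinite")

    # -- individual realisation ------------------------------------------

    def covariate_multipliers(self, covariates: Mapping[str, object]) -> np.ndarray:
        missing = [c for c in REQUIRED_COVARIATES if c not in covariates]
        if missing:
            raise CovariateError(f"missing covariates: {missing}")
        mult = np.ones(4)
        for eff in self.covariate_effects:
            idx = PARAM_NAMES.index(eff.parameter)
            mult[idx] *= eff.multiplier(covariates)
        return mult

    def individual_params(
        self,
        covariates: Mapping[str, object],
        eta: Sequence[float] | np.ndarray | None = None,
    ) -> PKParameters:
        """Realise individual parameters: typical x covariates x exp(eta)."""
        if eta is None:
            eta = np.zeros(4)
        eta = np.asarray(eta, dtype=float)
        mult = self.covariate_multipliers(covariates) * np.exp(eta)
        typ = np.array([self.typical.CL, self.typical.V1, self.typical.Q, self.typical.V2])
        vals = typ * mult
        return PKParameters(*vals)

    def draw_etas(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Draw n multivariate-normal log-scale random-effect vectors."""
        if np.allclose(self.omega, 0):
            return np.zeros((n, 4))
        return rng.multivariate_normal(np.zeros(4), self.omega, size=n, method="cholesky")

    # -- serialisation ----------------------------------------------------

    @classmethod
    def from_dict(cls, cfg: Mapping) -> "PopPKModel":
        try:
            typ = cfg["typical"]
            typical = PKParameters(
                CL=float(typ["CL"]), V1=float(typ["V1"]),
                Q=float(typ["Q"]), V2=float(typ["V2"]),
            )
        except KeyError as exc:
            raise ValueError(f"model config missing typical value {exc}") from exc
        effects = []
        cov_cfg = cfg.get("covariates", {})
        for raw in cov_cfg.get("effects", []):
            if raw.get("parameter") not in PARAM_NAMES:
                raise ValueError(f"unknown parameter in covariate effect: {raw}")
            effects.append(
                CovariateEffect(
                    parameter=raw["parameter"],
                    covariate=raw["covariate"],
                    form=raw["form"],
                    reference=raw.get("reference"),
                    exponent=raw.get("exponent"),
                    level=raw.get("level"),
                    fold=raw.get("fold"),
                )
            )
        om = cfg.get("omega")
        if om is None:
            omega = np.zeros((4, 4))
        else:
            omega = _omega_from_lower_triangle(om)
        sigma = cfg.get("sigma", {})
        return cls(
            typical=typical,
            covariate_effects=effects,
            omega=omega,
            sigma_prop=float(sigma.get("prop", 0.0)),
            sigma_add=float(sigma.get("add", 0.0)),
            reference_covariates=dict(cov_cfg.get("reference", {})),
            name=str(cfg.get("name", "unnamed")),
        )

    @classmethod
    def from_yaml(cls, path) -> "PopPKModel":
        with open(path) as fh:
            cfg = yaml.safe_load(fh)
        if not isinstance(cfg, dict):
            raise ValueError(f"model config {path} is not a mapping")
        return cls.from_dict(cfg)

    @classmethod
    def default(cls) -> "PopPKModel":
        """The packaged default model calibrated to the printed PK summaries
        (CL 0.2 L/day, Vss 6.9 L, terminal half-life ~27 days)."""
        ref = resources.files("dosematch.data") / "default_atezolizumab.yaml"
        with resources.as_file(ref) as path:
            return cls.from_yaml(path)


def _omega_from_lower_triangle(rows: Sequence[Sequence[float]]) -> np.ndarray:
    """Build a symmetric 4x4 matrix from a lower-triangle row list."""
    omega = np.zeros((4, 4))
    if len(rows) != 4:
        raise ValueError("omega lower triangle must have 4 rows")
    for i, row in enumerate(rows):
        if len(row) != i + 1:
            raise ValueError("omega rows must have lengths 1..4")
        for j, val in enumerate(row):
            omega[i, j] = omega[j, i] = float(val)
    return omega
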