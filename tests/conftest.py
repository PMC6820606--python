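import numpy as np
import pytest

from dosematch.pk import DosingRegimen, PKParameters, PopPKModel


@pytest.fixture(scope="session")
def default_model() -> PopPKModel:
    return PopPKModel.default()


@pytest.fixture(scope="session")
def typical_params(default_model) -> PKParameters:
    return default_model.typical


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def q3w_single() -> DosingRegimen:
    return DosingRegimen(dose_mg=1200, interval_days=21, n_doses=1)


def random_pk_parameters(rng: np.random.Generator) -> PKParameters:
    """Random but physiologic two-compartment parameter sets (log-uniform)."""
    CL = float(np.exp(rng.uniform(np.log(0.05), np.log(1.0))))
    V1 = float(np.exp(rng.uniform(np.log(1.5), np.log(8.0))))
    Q = float(np.exp(rng.uniform(np.log(0.1), np.log(2.0))))
    V2 = float(np.exp(rng.uniform(np.log(1.0), np.log(8.0))))
    return PKParameters(CL=CL, V1=V1, Q=Q, V2=V2)


def ode_profile(params: PKParameters, regimen: DosingRegimen, times: np.ndarray
                ) -> np.ndarray:
    """Adaptive-step numerical ODE oracle for the two-compartment infusion
    model, independent of the closed-form engine."""
    from scipy.integrate import solve_ivp

    tinf = regimen.infusion_duration_days
    dose = regimen.dose_for()
    rate = dose / tinf

    def rhs(t, y):
        a1, a2 = y
        infusing = any(
            td <= t < td + tinf
            for td in np.arange(regimen.n_doses) * regimen.interval_days
        )
        inp = rate if infusing else 0.0
        da1 = inp - (params.CL / params.V1) * a1
        if params.Q > 0 and params.V2 > 0:
            da1 += -(params.Q / params.V1) * a1 + (params.Q / params.V2) * a2
            da2 = (params.Q / params.V1) * a1 - (params.Q / params.V2) * a2
        else:
            da2 = 0.0
        return [da1, da2]

    # integrate piecewise so infusion on/off switches are hit exactly
    breaks = sorted(
        {0.0, *(np.arange(regimen.n_doses) * regimen.interval_days),
         *(np.arange(regimen.n_doses) * regimen.interval_days + tinf),
         *times[times > 0], float(times.max())}
    )
    y = [0.0, 0.0]
    vals = {0.0: 0.0}
    for t0, t1 in zip(breaks[:-1], breaks[1:]):
        if t1 - t0 < 1e-12:
            continue
        sol = solve_ivp(rhs, (t0, t1), y, rtol=1e-11, atol=1e-12,
                        dense_output=True, max_step=(t1 - t0))
        y = sol.y[:, -1].tolist()
        for t in times[(times > t0) & (times <= t1)]:
            vals[float(t)] = float(sol.sol(t)[0]) / params.V1
    return np.array([vals.get(float(t), 0.0) for t in times])
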