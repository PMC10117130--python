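"""Staged nonlinear least-squares calibration of the kinetic parameters.

The model has a triangular dependency structure that the fitting exploits:

1. lignin decay (k1, k2) depends on the L series alone (closed form);
2. growth + substrate (mu_max, K_s, X_m, Y_XS, m_s, k_LD) require the ODE
   solution and take the lignin stage as fixed;
3. the gas-exchange laws (Y_XO, m_O) and (Y_CX, m_C) are exactly linear in
   their two free parameters given the fitted trajectory;
4. the Luedeking-Piret enzyme law, in integrated form
   P(t) - P0 = alpha*(X(t) - X0) + beta * int_0^t X dt,
   is likewise exactly linear in (alpha, beta).

Nonlinear stages run through a Levenberg-Marquardt driver (lmfit/MINPACK)
with seeded multi-start jitter; conditionally linear stages use bounded
linear least squares.  Residuals of jointly fitted responses are weighted
by the response's observed standard deviation so that biomass (~0.08 g/g)
and holocellulose (~0.5 g/g) contribute comparably.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import lmfit
import numpy as np
from scipy.optimize import lsq_linear

from .kinetics import lignin_closed_form, simulate_trajectory, Trajectory
from .params import InitialConditions, KineticParams

__all__ = [
    "FitConfig",
    "StageFit",
    "lm_driver",
    "fit_lignin",
    "fit_growth_substrate",
    "fit_gas_linear",
    "fit_enzyme",
]


@dataclass(frozen=True)
class FitConfig:
    """Optimiser and staging settings shared by the calibration stages.

    ``log_phase_end`` bounds the window of daily gas observations used by
    the linear OUR/CPR fits (growth is exponential out to day 14-22
    depending on treatment; the default window ends at day 14).
    ``n_starts`` jittered restarts guard the LM stages against local
    minima; ``seed`` makes the jitter reproducible.
    """

    fix_initial: bool = True
    log_phase_start: float = 1.0
    log_phase_end: float = 14.0
    n_starts: int = 5
    jitter_sd: float = 0.3
    seed: int = 0
    max_nfev: int = 2000
    xtol: float = 1e-12
    ftol: float = 1e-12
    corr_threshold: float = 0.95
    lignin_energy_sign: str = "as_printed"

    def __post_init__(self) -> None:
        if self.n_starts < 1:
            raise ValueError("n_starts must be >= 1")
        if not (0 <= self.log_phase_start < self.log_phase_end):
            raise ValueError("log-phase window must satisfy 0 <= start < end")


@dataclass
class StageFit:
    """Outcome of one calibration stage."""

    stage: str
    params: dict[str, float]
    stderr: dict[str, float | None]
    residuals: np.ndarray
    success: bool
    nfev: int
    message: str
    cov: np.ndarray | None = None
    param_order: tuple[str, ...] = ()
    flags: tuple[str, ...] = ()

    @property
    def sse(self) -> float:
        return float(np.sum(self.residuals**2))


class FitError(RuntimeError):
    """A calibration stage could not produce usable estimates."""


def lm_driver(
    residual_fn,
    parameters: lmfit.Parameters,
    config: FitConfig | None = None,
    rng: np.random.Generator | None = None,
) -> lmfit.minimizer.MinimizerResult:
    """Levenberg-Marquardt minimisation with seeded multi-start jitter.

    Runs ``config.n_starts`` restarts: the first from ``parameters`` as
    given, the rest from log-normally jittered copies of the free
    parameters (sign-preserving), and returns the lowest-SSE converged
    result.  Deterministic given the config seed.
    """
    config = config or FitConfig()
    if rng is None:
        rng = np.random.default_rng(config.seed)

    best = None
    for start in range(config.n_starts):
        p = parameters.copy()
        if start > 0:
            for name, par in p.items():
                if not par.vary or par.value == 0:
                    continue
                factor = float(np.exp(config.jitter_sd * rng.standard_normal()))
                val = par.value * factor
                lo, hi = par.min, par.max
                if np.isfinite(lo) and val <= lo:
                    val = lo + 0.5 * abs(par.value - lo)
                if np.isfinite(hi) and val >= hi:
                    val = hi - 0.5 * abs(hi - par.value)
                par.value = val
        try:
            res = lmfit.minimize(
                residual_fn, p, method="leastsq",
                max_nfev=config.max_nfev, xtol=config.xtol, ftol=config.ftol,
            )
        except Exception:  # singular steps on pathological starts
            continue
        sse = float(np.sum(np.asarray(res.residual) ** 2))
        if best is None or sse < best[0]:
            best = (sse, res)
    if best is None:
        raise FitError("all Levenberg-Marquardt starts failed")
    return best[1]


def _stage_from_lmfit(stage: str, res, order: tuple[str, ...],
                      flags: tuple[str, ...] = ()) -> StageFit:
    params = {n: float(res.params[n].value) for n in order}
    stderr = {
        n: (float(res.params[n].stderr) if res.params[n].stderr is not None else None)
        for n in order
    }
    cov = getattr(res, "covar", None)
    return StageFit(
        stage=stage, params=params, stderr=stderr,
        residuals=np.asarray(res.residual, dtype=float),
        success=bool(res.success), nfev=int(res.nfev),
        message=str(res.message), cov=cov, param_order=order, flags=flags,
    )


# ---------------------------------------------------------------------------
# stage 1: lignin decay
# ---------------------------------------------------------------------------

def fit_lignin(
    t,
    L,
    L0: float | None = None,
    fix_L0: bool = True,
    config: FitConfig | None = None,
) -> StageFit:
    """Fit the time-varying first-order lignin decay (k1, k2[, L0]).

    Least squares of the closed form L(t) = L0 exp((k1/k2)(e^{-k2 t}-1))
    against the observed lignin series.  ``L0`` defaults to the mean
    observation at the earliest day and is held fixed unless
    ``fix_L0=False``.  Requires >= 4 points; all L must be positive.
    """
    config = config or FitConfig()
    t = np.asarray(t, dtype=float)
    L = np.asarray(L, dtype=float)
    if t.shape != L.shape:
        raise ValueError("t and L must have equal length")
    if t.size < 4:
        raise ValueError(f"need >= 4 lignin observations, got {t.size}")
    if np.any(L <= 0):
        raise ValueError("all lignin observations must be > 0")

    if L0 is None:
        L0 = float(np.mean(L[t == t.min()]))

    # crude first-order guess from the endpoints
    t_span = t.max() - t.min()
    L_end = float(np.mean(L[t == t.max()]))
    k1_guess = max(np.log(L0 / max(L_end, 1e-12)) / max(t_span, 1.0), 1e-4)

    p = lmfit.Parameters()
    p.add("k1", value=k1_guess, min=0.0, max=1.0)
    p.add("k2", value=-0.01, min=-1.0, max=1.0)
    p.add("L0", value=L0, vary=not fix_L0, min=1e-9)

    def resid(pars):
        kp = KineticParams(
            mu_max=1, K_s=1, X_m=1, Y_XS=1,
            k1=pars["k1"].value, k2=pars["k2"].value,
        )
        return lignin_closed_form(t, pars["L0"].value, kp) - L

    res = lm_driver(resid, p, config)
    order = ("k1", "k2", "L0")
    flags = () if res.success else ("non_convergence",)
    return _stage_from_lmfit("lignin", res, order, flags)


# ---------------------------------------------------------------------------
# stage 2: growth + substrate
# ---------------------------------------------------------------------------

def fit_growth_substrate(
    t,
    X,
    S,
    ic: InitialConditions,
    lignin: dict[str, float],
    config: FitConfig | None = None,
    weights: tuple[float, float] | None = None,
) -> StageFit:
    """Jointly fit (mu_max, K_s, X_m, Y_XS, m_s, k_LD) to X and S series.

    Each Levenberg-Marquardt step re-integrates the coupled ODE system with
    the lignin stage held fixed, and stacks the X and S residuals weighted
    by each response's observed standard deviation (or supplied weights).
    Observations may carry replicates (repeated days).

    Flags ``mu_Ks_correlated`` when the estimated |corr(mu_max, K_s)|
    exceeds the config threshold, and ``at_bound`` when any estimate sits
    on its box constraint.
    """
    config = config or FitConfig()
    t = np.asarray(t, dtype=float)
    X = np.asarray(X, dtype=float)
    S = np.asarray(S, dtype=float)
    if not (t.shape == X.shape == S.shape):
        raise ValueError("t, X, S must have equal length")

    t_unique = np.unique(t)
    if t_unique[0] != ic.t0:
        raise ValueError("observations must include the initial day t0")
    idx = np.searchsorted(t_unique, t)

    w_X = float(np.std(X)) if weights is None else weights[0]
    w_S = float(np.std(S)) if weights is None else weights[1]
    w_X = w_X if w_X > 0 else max(float(np.mean(np.abs(X))), 1e-12)
    w_S = w_S if w_S > 0 else max(float(np.mean(np.abs(S))), 1e-12)

    X_max = float(np.max(X))
    p = lmfit.Parameters()
    p.add("mu_max", value=1.0, min=1e-6, max=10.0)
    p.add("K_s", value=0.5 * ic.S0, min=1e-6, max=10.0)
    p.add("X_m", value=1.05 * X_max, min=max(1.01 * ic.X0, 1e-6), max=1.0)
    p.add("Y_XS", value=0.25, min=1e-6, max=10.0)
    p.add("m_s", value=0.05, min=0.0, max=10.0)
    p.add("k_LD", value=0.5, min=-50.0, max=50.0)

    lig = {"k1": float(lignin["k1"]), "k2": float(lignin["k2"])}

    def resid(pars):
        kp = KineticParams(
            mu_max=pars["mu_max"].value, K_s=pars["K_s"].value,
            X_m=pars["X_m"].value, Y_XS=pars["Y_XS"].value,
            m_s=pars["m_s"].value, k_LD=pars["k_LD"].value, **lig,
        )
        try:
            traj = simulate_trajectory(
                ic, kp, t_unique, lignin_energy_sign=config.lignin_energy_sign,
            )
        except (RuntimeError, ValueError):
            return np.full(2 * t.size, 1e6)
        rX = (traj.X[idx] - X) / w_X
        rS = (traj.S[idx] - S) / w_S
        return np.concatenate([rX, rS])

    res = lm_driver(resid, p, config)
    order = ("mu_max", "K_s", "X_m", "Y_XS", "m_s", "k_LD")
    flags: list[str] = []
    if not res.success:
        flags.append("non_convergence")
    cov = getattr(res, "covar", None)
    if cov is not None and cov.shape[0] >= 2:
        var_names = list(res.var_names)
        if "mu_max" in var_names and "K_s" in var_names:
            i, j = var_names.index("mu_max"), var_names.index("K_s")
            denom = np.sqrt(cov[i, i] * cov[j, j])
            if denom > 0 and abs(cov[i, j] / denom) > config.corr_threshold:
                flags.append("mu_Ks_correlated")
    for name in order:
        par = res.params[name]
        if par.vary and (np.isclose(par.value, par.min) or np.isclose(par.value, par.max)):
            flags.append(f"at_bound:{name}")
    return _stage_from_lmfit("growth_substrate", res, order, tuple(flags))


# ---------------------------------------------------------------------------
# stage 3: gas exchange (conditionally linear)
# ---------------------------------------------------------------------------

def interval_regressors(traj: Trajectory, days) -> tuple[np.ndarray, np.ndarray]:
    """Interval-averaged (dX/dt, X) over daily windows [d-1, d].

    Daily headspace sampling integrates the instantaneous rate over 24 h,
    so the matching regressors are the daily biomass increment and the
    daily mean biomass (from the running integral of X on the trajectory).
    """
    days = np.asarray(days, dtype=float)
    tgrid = traj.t
    lo = np.searchsorted(tgrid, days - 1.0)
    hi = np.searchsorted(tgrid, days)
    if np.any(tgrid[lo] != days - 1.0) or np.any(tgrid[hi] != days):
        raise ValueError("trajectory grid must contain every day and day-1 point")
    dX_avg = traj.X[hi] - traj.X[lo]          # /1 d
    X_avg = traj.intX[hi] - traj.intX[lo]     # mean over 1-day window
    return dX_avg, X_avg


def fit_gas_linear(
    rates,
    dXdt_avg,
    X_avg,
    species: str = "O2",
    config: FitConfig | None = None,
) -> StageFit:
    """Fit the two-parameter linear gas law to daily rates.

    For O2: OUR = (1/Y_XO) dX/dt + m_O X, estimating (a, b) = (1/Y_XO, m_O);
    for CO2: CPR = Y_CX dX/dt + m_C X, estimating (a, b) = (Y_CX, m_C).
    Bounded (non-negative) linear least squares; exact for noise-free data.
    Requires >= 3 usable days.
    """
    rates = np.asarray(rates, dtype=float)
    dXdt_avg = np.asarray(dXdt_avg, dtype=float)
    X_avg = np.asarray(X_avg, dtype=float)
    if not (rates.shape == dXdt_avg.shape == X_avg.shape):
        raise ValueError("rates and regressors must have equal length")
    if rates.size < 3:
        raise ValueError(f"need >= 3 usable gas days, got {rates.size}")

    A = np.column_stack([dXdt_avg, X_avg])
    sol = lsq_linear(A, rates, bounds=(0.0, np.inf))
    a, b = sol.x
    resid = A @ sol.x - rates

    flags: list[str] = []
    if np.isclose(b, 0.0):
        flags.append("at_bound:maintenance")
    if np.isclose(a, 0.0):
        flags.append("at_bound:yield")

    # unweighted OLS covariance of (a, b) for standard errors
    dof = max(rates.size - 2, 1)
    s2 = float(resid @ resid) / dof
    try:
        cov = s2 * np.linalg.inv(A.T @ A)
        se = np.sqrt(np.diag(cov))
    except np.linalg.LinAlgError:
        cov, se = None, (None, None)

    if species.upper() == "O2":
        if a <= 0:
            raise FitError("OUR fit produced non-positive 1/Y_XO; no growth signal")
        params = {"Y_XO": 1.0 / a, "m_O": b}
        # delta method for Y_XO = 1/a
        se_y = (se[0] / a**2) if se[0] is not None else None
        stderr = {"Y_XO": se_y, "m_O": se[1]}
        order = ("Y_XO", "m_O")
    elif species.upper() == "CO2":
        params = {"Y_CX": a, "m_C": b}
        stderr = {"Y_CX": se[0], "m_C": se[1]}
        order = ("Y_CX", "m_C")
    else:
        raise ValueError(f"species must be 'O2' or 'CO2', got {species!r}")

    return StageFit(
        stage=f"gas_{species.upper()}", params=params, stderr=stderr,
        residuals=resid, success=True, nfev=1, message="linear least squares",
        cov=cov, param_order=order, flags=tuple(flags),
    )


# ---------------------------------------------------------------------------
# stage 4: enzyme (conditionally linear)
# ---------------------------------------------------------------------------

def fit_enzyme(
    t,
    P,
    traj: Trajectory,
    config: FitConfig | None = None,
) -> StageFit:
    """Fit the Luedeking-Piret constants (alpha, beta) in integrated form.

    P(t) - P0 = alpha*(X(t) - X0) + beta * int_0^t X dt is exactly linear
    in (alpha, beta) given the fitted trajectory; solved by non-negative
    linear least squares.  Observations may carry replicates.
    """
    t = np.asarray(t, dtype=float)
    P = np.asarray(P, dtype=float)
    if t.shape != P.shape:
        raise ValueError("t and P must have equal length")
    if t.size < 3:
        raise ValueError(f"need >= 3 enzyme observations, got {t.size}")

    idx = np.searchsorted(traj.t, t)
    if np.any(traj.t[idx] != t):
        raise ValueError("trajectory grid must contain every enzyme observation day")

    X0, P0 = traj.ic.X0, traj.ic.P0
    A = np.column_stack([traj.X[idx] - X0, traj.intX[idx]])
    y = P - P0
    sol = lsq_linear(A, y, bounds=(0.0, np.inf))
    alpha, beta = sol.x
    resid = A @ sol.x - y

    flags = tuple(
        f"at_bound:{n}" for n, v in (("alpha", alpha), ("beta", beta))
        if np.isclose(v, 0.0)
    )
    dof = max(y.size - 2, 1)
    s2 = float(resid @ resid) / dof
    try:
        cov = s2 * np.linalg.inv(A.T @ A)
        se = np.sqrt(np.diag(cov))
    except np.linalg.LinAlgError:
        cov, se = None, (None, None)

    return StageFit(
        stage="enzyme", params={"alpha": alpha, "beta": beta},
        stderr={"alpha": se[0], "beta": se[1]}, residuals=resid,
        success=True, nfev=1, message="linear least squares",
        cov=cov, param_order=("alpha", "beta"), flags=flags,
    )
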