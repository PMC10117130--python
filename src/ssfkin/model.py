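"""The top-level modelling object: build from tidy data, fit, inspect.

`SSFKineticsModel` is constructed from a destructive-sampling trajectory
table (biomass X, holocellulose S, lignin L, protein P per flask and day)
and optionally a daily headspace-gas table, then calibrated by the staged
nonlinear least-squares procedure in :mod:`ssfkin.estimation`:

>>> from ssfkin import SSFKineticsModel, datasets
>>> bundle = datasets.generate_treatment_dataset(
...     datasets.get_fixture("CS-TV52J"), n_replicates=3, seed=7)
>>> res = SSFKineticsModel.from_dataset(bundle).fit()
>>> print(res.summary())                           # doctest: +SKIP

All concentrations in the input tables are on the internal g per g
dry-basis scale; use :mod:`ssfkin.io` to read percent-unit CSV files.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd

from .estimation import (
    FitConfig,
    FitError,
    StageFit,
    fit_enzyme,
    fit_gas_linear,
    fit_growth_substrate,
    fit_lignin,
    interval_regressors,
)
from .gas import GasObservation, rate_from_headspace
from .kinetics import simulate_trajectory
from .params import InitialConditions, KineticParams
from .results import SSFKineticsResults

__all__ = ["SSFKineticsModel"]

_TRAJ_COLS = {"day", "X", "S", "L", "P"}
_GAS_COLS = {"day", "o2_drop", "co2_rise", "headspace_L", "temp_K", "substrate_g"}


class SSFKineticsModel:
    """Growth-kinetic model of one fungus x substrate SSF treatment.

    Parameters
    ----------
    trajectory : DataFrame
        Destructive-sampling observations with columns
        ``day, X, S, L, P`` (g/g dry basis) and optionally
        ``treatment, replicate``.  Must include day 0.
    gas_daily : DataFrame, optional
        Daily headspace observations with columns
        ``day, o2_drop, co2_rise, headspace_L, temp_K, substrate_g``
        (volume fractions over each 24 h interval).  Without it the gas
        stages are skipped.
    config : FitConfig, optional
        Optimiser/staging settings.
    """

    def __init__(
        self,
        trajectory: pd.DataFrame,
        gas_daily: pd.DataFrame | None = None,
        config: FitConfig | None = None,
        treatment: str | None = None,
    ) -> None:
        missing = _TRAJ_COLS - set(trajectory.columns)
        if missing:
            raise ValueError(f"trajectory table missing columns: {sorted(missing)}")
        if len(trajectory) == 0:
            raise ValueError("trajectory table is empty")
        if gas_daily is not None:
            gmissing = _GAS_COLS - set(gas_daily.columns)
            if gmissing:
                raise ValueError(f"gas table missing columns: {sorted(gmissing)}")
        self.trajectory = trajectory.sort_values("day", kind="stable").reset_index(drop=True)
        self.gas_daily = (
            gas_daily.sort_values("day", kind="stable").reset_index(drop=True)
            if gas_daily is not None else None
        )
        self.config = config or FitConfig()
        if treatment is None and "treatment" in trajectory.columns:
            vals = trajectory["treatment"].unique()
            treatment = str(vals[0]) if len(vals) == 1 else None
        self.treatment = treatment
        if 0.0 not in set(self.trajectory["day"].astype(float)):
            raise ValueError("trajectory must include day-0 observations")

    # -- constructors -------------------------------------------------------

    @classmethod
    def from_dataset(cls, bundle, config: FitConfig | None = None) -> "SSFKineticsModel":
        """Build from a :class:`~ssfkin.datasets.DatasetBundle`."""
        return cls(bundle.trajectory, bundle.gas_daily, config=config,
                   treatment=bundle.treatment)

    @classmethod
    def from_csv(
        cls,
        trajectory_path,
        gas_path=None,
        config: FitConfig | None = None,
        treatment: str | None = None,
    ) -> "SSFKineticsModel":
        """Build from the packaged CSV schemas (percent units on disk)."""
        from . import io as _io

        traj = _io.read_trajectory_csv(trajectory_path)
        gas = _io.read_gas_csv(gas_path) if gas_path is not None else None
        if treatment is not None:
            traj = traj[traj["treatment"] == treatment].reset_index(drop=True)
            if gas is not None:
                gas = gas[gas["treatment"] == treatment].reset_index(drop=True)
            if len(traj) == 0:
                raise ValueError(f"no rows for treatment {treatment!r}")
        return cls(traj, gas, config=config, treatment=treatment)

    # -- fitting ------------------------------------------------------------

    def _initial_conditions(self) -> InitialConditions:
        day0 = self.trajectory[self.trajectory["day"] == 0.0]
        return InitialConditions(
            X0=float(day0["X"].mean()), S0=float(day0["S"].mean()),
            L0=float(day0["L"].mean()), P0=float(day0["P"].mean()),
        )

    def fit(self) -> SSFKineticsResults:
        """Run the staged calibration and return a results object.

        Stages: lignin closed form; growth + substrate over re-integrated
        ODE solutions (Levenberg-Marquardt, seeded multi-start); then,
        conditionally on the fitted trajectory, the linear gas-exchange
        and Luedeking-Piret enzyme fits.
        """
        cfg = self.config
        df = self.trajectory
        ic = self._initial_conditions()
        t_obs = df["day"].to_numpy(dtype=float)

        stage_fits: dict[str, StageFit] = {}

        lig = fit_lignin(
            t_obs, df["L"].to_numpy(dtype=float),
            L0=ic.L0 if cfg.fix_initial else None,
            fix_L0=cfg.fix_initial, config=cfg,
        )
        stage_fits["lignin"] = lig
        if not cfg.fix_initial:
            ic = replace(ic, L0=lig.params["L0"])

        growth = fit_growth_substrate(
            t_obs, df["X"].to_numpy(dtype=float), df["S"].to_numpy(dtype=float),
            ic, lig.params, config=cfg,
        )
        stage_fits["growth_substrate"] = growth

        estimates = {**growth.params, "k1": lig.params["k1"], "k2": lig.params["k2"]}

        # dense daily grid (plus sampling days) for regressors and predictions
        t_dense = np.union1d(np.unique(t_obs), np.arange(0.0, np.ceil(t_obs.max()) + 1))
        partial = KineticParams(**{**_NEUTRAL_GAS, **estimates})
        traj = simulate_trajectory(ic, partial, t_dense,
                                   lignin_energy_sign=cfg.lignin_energy_sign)

        if self.gas_daily is not None and len(self.gas_daily):
            gas = self.gas_daily
            mask = (gas["day"] >= cfg.log_phase_start) & (gas["day"] <= cfg.log_phase_end)
            win = gas[mask]
            if len(win) >= 3:
                days = win["day"].to_numpy(dtype=float)
                our = np.array([
                    rate_from_headspace(GasObservation(
                        delta_c=row.o2_drop, delta_t=1.0, V=row.headspace_L,
                        m_S=row.substrate_g, T=row.temp_K, species="O2"))
                    for row in win.itertuples()
                ])
                cpr = np.array([
                    rate_from_headspace(GasObservation(
                        delta_c=row.co2_rise, delta_t=1.0, V=row.headspace_L,
                        m_S=row.substrate_g, T=row.temp_K, species="CO2"))
                    for row in win.itertuples()
                ])
                dX_avg, X_avg = interval_regressors(traj, days)
                stage_fits["gas_O2"] = fit_gas_linear(our, dX_avg, X_avg, "O2", cfg)
                stage_fits["gas_CO2"] = fit_gas_linear(cpr, dX_avg, X_avg, "CO2", cfg)
                estimates.update(stage_fits["gas_O2"].params)
                estimates.update(stage_fits["gas_CO2"].params)

        enz = fit_enzyme(t_obs, df["P"].to_numpy(dtype=float), traj, cfg)
        stage_fits["enzyme"] = enz
        estimates.update(enz.params)

        params = KineticParams(**{**_NEUTRAL_GAS, **estimates})
        fitted = simulate_trajectory(ic, params, t_dense,
                                     lignin_energy_sign=cfg.lignin_energy_sign)
        return SSFKineticsResults(
            model=self, params=params, ic=ic,
            stage_fits=stage_fits, fitted_trajectory=fitted,
        )

    # -- simulation ---------------------------------------------------------

    def simulate(self, params: KineticParams, t_grid=None,
                 ic: InitialConditions | None = None):
        """Forward-simulate the coupled system under given parameters."""
        if ic is None:
            ic = self._initial_conditions()
        if t_grid is None:
            t_max = float(self.trajectory["day"].max())
            t_grid = np.union1d(self.trajectory["day"].unique().astype(float),
                                np.arange(0.0, t_max + 1))
        return simulate_trajectory(ic, params, t_grid,
                                   lignin_energy_sign=self.config.lignin_energy_sign)


# placeholder values for gas/enzyme parameters not yet fitted at the time a
# partial trajectory is needed (they do not feed back into X/S/L/P dynamics)
_NEUTRAL_GAS = {
    "Y_XO": 1.0, "m_O": 0.0, "Y_CX": 0.0, "m_C": 0.0, "alpha": 0.0, "beta": 0.0,
}
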