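"""Results container for a fitted SSF growth-kinetic model."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING

import numpy as np
import pandas as pd

from .diagnostics import residual_table, runs_test, sigma_est
from .kinetics import Trajectory
from .params import InitialConditions, KineticParams, PARAM_NAMES, PARAM_UNITS

if TYPE_CHECKING:  # pragma: no cover
    from .model import SSFKineticsModel

__all__ = ["SSFKineticsResults"]

_RESPONSES = ("X", "S", "L", "P")


@dataclass
class SSFKineticsResults:
    """Estimates, uncertainties and diagnostics from a staged calibration.

    Attributes
    ----------
    params : KineticParams
        The assembled parameter vector (all four stages merged).
    ic : InitialConditions
        The initial conditions the fit conditioned on.
    stage_fits : dict
        Per-stage :class:`~ssfkin.estimation.StageFit` records carrying
        residuals, standard errors, covariance and convergence flags.
    fitted_trajectory : Trajectory
        Model solution under the estimates on a dense daily grid.
    """

    model: "SSFKineticsModel"
    params: KineticParams
    ic: InitialConditions
    stage_fits: dict
    fitted_trajectory: Trajectory

    # -- convenience accessors ---------------------------------------------

    @property
    def converged(self) -> bool:
        return all(sf.success for sf in self.stage_fits.values())

    @property
    def flags(self) -> tuple[str, ...]:
        out = []
        for name, sf in self.stage_fits.items():
            out.extend(f"{name}:{f}" for f in sf.flags)
        return tuple(out)

    def stderr(self, name: str):
        """Standard error of one parameter, if its stage reported one."""
        for sf in self.stage_fits.values():
            if name in sf.stderr:
                return sf.stderr[name]
        return None

    # -- predictions and residuals -----------------------------------------

    def predict(self, t=None) -> pd.DataFrame:
        """Model trajectory as a tidy frame (day, X, S, L, P, OUR, CPR)."""
        traj = self.fitted_trajectory
        if t is not None:
            from .kinetics import simulate_trajectory

            traj = simulate_trajectory(
                self.ic, self.params, np.asarray(t, dtype=float),
                lignin_energy_sign=self.model.config.lignin_energy_sign,
            )
        return pd.DataFrame({
            "day": traj.t, "X": traj.X, "S": traj.S, "L": traj.L, "P": traj.P,
            "OUR": traj.OUR, "CPR": traj.CPR,
            "cum_O2": traj.cum_O2, "cum_CO2": traj.cum_CO2,
        })

    def residual_tables(self) -> pd.DataFrame:
        """Per-point residuals of every destructive-sampling response."""
        obs = self.model.trajectory
        traj = self.fitted_trajectory
        idx = np.searchsorted(traj.t, obs["day"].to_numpy(dtype=float))
        pred = {"X": traj.X[idx], "S": traj.S[idx],
                "L": traj.L[idx], "P": traj.P[idx]}
        parts = [
            residual_table(
                obs["day"], obs[r], pred[r], response=r,
                treatment=self.model.treatment or "",
            )
            for r in _RESPONSES
        ]
        return pd.concat(parts, ignore_index=True)

    def sigma_est_table(self, ddof: int = 0) -> pd.Series:
        """Standard error of the estimate per response."""
        tbl = self.residual_tables()
        return tbl.groupby("response").apply(
            lambda g: sigma_est(g["observed"], g["predicted"], ddof=ddof),
            include_groups=False,
        ).rename("sigma_est")

    def residual_randomness(self) -> pd.DataFrame:
        """Runs-test summary of residual sign patterns per response."""
        tbl = self.residual_tables()
        rows = []
        for resp, g in tbl.groupby("response"):
            # mean residual per day, in time order, so replicate scatter
            # does not mask a systematic trend
            daily = g.groupby("day")["residual"].mean().sort_index()
            rt = runs_test(daily.to_numpy())
            rows.append({
                "response": resp, "n_runs": rt.n_runs,
                "expected_runs": rt.expected_runs, "z": rt.z,
                "systematic": rt.systematic,
            })
        return pd.DataFrame(rows)

    # -- reporting ----------------------------------------------------------

    def params_frame(self) -> pd.DataFrame:
        """Parameter estimates with units and standard errors."""
        rows = []
        for name in PARAM_NAMES:
            if not any(name in sf.params for sf in self.stage_fits.values()):
                continue
            rows.append({
                "parameter": name, "unit": PARAM_UNITS[name],
                "estimate": getattr(self.params, name),
                "stderr": self.stderr(name),
            })
        return pd.DataFrame(rows)

    def summary(self) -> str:
        """Plain-text summary table in the statsmodels spirit."""
        lines = []
        title = "SSF growth-kinetics fit"
        if self.model.treatment:
            title += f" — {self.model.treatment}"
        lines.append(title)
        lines.append("=" * 72)
        lines.append(
            f"observations: {len(self.model.trajectory)} trajectory rows"
            + (f", {len(self.model.gas_daily)} gas rows"
               if self.model.gas_daily is not None else "")
        )
        lines.append(f"converged: {self.converged}   flags: "
                     + (", ".join(self.flags) if self.flags else "none"))
        lines.append("-" * 72)
        lines.append(f"{'parameter':<10}{'estimate':>12}{'std err':>12}  unit")
        for _, row in self.params_frame().iterrows():
            se = f"{row.stderr:.4g}" if row.stderr is not None and np.isfinite(row.stderr or np.nan) else "--"
            lines.append(
                f"{row.parameter:<10}{row.estimate:>12.4g}{se:>12}  {row.unit}"
            )
        lines.append("-" * 72)
        sig = self.sigma_est_table()
        lines.append("sigma_est: " + "  ".join(
            f"{r}={v:.3g}" for r, v in sig.items()))
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover
        trt = self.model.treatment or "?"
        return (f"<SSFKineticsResults {trt}: mu_max={self.params.mu_max:.3f}, "
                f"X_m={self.params.X_m:.3f}, converged={self.converged}>")
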