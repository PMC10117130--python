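"""Synthetic datasets emulating the six fungus x substrate SSF treatments.

Six treatments — camelina straw (CS) or switchgrass (SG) colonised by
*Trametes versicolor* m4D (CDH-deficient mutant), *T. versicolor* 52J
(wild type) or *Phanerochaete chrysosporium* (PC) — each carry a full
published parameter vector used here as generating truth.  The design
emulated is a 30-day batch: destructive sampling of triplicate flasks on
days {0,2,4,6,8,10,12,14,18,22,26,30} for biomass/holocellulose/lignin/
protein, plus daily headspace gas sampling after pure-O2 flushing.

Replicate noise is multiplicative Gaussian (per-response coefficient of
variation, truncated at zero), so responses of very different magnitude
are corrupted comparably.  The published record reports triplicates but
no replicate variance; the 5% default CV is a stand-in, not an inference
from the data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .gas import headspace_from_rate, headspace_volume, DEFAULT_TEMPERATURE_K
from .kinetics import Trajectory, simulate_trajectory
from .params import InitialConditions, KineticParams

__all__ = [
    "TREATMENTS",
    "TreatmentFixture",
    "NoiseModel",
    "builtin_fixtures",
    "get_fixture",
    "design_grid",
    "generate_treatment_dataset",
    "DatasetBundle",
]

#: destructive-sampling days of the batch design
SAMPLING_DAYS = (0, 2, 4, 6, 8, 10, 12, 14, 18, 22, 26, 30)
#: daily headspace-gas sampling days
GAS_DAYS = tuple(range(1, 31))

TREATMENTS = ("CS-TVm4D", "CS-TV52J", "CS-PC", "SG-TVm4D", "SG-TV52J", "SG-PC")

# untreated-substrate composition, g per g dry matter
_SUBSTRATE_COMPOSITION = {"CS": (0.586, 0.373), "SG": (0.662, 0.263)}

# published parameter vectors, one column per treatment
# order: mu_max, K_s, X_m, Y_XS, m_s, k_LD, k1, k2, Y_XO, m_O, Y_CX, m_C, alpha, beta
_TABLE = {
    "CS-TVm4D": (1.005, 0.682, 0.052, 0.180, 0.086, 0.528, 0.008, -0.043,
                 0.080, 9.525, 20.394, 6.886, 0.089, 0.011),
    "CS-TV52J": (1.210, 0.664, 0.084, 0.249, 0.081, 0.787, 0.005, -0.053,
                 0.018, 20.567, 26.741, 17.091, 0.154, 0.005),
    "CS-PC":    (1.005, 0.415, 0.070, 0.213, 0.059, 0.744, 0.003, -0.057,
                 0.037, 13.046, 16.055, 8.983, 0.105, 0.009),
    "SG-TVm4D": (0.911, 0.690, 0.047, 0.152, 0.100, 1.037, 0.005, -0.043,
                 0.078, 9.712, 10.300, 5.517, 0.124, 0.009),
    "SG-TV52J": (1.216, 0.539, 0.094, 0.296, 0.085, 2.962, 0.003, -0.037,
                 0.009, 19.434, 19.901, 18.094, 0.126, 0.008),
    "SG-PC":    (0.788, 0.418, 0.073, 0.247, 0.046, -0.058, 0.003, -0.025,
                 0.031, 13.526, 22.109, 8.998, 0.139, 0.008),
}

#: default inoculum biomass, g X per g dry substrate (liquid inoculum carries
#: an unmeasured small biomass; 0.5% of dry matter is assumed)
DEFAULT_X0 = 0.005
DEFAULT_P0 = 0.0
DEFAULT_SUBSTRATE_G = 3.0


@dataclass(frozen=True)
class TreatmentFixture:
    """One treatment's generating truth: parameters plus initial conditions."""

    treatment: str
    params: KineticParams
    ic: InitialConditions

    @property
    def substrate(self) -> str:
        return self.treatment.split("-")[0]

    @property
    def fungus(self) -> str:
        return self.treatment.split("-", 1)[1]


@dataclass(frozen=True)
class NoiseModel:
    """Multiplicative Gaussian replicate noise, truncated at zero.

    ``cv`` is the per-response coefficient of variation; a value of 0
    reproduces the model trajectory exactly.
    """

    cv: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cv < 0:
            raise ValueError("cv must be >= 0")


def builtin_fixtures(
    X0: float = DEFAULT_X0, P0: float = DEFAULT_P0
) -> dict[str, TreatmentFixture]:
    """All six packaged treatment fixtures keyed by treatment id."""
    out = {}
    for trt in TREATMENTS:
        params = KineticParams(*_TABLE[trt])
        S0, L0 = _SUBSTRATE_COMPOSITION[trt.split("-")[0]]
        out[trt] = TreatmentFixture(
            treatment=trt,
            params=params,
            ic=InitialConditions(X0=X0, S0=S0, L0=L0, P0=P0),
        )
    return out


def get_fixture(treatment: str, **kwargs) -> TreatmentFixture:
    if treatment not in TREATMENTS:
        raise KeyError(f"unknown treatment {treatment!r}; expected one of {TREATMENTS}")
    return builtin_fixtures(**kwargs)[treatment]


def design_grid() -> tuple[np.ndarray, np.ndarray]:
    """(destructive sampling days, daily gas days) of the batch design."""
    return np.array(SAMPLING_DAYS, dtype=float), np.array(GAS_DAYS, dtype=float)


@dataclass(frozen=True)
class DatasetBundle:
    """One generated treatment dataset: tidy tables plus provenance.

    ``trajectory`` has columns (treatment, replicate, day, X, S, L, P) on
    the g/g scale; ``gas_daily`` has per-day headspace fractions
    (o2_drop, co2_rise as volume fractions consumed/produced over 24 h)
    alongside flask geometry.  ``truth`` is the noise-free trajectory the
    noise was applied to.
    """

    treatment: str
    trajectory: pd.DataFrame
    gas_daily: pd.DataFrame
    truth: Trajectory
    fixture: TreatmentFixture
    noise: NoiseModel
    n_replicates: int
    n_truncated: int = 0


def generate_treatment_dataset(
    fixture: TreatmentFixture,
    noise: NoiseModel | None = None,
    n_replicates: int = 3,
    seed: int | None = None,
    substrate_g: float = DEFAULT_SUBSTRATE_G,
    headspace_L: float | None = None,
    temperature_K: float = DEFAULT_TEMPERATURE_K,
) -> DatasetBundle:
    """Simulate one treatment on the batch design and add replicate noise.

    The trajectory table holds the destructive-sampling responses; the gas
    table holds daily interval-averaged OUR/CPR re-expressed as headspace
    volume-fraction changes (what a GC actually measures).  Fully
    reproducible given ``seed`` (overrides the NoiseModel's seed when
    given).  Noise draws that would push a concentration negative are
    re-truncated to zero, counted and warned about.
    """
    if noise is None:
        noise = NoiseModel(cv=0.0)
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    rng = np.random.default_rng(noise.seed if seed is None else seed)
    if headspace_L is None:
        headspace_L = headspace_volume(substrate_dry_g=substrate_g)

    days, gas_days = design_grid()
    # single integration over the union grid: sampling days + daily gas days
    t_union = np.union1d(days, np.concatenate([[0.0], gas_days]))
    truth = simulate_trajectory(fixture.ic, fixture.params, t_union)
    idx_samp = np.searchsorted(t_union, days)

    n_truncated = 0
    rows = []
    for rep in range(1, n_replicates + 1):
        for j, day in zip(idx_samp, days):
            vals = {}
            for name, series in (("X", truth.X), ("S", truth.S),
                                 ("L", truth.L), ("P", truth.P)):
                mu = max(series[j], 0.0)
                v = mu * (1.0 + noise.cv * rng.standard_normal()) if noise.cv > 0 else mu
                if v < 0:
                    n_truncated += 1
                    v = 0.0
                vals[name] = v
            rows.append({"treatment": fixture.treatment, "replicate": rep,
                         "day": day, **vals})
    trajectory = pd.DataFrame(rows)

    # daily interval-averaged rates from the cumulative gas channels
    idx_gas = np.searchsorted(t_union, np.concatenate([[0.0], gas_days]))
    cum_O2 = truth.cum_O2[idx_gas]
    cum_CO2 = truth.cum_CO2[idx_gas]
    our_daily = np.diff(cum_O2)   # mmol (g d.b.)^-1 d^-1 over 1-day intervals
    cpr_daily = np.diff(cum_CO2)

    gas_rows = []
    for rep in range(1, n_replicates + 1):
        for k, day in enumerate(gas_days):
            our = our_daily[k]
            cpr = cpr_daily[k]
            if noise.cv > 0:
                our = max(our * (1.0 + noise.cv * rng.standard_normal()), 0.0)
                cpr = max(cpr * (1.0 + noise.cv * rng.standard_normal()), 0.0)
            o2_drop, cl1 = headspace_from_rate(our, headspace_L, substrate_g,
                                               T=temperature_K)
            co2_rise, cl2 = headspace_from_rate(cpr, headspace_L, substrate_g,
                                                T=temperature_K)
            if cl1 or cl2:
                n_truncated += 1
            gas_rows.append({
                "treatment": fixture.treatment, "replicate": rep, "day": float(day),
                "o2_drop": o2_drop, "co2_rise": co2_rise,
                "headspace_L": headspace_L, "temp_K": temperature_K,
                "substrate_g": substrate_g,
            })
    gas_daily = pd.DataFrame(gas_rows)

    if n_truncated:
        warnings.warn(
            f"{n_truncated} noisy draws truncated to the physical range "
            f"for {fixture.treatment}", stacklevel=2,
        )
    return DatasetBundle(
        treatment=fixture.treatment, trajectory=trajectory, gas_daily=gas_daily,
        truth=truth, fixture=fixture, noise=noise, n_replicates=n_replicates,
        n_truncated=n_truncated,
    )
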