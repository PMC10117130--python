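"""Headspace gas arithmetic: volume-percent changes <-> molar exchange rates.

Flasks are flushed daily with pure oxygen; the next day's headspace
composition gives the O2 consumed (concentration decrease) and CO2
produced (concentration increase) over the interval.  The ideal-gas
conversion uses R = 0.082057 L atm mol^-1 K^-1 at the incubation
temperature (301 K default) and 1 atm; rates are expressed in
mmol per g dry substrate per day — the x1000 mol->mmol factor lives in
this module only.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

__all__ = [
    "GAS_CONSTANT",
    "DEFAULT_TEMPERATURE_K",
    "GasObservation",
    "rate_from_headspace",
    "headspace_from_rate",
    "co2_o2_ratio",
    "cumulative_gas",
    "headspace_volume",
]

GAS_CONSTANT = 0.082057  # L atm mol^-1 K^-1
DEFAULT_TEMPERATURE_K = 301.0
DEFAULT_PRESSURE_ATM = 1.0


@dataclass(frozen=True)
class GasObservation:
    """One headspace measurement interval for a single gas species.

    ``delta_c`` is the change in volume fraction (0-1) over ``delta_t``
    days: an O2 decrease or a CO2 increase, both entered as positive for
    uptake/production.  ``V`` is the headspace volume in litres after
    correcting for the volume taken up by the moist substrate; ``C_air``
    is the species' volume fraction in the flushing gas (1.0 for O2 under
    pure-oxygen flushing).
    """

    delta_c: float
    delta_t: float
    V: float
    m_S: float
    T: float = DEFAULT_TEMPERATURE_K
    P_atm: float = DEFAULT_PRESSURE_ATM
    C_air: float = 1.0
    species: Literal["O2", "CO2"] = "O2"

    def __post_init__(self) -> None:
        if self.delta_t <= 0:
            raise ValueError("delta_t must be > 0")
        if self.V <= 0:
            raise ValueError("headspace volume V must be > 0")
        if self.m_S <= 0:
            raise ValueError("dry substrate mass m_S must be > 0")
        if not (0 < self.C_air <= 1):
            raise ValueError("C_air must be in (0, 1]")
        if abs(self.delta_c) > 1:
            raise ValueError("|delta_c| cannot exceed 1 (volume fraction)")


def rate_from_headspace(obs: GasObservation) -> float:
    """Molar exchange rate [mmol (g d.b.)^-1 d^-1] from one headspace interval.

    r = (delta_c/delta_t) * V*P/(R*T*C_air) * (1/m_S) * 1000.
    """
    mol_per_L = obs.P_atm / (GAS_CONSTANT * obs.T)
    return (obs.delta_c / obs.delta_t) * obs.V * mol_per_L / obs.C_air / obs.m_S * 1000.0


def headspace_from_rate(
    rate: float,
    V: float,
    m_S: float,
    delta_t: float = 1.0,
    T: float = DEFAULT_TEMPERATURE_K,
    P_atm: float = DEFAULT_PRESSURE_ATM,
    C_air: float = 1.0,
) -> tuple[float, bool]:
    """Invert the headspace formula: rate -> expected delta_c.

    Returns ``(delta_c, clamped)``; the fraction change is clamped to
    [0, 1] with ``clamped=True`` when the un-clamped value falls outside
    the physical range (a rate too large for the flask's gas inventory).
    Exact inverse of :func:`rate_from_headspace` when not clamped.
    """
    if V <= 0 or m_S <= 0 or delta_t <= 0:
        raise ValueError("V, m_S and delta_t must be > 0")
    mol_per_L = P_atm / (GAS_CONSTANT * T)
    delta_c = rate * delta_t * m_S * C_air / (V * mol_per_L * 1000.0)
    clamped = not (0.0 <= delta_c <= 1.0)
    return float(np.clip(delta_c, 0.0, 1.0)), clamped


def co2_o2_ratio(our, cpr):
    """Daily respiratory quotient CPR/OUR.

    Days with zero OUR are masked (returned as NaN alongside a boolean
    validity mask) rather than propagated silently.  A ratio below one
    indicates simultaneous lignin oxidation alongside holocellulose
    metabolism — the weaker the CO2/O2 ratio, the stronger the
    delignification activity.

    Returns
    -------
    ratio : ndarray
        CPR/OUR elementwise; NaN where OUR == 0.
    valid : ndarray of bool
        False on the masked (OUR == 0) days.
    """
    our = np.asarray(our, dtype=float)
    cpr = np.asarray(cpr, dtype=float)
    if our.shape != cpr.shape:
        raise ValueError(f"length mismatch: OUR {our.shape} vs CPR {cpr.shape}")
    valid = our != 0.0
    ratio = np.full(our.shape, np.nan)
    np.divide(cpr, our, out=ratio, where=valid)
    return ratio, valid


def cumulative_gas(days, rates) -> np.ndarray:
    """Trapezoidal cumulative gas total [mmol (g d.b.)^-1] over daily rates.

    ``days`` must be strictly increasing.  Non-decreasing whenever the
    rates are non-negative.
    """
    days = np.asarray(days, dtype=float)
    rates = np.asarray(rates, dtype=float)
    if days.shape != rates.shape:
        raise ValueError("days and rates must have equal length")
    if days.size > 1 and np.any(np.diff(days) <= 0):
        raise ValueError("days must be strictly increasing (sorted, unique)")
    if days.size == 0:
        return np.array([])
    out = np.empty_like(rates)
    # rectangle from t=0 when the series starts later than day 0
    out[0] = rates[0] * days[0]
    if days.size > 1:
        increments = 0.5 * (rates[1:] + rates[:-1]) * np.diff(days)
        out[1:] = out[0] + np.cumsum(increments)
    return out


def headspace_volume(
    flask_volume_L: float = 0.250,
    substrate_dry_g: float = 3.0,
    moisture_wb: float = 0.75,
    bulk_density_g_per_mL: float = 0.45,
) -> float:
    """Headspace gas volume [L]: flask minus dry-solid and water volumes.

    The substrate solid volume uses an assumed bulk density (default
    0.45 g/mL) and the water volume follows from the wet-basis moisture
    content (mass water = dry mass * mc/(1-mc), density 1 g/mL).
    Defaults emulate a 250 mL flask with 3 g dry substrate at 75% w.b.,
    giving roughly 0.23 L.
    """
    if not (0 <= moisture_wb < 1):
        raise ValueError("moisture_wb must be in [0, 1)")
    water_mL = substrate_dry_g * moisture_wb / (1.0 - moisture_wb)
    solid_mL = substrate_dry_g / bulk_density_g_per_mL
    V = flask_volume_L - (water_mL + solid_mL) / 1000.0
    if V <= 0:
        raise ValueError("substrate volume exceeds flask volume")
    return V
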