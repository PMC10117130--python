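"""Parameter and state containers for the SSF growth-kinetic model.

All concentrations are stored internally as mass fractions on a dry-basis
scale (g per g dry substrate, 0-1).  File I/O and printed reports use
g per 100 g dry matter; the conversion lives in :mod:`ssfkin.io` only.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from typing import Iterator

__all__ = ["KineticParams", "InitialConditions", "StateVector", "PARAM_NAMES"]

#: canonical ordering of the fourteen kinetic parameters
PARAM_NAMES = (
    "mu_max", "K_s", "X_m", "Y_XS", "m_s", "k_LD",
    "k1", "k2", "Y_XO", "m_O", "Y_CX", "m_C", "alpha", "beta",
)

#: human-readable units for reports (concentrations on the g/g scale)
PARAM_UNITS = {
    "mu_max": "d^-1",
    "K_s": "g S (g d.b.)^-1",
    "X_m": "g X (g d.b.)^-1",
    "Y_XS": "g X (g S)^-1",
    "m_s": "g S (g X)^-1 d^-1",
    "k_LD": "g S (g L)^-1",
    "k1": "d^-1",
    "k2": "d^-1",
    "Y_XO": "g X (mmol O2)^-1",
    "m_O": "mmol O2 (g X)^-1 d^-1",
    "Y_CX": "mmol CO2 (g X)^-1",
    "m_C": "mmol CO2 (g X)^-1 d^-1",
    "alpha": "g protein (g X)^-1",
    "beta": "g protein (g X)^-1 d^-1",
}


@dataclass(frozen=True)
class KineticParams:
    """Full parameter vector of the coupled growth/consumption/gas/enzyme model.

    Parameters
    ----------
    mu_max : float
        Maximum specific growth rate [d^-1].
    K_s : float
        Half-saturation constant: substrate concentration at which the
        specific growth rate is half of ``mu_max`` [g S (g d.b.)^-1].
    X_m : float
        Self-inhibiting factor / carrying-capacity biomass [g X (g d.b.)^-1].
    Y_XS : float
        Substrate-to-biomass yield [g X (g S)^-1].
    m_s : float
        Substrate maintenance coefficient [g S (g X)^-1 d^-1].
    k_LD : float
        Lignin-degradation energy coefficient (dimensionless mass ratio);
        may be negative (a statistically insignificant fit).
    k1, k2 : float
        Lignin decay constants of the time-varying first-order coefficient
        ``k_l(t) = k1 * exp(-k2 * t)``; ``k2`` may be negative, which makes
        delignification accelerate with time.
    Y_XO : float
        Oxygen-to-biomass yield [g X (mmol O2)^-1].
    m_O : float
        O2 maintenance coefficient [mmol O2 (g X)^-1 d^-1].
    Y_CX : float
        CO2-from-biomass yield [mmol CO2 (g X)^-1].
    m_C : float
        CO2 maintenance coefficient [mmol CO2 (g X)^-1 d^-1].
    alpha : float
        Growth-associated Luedeking-Piret constant [g protein (g X)^-1].
    beta : float
        Non-growth-associated Luedeking-Piret constant
        [g protein (g X)^-1 d^-1].
    """

    mu_max: float
    K_s: float
    X_m: float
    Y_XS: float
    m_s: float = 0.0
    k_LD: float = 0.0
    k1: float = 0.0
    k2: float = 0.0
    Y_XO: float = 1.0
    m_O: float = 0.0
    Y_CX: float = 0.0
    m_C: float = 0.0
    alpha: float = 0.0
    beta: float = 0.0

    def __post_init__(self) -> None:
        for name in ("mu_max", "K_s", "X_m", "Y_XS", "Y_XO"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")
        for name in ("m_s", "m_O", "m_C", "alpha", "beta", "k1"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")
        if self.Y_CX < 0:
            raise ValueError(f"Y_CX must be >= 0, got {self.Y_CX}")
        # k2 and k_LD are unconstrained in sign

    def replace(self, **updates: float) -> "KineticParams":
        return replace(self, **updates)

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    def __iter__(self) -> Iterator[float]:
        return iter(getattr(self, n) for n in PARAM_NAMES)


@dataclass(frozen=True)
class InitialConditions:
    """Day-0 state of a batch: inoculated biomass, substrate, lignin, protein.

    Concentrations share the internal g/g dry-basis scale.  ``X0`` must be
    strictly positive (the flask is inoculated) and below the carrying
    capacity of the parameter set it is simulated with.
    """

    X0: float
    S0: float
    L0: float
    P0: float = 0.0
    t0: float = 0.0

    def __post_init__(self) -> None:
        if self.X0 <= 0:
            raise ValueError(f"X0 must be > 0 (inoculated batch), got {self.X0}")
        if self.S0 <= 0 or self.L0 <= 0:
            raise ValueError("S0 and L0 must be > 0")
        if self.P0 < 0:
            raise ValueError("P0 must be >= 0")

    def as_array(self) -> tuple[float, float, float, float]:
        return (self.X0, self.S0, self.L0, self.P0)


@dataclass(frozen=True)
class StateVector:
    """One (X, S, L, P) concentration snapshot on the g/g dry-basis scale."""

    X: float
    S: float
    L: float
    P: float = 0.0

    def __post_init__(self) -> None:
        for name in ("X", "S", "L", "P"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")
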