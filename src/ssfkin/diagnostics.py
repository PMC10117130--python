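"""Model-adequacy checks and summary statistics for the kinetic fits.

Covers the standard error of the estimate per response, ordinary linear
regressions of gas-exchange rates on biomass, percent-reduction summaries
of the pretreatment outcome, and a runs-based check that residuals scatter
non-systematically around the fitted curves.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "sigma_est",
    "linear_gas_regression",
    "reduction_percent",
    "residual_table",
    "runs_test",
    "RunsTestResult",
]


def sigma_est(observed, predicted, ddof: int = 0) -> float:
    """Standard error of the estimate: sqrt(sum((obs-pred)^2) / (n - ddof)).

    The default convention divides by n (no degrees-of-freedom correction);
    pass ``ddof=p`` for the n-p convention.
    """
    observed = np.asarray(observed, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if observed.shape != predicted.shape:
        raise ValueError("observed and predicted must have equal length")
    n = observed.size
    if n < 2:
        raise ValueError(f"need >= 2 points, got {n}")
    if not 0 <= ddof < n:
        raise ValueError("ddof must satisfy 0 <= ddof < n")
    return float(np.sqrt(np.sum((observed - predicted) ** 2) / (n - ddof)))


def linear_gas_regression(X, rate) -> tuple[float, float, float]:
    """OLS regression of a gas-exchange rate on biomass: (slope, intercept, R2).

    R2 = 1 - SSE/SST, reported as a fraction in [0, 1]; multiply by 100
    for the percent convention used in reports.
    """
    X = np.asarray(X, dtype=float)
    rate = np.asarray(rate, dtype=float)
    if X.shape != rate.shape:
        raise ValueError("X and rate must have equal length")
    if X.size < 3:
        raise ValueError(f"need >= 3 points, got {X.size}")
    if np.std(X) == 0:
        raise ValueError("X has zero variance; regression undefined")
    res = stats.linregress(X, rate)
    return float(res.slope), float(res.intercept), float(res.rvalue**2)


def reduction_percent(initial: float, final: float) -> float:
    """Percent reduction 100*(initial - final)/initial; scale-invariant."""
    if initial <= 0:
        raise ValueError(f"initial concentration must be > 0, got {initial}")
    if final < 0:
        raise ValueError(f"final concentration must be >= 0, got {final}")
    return 100.0 * (initial - final) / initial


@dataclass(frozen=True)
class RunsTestResult:
    """Wald-Wolfowitz runs summary of residual signs.

    ``systematic`` is True when the observed number of sign runs falls
    more than ~2 SD below its expectation under randomness — long same-sign
    stretches, the signature of a mis-specified mean function.
    """

    n_runs: int
    n_pos: int
    n_neg: int
    expected_runs: float
    z: float
    systematic: bool


def runs_test(residuals, z_threshold: float = 1.96) -> RunsTestResult:
    """Runs test on residual signs (zeros dropped).

    A one-sided check for too few runs: clustered same-sign residuals
    indicate a trend the model failed to capture.
    """
    r = np.asarray(residuals, dtype=float)
    signs = np.sign(r[r != 0])
    n_pos = int(np.sum(signs > 0))
    n_neg = int(np.sum(signs < 0))
    n = n_pos + n_neg
    if n < 2 or n_pos == 0 or n_neg == 0:
        # one-sided sign pattern: cannot alternate, flag only if long
        return RunsTestResult(
            n_runs=1 if n else 0, n_pos=n_pos, n_neg=n_neg,
            expected_runs=float(n > 0), z=0.0, systematic=n >= 6,
        )
    n_runs = int(1 + np.sum(signs[1:] != signs[:-1]))
    mu = 1.0 + 2.0 * n_pos * n_neg / n
    var = 2.0 * n_pos * n_neg * (2.0 * n_pos * n_neg - n) / (n**2 * (n - 1))
    z = (n_runs - mu) / np.sqrt(var) if var > 0 else 0.0
    return RunsTestResult(
        n_runs=n_runs, n_pos=n_pos, n_neg=n_neg,
        expected_runs=mu, z=float(z), systematic=bool(z < -z_threshold),
    )


def residual_table(
    day, observed, predicted, response: str = "", treatment: str = ""
) -> pd.DataFrame:
    """Tidy per-point residual table with columns for downstream plots.

    Columns: treatment, response, day, observed, predicted, residual.
    Sorted by day so the runs summary reads the residuals in time order.
    """
    day = np.asarray(day, dtype=float)
    observed = np.asarray(observed, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if not (day.shape == observed.shape == predicted.shape):
        raise ValueError("day, observed and predicted must have equal length")
    df = pd.DataFrame({
        "treatment": treatment, "response": response, "day": day,
        "observed": observed, "predicted": predicted,
        "residual": observed - predicted,
    })
    return df.sort_values("day", kind="stable").reset_index(drop=True)
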