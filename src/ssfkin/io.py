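"""CSV schemas and unit conversion for the packaged file formats.

On disk, concentrations use the bioprocess-report convention of g per
100 g dry matter (columns ``X_pct, S_pct, L_pct, P_pct``); in memory
everything is a mass fraction (0-1).  The percent<->fraction conversion
happens exactly once, here.

Schemas
-------
trajectory.csv : treatment, replicate, day, X_pct, S_pct, L_pct, P_pct
gas_daily.csv  : treatment, replicate, day, o2_pct, co2_pct, headspace_L,
                 temp_K, substrate_g
fit_report.csv : parameter, unit, one column per treatment
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .params import PARAM_NAMES, PARAM_UNITS

__all__ = [
    "read_trajectory_csv",
    "write_trajectory_csv",
    "read_gas_csv",
    "write_gas_csv",
    "write_fit_report",
    "SchemaError",
]

_TRAJ_SCHEMA = ["treatment", "replicate", "day", "X_pct", "S_pct", "L_pct", "P_pct"]
_GAS_SCHEMA = ["treatment", "replicate", "day", "o2_pct", "co2_pct",
               "headspace_L", "temp_K", "substrate_g"]
_PCT = {"X_pct": "X", "S_pct": "S", "L_pct": "L", "P_pct": "P"}


class SchemaError(ValueError):
    """A CSV file violated the packaged schema; message carries row numbers."""


def _check_columns(df: pd.DataFrame, schema: list[str], path) -> None:
    missing = [c for c in schema if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")


def _check_numeric(df: pd.DataFrame, cols: list[str], path) -> pd.DataFrame:
    for c in cols:
        coerced = pd.to_numeric(df[c], errors="coerce")
        bad = df.index[coerced.isna() & df[c].notna()]
        if len(bad):
            rows = ", ".join(str(i + 2) for i in bad[:5])  # +2: header + 1-based
            raise SchemaError(f"{path}: non-numeric values in column {c!r} "
                              f"at file rows {rows}")
        if coerced.isna().any():
            rows = ", ".join(str(i + 2) for i in df.index[coerced.isna()][:5])
            raise SchemaError(f"{path}: empty cells in column {c!r} at file rows {rows}")
        df[c] = coerced
    return df


def read_trajectory_csv(path) -> pd.DataFrame:
    """Read a destructive-sampling table; returns g/g-fraction columns X,S,L,P."""
    path = Path(path)
    df = pd.read_csv(path)
    _check_columns(df, _TRAJ_SCHEMA, path)
    df = _check_numeric(df, ["day"] + list(_PCT), path)
    for col, frac in _PCT.items():
        neg = df.index[df[col] < 0]
        if len(neg):
            rows = ", ".join(str(i + 2) for i in neg[:5])
            raise SchemaError(f"{path}: negative {col} at file rows {rows}")
        df[frac] = df[col] / 100.0
    dup = df.duplicated(subset=["treatment", "replicate", "day"])
    if dup.any():
        rows = ", ".join(str(i + 2) for i in df.index[dup][:5])
        raise SchemaError(f"{path}: duplicated (treatment, replicate, day) "
                          f"keys at file rows {rows}")
    return df.drop(columns=list(_PCT))


def write_trajectory_csv(df: pd.DataFrame, path) -> None:
    """Write a g/g-fraction trajectory frame using the percent schema."""
    out = df.copy()
    for col, frac in _PCT.items():
        out[col] = out[frac] * 100.0
    out[_TRAJ_SCHEMA].to_csv(path, index=False, float_format="%.17g")


def read_gas_csv(path) -> pd.DataFrame:
    """Read a daily headspace table; returns fraction columns o2_drop, co2_rise."""
    path = Path(path)
    df = pd.read_csv(path)
    _check_columns(df, _GAS_SCHEMA, path)
    df = _check_numeric(df, ["day", "o2_pct", "co2_pct", "headspace_L",
                             "temp_K", "substrate_g"], path)
    for c in ("o2_pct", "co2_pct"):
        bad = df.index[(df[c] < 0) | (df[c] > 100)]
        if len(bad):
            rows = ", ".join(str(i + 2) for i in bad[:5])
            raise SchemaError(f"{path}: {c} outside [0, 100] at file rows {rows}")
    df["o2_drop"] = df["o2_pct"] / 100.0
    df["co2_rise"] = df["co2_pct"] / 100.0
    return df.drop(columns=["o2_pct", "co2_pct"])


def write_gas_csv(df: pd.DataFrame, path) -> None:
    out = df.copy()
    out["o2_pct"] = out["o2_drop"] * 100.0
    out["co2_pct"] = out["co2_rise"] * 100.0
    out[_GAS_SCHEMA].to_csv(path, index=False, float_format="%.17g")


def write_fit_report(results: dict, path, metadata_path=None) -> pd.DataFrame:
    """Write the parameter-by-treatment report plus a JSON metadata sidecar.

    ``results`` maps treatment id -> fitted results object.  Concentration
    -like parameters stay on the g/g scale in the CSV (units column says
    so); the JSON sidecar records convergence flags per treatment.
    """
    rows = []
    for name in PARAM_NAMES:
        row = {"parameter": name, "unit": PARAM_UNITS[name]}
        for trt, res in results.items():
            row[trt] = getattr(res.params, name)
        rows.append(row)
    report = pd.DataFrame(rows)
    report.to_csv(path, index=False, float_format="%.6g")
    if metadata_path is not None:
        meta = {
            trt: {
                "converged": bool(res.converged),
                "flags": list(res.flags),
                "stages": {
                    s: {"success": bool(sf.success), "nfev": int(sf.nfev),
                        "sse": float(sf.sse), "message": sf.message}
                    for s, sf in res.stage_fits.items()
                },
            }
            for trt, res in results.items()
        }
        Path(metadata_path).write_text(json.dumps(meta, indent=2))
    return report
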