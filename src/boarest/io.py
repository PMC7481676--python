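"""Readers and writers for the tabular interchange files.

All inputs and outputs are RFC 4180 CSV (UTF-8).  Six tables make up a study:

=================   ==========================================================
detections.csv      camera_id, timestamp (ISO-8601, local time), age_class,
                    staying_time_s (blank when not measured)
deployments.csv     camera_id, start, end (ISO-8601; half-open interval)
landscape_sites.csv site_id + percentage of each of the 6 land-use classes
landscape_cells.csv cell_id + the same 6 percentage columns
harvest.csv         unit_id, month (YYYY-MM), trap_type (box|snare),
                    n_traps, n_trapped
units.csv           cell_id, unit_id, forest_area_km2
=================   ==========================================================

Readers validate row-level invariants and raise with offending row numbers
(1-based, excluding the header).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .landscape import LANDSCAPE_CLASSES
from .management import TRAP_TYPES

__all__ = [
    "TableFormatError",
    "TableValidationError",
    "AGE_CLASSES",
    "read_detections",
    "write_detections",
    "read_deployments",
    "write_deployments",
    "read_harvest",
    "write_harvest",
    "read_landscape",
    "write_landscape",
    "read_units",
    "write_units",
]

AGE_CLASSES = ["adult", "juvenile"]


class TableFormatError(ValueError):
    """Structural problem: missing columns, unreadable file."""


class TableValidationError(ValueError):
    """Row-level invariant violations, reported with row numbers."""


def _require_columns(df: pd.DataFrame, cols: list[str], path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise TableFormatError(f"{path}: missing required columns {missing}")


def _rows(mask: pd.Series) -> list[int]:
    return (np.flatnonzero(mask.to_numpy()) + 1).tolist()


def _fail_rows(mask: pd.Series, path, message: str) -> None:
    if mask.any():
        rows = _rows(mask)
        shown = rows[:20]
        more = "" if len(rows) <= 20 else f" (+{len(rows) - 20} more)"
        raise TableValidationError(
            f"{path}: {message} in {len(rows)} row(s): {shown}{more}"
        )


def read_detections(path: str | Path) -> pd.DataFrame:
    """Read and validate the camera detection table."""
    df = pd.read_csv(path)
    _require_columns(df, ["camera_id", "timestamp", "age_class", "staying_time_s"], path)
    ts = pd.to_datetime(df["timestamp"], errors="coerce", format="ISO8601")
    _fail_rows(ts.isna(), path, "unparseable ISO-8601 timestamp")
    df["timestamp"] = ts
    _fail_rows(~df["age_class"].isin(AGE_CLASSES), path,
               f"age_class not in {AGE_CLASSES}")
    stay = pd.to_numeric(df["staying_time_s"], errors="coerce")
    bad_stay = df["staying_time_s"].notna() & stay.isna()
    _fail_rows(bad_stay, path, "non-numeric staying_time_s")
    _fail_rows(stay.notna() & (stay <= 0), path, "staying_time_s must be > 0")
    df["staying_time_s"] = stay
    return df


def write_detections(df: pd.DataFrame, path: str | Path) -> None:
    out = df.copy()
    out["timestamp"] = pd.to_datetime(out["timestamp"]).dt.strftime("%Y-%m-%dT%H:%M:%S")
    out.to_csv(path, index=False)


def read_deployments(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, ["camera_id", "start", "end"], path)
    for col in ("start", "end"):
        parsed = pd.to_datetime(df[col], errors="coerce", format="ISO8601")
        _fail_rows(parsed.isna(), path, f"unparseable {col} timestamp")
        df[col] = parsed
    _fail_rows(df["end"] <= df["start"], path, "deployment end must be after start")
    return df


def write_deployments(df: pd.DataFrame, path: str | Path) -> None:
    out = df.copy()
    for col in ("start", "end"):
        out[col] = pd.to_datetime(out[col]).dt.strftime("%Y-%m-%dT%H:%M:%S")
    out.to_csv(path, index=False)


def read_harvest(path: str | Path) -> pd.DataFrame:
    """Read and validate the monthly harvest (trapping) table."""
    df = pd.read_csv(path)
    _require_columns(df, ["unit_id", "month", "trap_type", "n_traps", "n_trapped"], path)
    _fail_rows(
        ~df["trap_type"].isin(TRAP_TYPES), path,
        f"trap_type must be one of {TRAP_TYPES}",
    )
    for col in ("n_traps", "n_trapped"):
        vals = pd.to_numeric(df[col], errors="coerce")
        _fail_rows(vals.isna() | (vals < 0) | (vals != vals.round()), path,
                   f"{col} must be a non-negative integer")
        df[col] = vals.astype(int)
    _fail_rows((df["n_traps"] == 0) & (df["n_trapped"] > 0), path,
               "n_trapped must be 0 where n_traps is 0")
    return df


def write_harvest(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)


def read_landscape(path: str | Path, id_col: str) -> pd.DataFrame:
    """Read a landscape composition table keyed by ``id_col``."""
    df = pd.read_csv(path)
    _require_columns(df, [id_col] + LANDSCAPE_CLASSES, path)
    for col in LANDSCAPE_CLASSES:
        vals = pd.to_numeric(df[col], errors="coerce")
        _fail_rows(vals.isna() | (vals < 0) | (vals > 100), path,
                   f"{col} must be a percentage in [0, 100]")
        df[col] = vals
    total = df[LANDSCAPE_CLASSES].sum(axis=1)
    _fail_rows(total > 100.0 + 1e-6, path, "class percentages must sum to <= 100")
    _fail_rows(df[id_col].duplicated(), path, f"duplicate {id_col}")
    return df


def write_landscape(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)


def read_units(path: str | Path) -> pd.DataFrame:
    """Read the cell -> management-unit map with forested areas."""
    df = pd.read_csv(path)
    _require_columns(df, ["cell_id", "unit_id", "forest_area_km2"], path)
    area = pd.to_numeric(df["forest_area_km2"], errors="coerce")
    _fail_rows(area.isna() | (area < 0), path, "forest_area_km2 must be >= 0")
    df["forest_area_km2"] = area
    _fail_rows(df["cell_id"].duplicated(), path,
               "each cell must map to exactly one unit")
    return df


def write_units(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)
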