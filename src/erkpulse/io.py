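"""Trajectory table I/O (wide and long CSV dialects).

Wide: a ``time_min`` column followed by one column per cell.
Long: columns ``time_min, cell_id, erk`` (+ optional ``condition``).
Values are written at six significant digits; round trips are lossless to
that precision.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["write_trajectories", "read_trajectories", "wide_to_long", "long_to_wide"]

_FLOAT_FMT = "%.8g"


class TrajectoryIOError(ValueError):
    """Structured error for malformed trajectory tables."""


def _validate_wide(df: pd.DataFrame) -> pd.DataFrame:
    if "time_min" in df.columns:
        df = df.set_index("time_min")
    if df.index.name != "time_min":
        raise TrajectoryIOError("missing 'time_min' column")
    t = df.index.to_numpy(dtype=float)
    if np.any(np.diff(t) <= 0):
        raise TrajectoryIOError("non-monotone time axis")
    if df.columns.duplicated().any():
        dup = df.columns[df.columns.duplicated()][0]
        raise TrajectoryIOError(f"duplicated cell id {dup!r}")
    for col in df.columns:
        if df[col].isna().any():
            raise TrajectoryIOError(f"cell {col!r} has missing samples (gap)")
    return df


def write_trajectories(df: pd.DataFrame, path, dialect: str = "wide") -> None:
    """Write a wide table (index time_min, one column per cell) to CSV."""
    df = _validate_wide(df.copy())
    if dialect == "wide":
        df.to_csv(path, float_format=_FLOAT_FMT)
    elif dialect == "long":
        wide_to_long(df).to_csv(path, index=False, float_format=_FLOAT_FMT)
    else:
        raise TrajectoryIOError(f"unknown dialect {dialect!r}")


def read_trajectories(path, dialect: str = "wide") -> pd.DataFrame:
    """Read a trajectory CSV into a validated wide table."""
    if dialect == "wide":
        df = pd.read_csv(path)
        return _validate_wide(df)
    if dialect == "long":
        df = pd.read_csv(path)
        need = {"time_min", "cell_id", "erk"}
        if not need.issubset(df.columns):
            raise TrajectoryIOError(f"long table must have columns {sorted(need)}")
        return _validate_wide(long_to_wide(df))
    raise TrajectoryIOError(f"unknown dialect {dialect!r}")


def wide_to_long(df: pd.DataFrame, condition: str | None = None) -> pd.DataFrame:
    df = _validate_wide(df.copy())
    out = df.reset_index().melt(id_vars="time_min", var_name="cell_id",
                                value_name="erk")
    if condition is not None:
        out["condition"] = condition
    return out.sort_values(["cell_id", "time_min"], kind="stable").reset_index(drop=True)


def long_to_wide(df: pd.DataFrame) -> pd.DataFrame:
    piv = df.pivot(index="time_min", columns="cell_id", values="erk")
    piv.columns.name = None
    # preserve first-appearance cell order
    order = list(dict.fromkeys(df["cell_id"]))
    return piv[order]
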