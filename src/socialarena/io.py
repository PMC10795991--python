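"""Reading, writing and validating trajectory tables.

A trajectory table is a comma-delimited UTF-8 text file with the exact
header ``frame,id,x,y,theta,a,b`` and one row per (frame, individual):
0-based frame index, individual label, arena-centered position in mm,
heading in rad (wrapped to (-pi, pi]) and body-ellipse semi-axes in mm.
In memory it is a plain pandas DataFrame with those columns.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .geometry import wrap_angle

__all__ = ["TrajectoryFormatError", "COLUMNS", "read_trajectories",
           "write_trajectories", "validate_trajectories"]

COLUMNS = ["frame", "id", "x", "y", "theta", "a", "b"]
_NUMERIC = ["frame", "x", "y", "theta", "a", "b"]


class TrajectoryFormatError(ValueError):
    """Raised when a trajectory file or table violates the format contract."""


def validate_trajectories(table: pd.DataFrame) -> pd.DataFrame:
    """Validate a trajectory table; returns it with theta wrapped to (-pi, pi].

    Checks: required columns, finite numeric values, unique (frame, id),
    contiguous frame range per individual, and a >= b > 0.
    """
    missing = [c for c in COLUMNS if c not in table.columns]
    if missing:
        raise TrajectoryFormatError(f"missing columns: {missing}")
    table = table[COLUMNS].copy()
    for col in _NUMERIC:
        vals = pd.to_numeric(table[col], errors="coerce")
        bad = vals.index[~np.isfinite(vals)]
        if len(bad):
            lines = [int(i) + 2 for i in bad[:5]]  # +2: header + 1-based
            raise TrajectoryFormatError(
                f"non-numeric or non-finite values in column {col!r} "
                f"(file lines {lines}{'...' if len(bad) > 5 else ''})")
        table[col] = vals
    table["frame"] = table["frame"].astype(np.int64)

    dup = table.duplicated(subset=["frame", "id"])
    if dup.any():
        lines = [int(i) + 2 for i in table.index[dup][:5]]
        raise TrajectoryFormatError(
            f"duplicated (frame, id) rows at file lines {lines}")

    for ind, sub in table.groupby("id", sort=False):
        frames = np.sort(sub["frame"].to_numpy())
        if not np.array_equal(frames, np.arange(frames[0], frames[-1] + 1)):
            raise TrajectoryFormatError(
                f"frames of individual {ind!r} are not a contiguous range")

    if not ((table["a"] >= table["b"]) & (table["b"] > 0)).all():
        raise TrajectoryFormatError("body semi-axes must satisfy a >= b > 0")

    table["theta"] = wrap_angle(table["theta"].to_numpy())
    return table.sort_values(["frame", "id"], kind="stable").reset_index(drop=True)


def read_trajectories(path) -> pd.DataFrame:
    """Read and validate a trajectory table from a delimited text file."""
    try:
        table = pd.read_csv(path)
    except Exception as exc:  # malformed CSV structure
        raise TrajectoryFormatError(f"cannot parse {path}: {exc}") from exc
    return validate_trajectories(table)


def write_trajectories(table: pd.DataFrame, path) -> None:
    """Write a trajectory table; round-trips through read_trajectories to 1e-9."""
    table = table[COLUMNS]
    table.to_csv(path, index=False, float_format="%.12g")
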