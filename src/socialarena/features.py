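"""Per-frame kinetic and pairwise geometric features of a trajectory table.

These are the quantities the interaction definition and the behavioral
signatures consume: per-individual speed and angular speed, number of
close neighbors, and the directed pair features — nose-to-ellipse
distance, the visual angle the other animal subtends, and the absolute
differences in bearing, orientation and displacement direction.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .geometry import (TWO_PI, angle_subtended, nose_position,
                       point_to_ellipse_distance, wrap_angle)

__all__ = ["SPEED_FLOOR", "trajectory_arrays", "pair_frame_features",
           "frame_features", "close_counts", "pair_distance_condition"]

#: minimum speed (mm/s) at which a displacement direction is defined
SPEED_FLOOR = 0.1


def trajectory_arrays(table: pd.DataFrame):
    """Pivot a trajectory table to per-frame arrays.

    Returns (ids, X, Y, TH, A, B) where arrays have shape (n_frames, n_ids)
    with ids in sorted order.  Requires every id on every frame.
    """
    piv = table.pivot(index="frame", columns="id")
    if piv["x"].isna().any().any():
        raise ValueError("every individual must be present on every frame")
    ids = piv["x"].columns.to_numpy()
    return (ids, piv["x"].to_numpy(), piv["y"].to_numpy(),
            piv["theta"].to_numpy(), piv["a"].to_numpy(), piv["b"].to_numpy())


def _displacement_direction(X, Y, fps):
    """Per-frame displacement direction phi and speed, assigned to the
    earlier frame; the last frame is NaN."""
    F = X.shape[0]
    speed = np.full(X.shape, np.nan)
    phi = np.full(X.shape, np.nan)
    if F >= 2:
        dx = np.diff(X, axis=0)
        dy = np.diff(Y, axis=0)
        speed[:-1] = np.hypot(dx, dy) * fps
        phi[:-1] = np.arctan2(dy, dx)
        phi[:-1][speed[:-1] < SPEED_FLOOR] = np.nan
    return speed, phi


def pair_frame_features(table: pd.DataFrame, fov: float = TWO_PI,
                        fps: float = 30.0) -> pd.DataFrame:
    """Directed geometric features for every ordered pair (i, j), i != j.

    Columns: frame, i, j, dnose2ell, anglesub, absanglefrom1to2,
    absthetadiff, absphidiff.  absphidiff is NaN whenever either
    individual's speed is below SPEED_FLOOR (displacement direction
    undefined) or on the last frame.
    """
    if not 0 < fov <= TWO_PI:
        raise ValueError("fov must be in (0, 2*pi]")
    ids, X, Y, TH, A, B = trajectory_arrays(table)
    F, N = X.shape
    speed, phi = _displacement_direction(X, Y, fps)

    rows = []
    frames = np.arange(F)
    for ii in range(N):
        nx, ny = nose_position(X[:, ii], Y[:, ii], TH[:, ii], A[:, ii])
        for jj in range(N):
            if ii == jj:
                continue
            d = point_to_ellipse_distance(nx, ny, X[:, jj], Y[:, jj],
                                          TH[:, jj], A[:, jj], B[:, jj])
            asub = angle_subtended(X[:, ii], Y[:, ii], TH[:, ii], A[:, ii],
                                   X[:, jj], Y[:, jj], TH[:, jj],
                                   A[:, jj], B[:, jj], fov)
            bearing = np.arctan2(Y[:, jj] - Y[:, ii], X[:, jj] - X[:, ii])
            absang = np.abs(wrap_angle(bearing - TH[:, ii]))
            absth = np.abs(wrap_angle(TH[:, ii] - TH[:, jj]))
            absphi = np.abs(wrap_angle(phi[:, ii] - phi[:, jj]))
            rows.append(pd.DataFrame({
                "frame": frames, "i": ids[ii], "j": ids[jj],
                "dnose2ell": d, "anglesub": asub,
                "absanglefrom1to2": absang, "absthetadiff": absth,
                "absphidiff": absphi,
            }))
    out = pd.concat(rows, ignore_index=True)
    return out.sort_values(["frame", "i", "j"], kind="stable",
                           ignore_index=True)


def pair_distance_condition(X, Y, TH, A, B, dist_max: float) -> np.ndarray:
    """Boolean array (F, N, N): nose of i within ``dist_max`` of j's ellipse.

    Exact distances are only computed where they can matter: j's ellipse
    contains the disk of radius b and is contained in the disk of radius a
    (both about j's center), so the nose-to-center distance brackets the
    nose-to-ellipse distance within [nc - a, nc - b]; only pairs falling in
    that ambiguous annulus need the exact computation.
    """
    F, N = X.shape
    nx, ny = nose_position(X, Y, TH, A)
    dx = nx[:, :, None] - X[:, None, :]
    dy = ny[:, :, None] - Y[:, None, :]
    nc = np.hypot(dx, dy)
    ub = nc - B[:, None, :]
    lb = nc - A[:, None, :]
    cond = ub <= dist_max
    ambiguous = (~cond) & (lb <= dist_max)
    eye = np.eye(N, dtype=bool)
    cond &= ~eye
    ambiguous &= ~eye
    if ambiguous.any():
        f, i, j = np.nonzero(ambiguous)
        d = point_to_ellipse_distance(nx[f, i], ny[f, i], X[f, j], Y[f, j],
                                      TH[f, j], A[f, j], B[f, j])
        cond[f, i, j] = d <= dist_max
    return cond


def close_counts(table_or_arrays, close_dist: float = 8.0) -> np.ndarray:
    """Number of other individuals whose body ellipse is within
    ``close_dist`` of the focal individual's nose; shape (F, N)."""
    if isinstance(table_or_arrays, pd.DataFrame):
        _, X, Y, TH, A, B = trajectory_arrays(table_or_arrays)
    else:
        _, X, Y, TH, A, B = table_or_arrays
    return pair_distance_condition(X, Y, TH, A, B, close_dist).sum(axis=2)


def frame_features(table: pd.DataFrame, close_dist: float = 8.0,
                   fps: float = 30.0) -> pd.DataFrame:
    """Per-individual per-frame speed (mm/s), angular speed (rad/s) and
    number of close neighbors.  Displacement-based features are assigned
    to the earlier frame; the last frame carries NaN."""
    arrays = trajectory_arrays(table)
    ids, X, Y, TH, _, _ = arrays
    F, N = X.shape
    speed = np.full(X.shape, np.nan)
    angspeed = np.full(X.shape, np.nan)
    if F >= 2:
        speed[:-1] = np.hypot(np.diff(X, axis=0), np.diff(Y, axis=0)) * fps
        angspeed[:-1] = np.abs(wrap_angle(np.diff(TH, axis=0))) * fps
    nclose = close_counts(arrays, close_dist)
    return pd.DataFrame({
        "frame": np.repeat(np.arange(F), N),
        "id": np.tile(ids, F),
        "speed": speed.ravel(),
        "angular_speed": angspeed.ravel(),
        "nflies_close": nclose.ravel(),
    })
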