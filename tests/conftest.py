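"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest


def brute_force_bouts(mask, min_frames, gap_frames):
    """Independent run-merging enumerator: scan the series frame by frame,
    collect maximal True runs, merge neighbors separated by < gap_frames
    False frames, keep groups with total True count >= min_frames.
    Returns a list of (start, end, frames_true)."""
    runs = []
    s = None
    for t, v in enumerate(list(mask) + [False]):
        if v and s is None:
            s = t
        elif not v and s is not None:
            runs.append((s, t - 1))
            s = None
    groups = []
    for run in runs:
        if groups and run[0] - groups[-1][-1][1] - 1 < gap_frames:
            groups[-1].append(run)
        else:
            groups.append([run])
    out = []
    for g in groups:
        total = sum(e - s + 1 for s, e in g)
        if total >= min_frames:
            out.append((g[0][0], g[-1][1], total))
    return out


def ray_casting_anglesub(xi, yi, thi, ai, xj, yj, thj, aj, bj, fov,
                         n_rays=4096):
    """Ray-casting oracle for the occluded visual angle: cast n_rays rays
    over the field of view from the focal nose and count hits on the
    other ellipse."""
    nx, ny = xi + ai * np.cos(thi), yi + ai * np.sin(thi)
    ct, st = np.cos(thj), np.sin(thj)
    qx = (ct * (nx - xj) + st * (ny - yj)) / aj
    qy = (-st * (nx - xj) + ct * (ny - yj)) / bj
    if qx * qx + qy * qy <= 1.0:
        return fov
    deltas = thi - fov / 2 + (np.arange(n_rays) + 0.5) * fov / n_rays
    wx = (ct * np.cos(deltas) + st * np.sin(deltas)) / aj
    wy = (-st * np.cos(deltas) + ct * np.sin(deltas)) / bj
    A = wx * wx + wy * wy
    B = 2 * (qx * wx + qy * wy)
    C = qx * qx + qy * qy - 1.0
    disc = B * B - 4 * A * C
    hit = disc >= 0
    r_far = (-B + np.sqrt(np.clip(disc, 0, None))) / (2 * A)
    hit &= r_far >= 0  # ellipse ahead of the nose, not behind
    return hit.sum() * fov / n_rays


def sampled_ellipse_distance(px, py, cx, cy, th, a, b, n=100_000):
    """Dense boundary-sampling oracle for point-to-ellipse distance."""
    u = np.cos(th) * (px - cx) + np.sin(th) * (py - cy)
    v = -np.sin(th) * (px - cx) + np.cos(th) * (py - cy)
    if (u / a) ** 2 + (v / b) ** 2 <= 1.0:
        return 0.0
    t = np.linspace(0, 2 * np.pi, n, endpoint=False)
    bx = cx + np.cos(th) * a * np.cos(t) - np.sin(th) * b * np.sin(t)
    by = cy + np.sin(th) * a * np.cos(t) + np.cos(th) * b * np.sin(t)
    return float(np.hypot(px - bx, py - by).min())


def make_trajectory(positions, thetas=None, a=1.2, b=0.6):
    """Trajectory table from an (n_frames, n_ids, 2) position array."""
    pos = np.asarray(positions, dtype=float)
    nf, n, _ = pos.shape
    if thetas is None:
        thetas = np.zeros((nf, n))
    thetas = np.broadcast_to(np.asarray(thetas, dtype=float), (nf, n))
    return pd.DataFrame({
        "frame": np.repeat(np.arange(nf), n),
        "id": np.tile(np.arange(n), nf),
        "x": pos[:, :, 0].ravel(), "y": pos[:, :, 1].ravel(),
        "theta": thetas.ravel(), "a": a, "b": b,
    })


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


@pytest.fixture
def random_walk_table(rng):
    """Small random-walk trajectory table (4 animals, 60 frames)."""
    nf, n = 60, 4
    pos = np.cumsum(rng.normal(0, 0.8, (nf, n, 2)), axis=0) + \
        rng.uniform(-8, 8, (1, n, 2))
    th = rng.uniform(-np.pi, np.pi, (nf, n))
    return make_trajectory(pos, th)
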