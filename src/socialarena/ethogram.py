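"""Rule-based behavior proxies and bout-level summaries.

The trained behavior classifiers used with multi-animal tracking rigs
are not reproducible from thresholds alone; this module provides simple,
declared rule-based proxies for locomotion (walk / stop / turn), chase
and sleep, plus bout statistics (fraction of time, counts, durations,
inter-bout intervals).  All thresholds live in EthogramThresholds and
carry no claim of equivalence with learned classifiers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .bouts import Bout, detect_bouts, true_runs
from .features import trajectory_arrays

__all__ = ["EthogramThresholds", "classify_locomotion", "detect_chase",
           "detect_sleep", "bout_metrics"]


@dataclass(frozen=True)
class EthogramThresholds:
    """Proxy thresholds.  Speeds mm/s, angles rad, angular speed rad/s.

    sleep_min_s defaults to 300 s (5 min of consolidated inactivity);
    move_eps gives "no movement" a numeric floor for continuous positions.
    """
    walk_speed_min: float = 2.0
    stop_speed_max: float = 1.0
    turn_angspeed_min: float = np.pi
    chase_dist_max: float = 6.0
    chase_align_max: float = np.pi / 4
    chase_min_frames: int = 15
    chase_gap_frames: int = 15
    sleep_min_s: float = 300.0
    move_eps: float = 0.1

    def __post_init__(self):
        if self.stop_speed_max > self.walk_speed_min:
            raise ValueError("stop_speed_max must be <= walk_speed_min")
        for name in ("walk_speed_min", "turn_angspeed_min", "chase_dist_max",
                     "chase_align_max", "sleep_min_s", "move_eps"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def classify_locomotion(frame_features: pd.DataFrame,
                        thresholds: EthogramThresholds | None = None
                        ) -> pd.Series:
    """Per-frame locomotion label with precedence stop > turn > walk.

    stop: speed <= stop_speed_max; turn: angular_speed >= turn_angspeed_min
    and not stop; walk: speed >= walk_speed_min and not turn/stop.  Frames
    matching none of the rules (or with undefined speed) are 'none'.
    """
    thr = thresholds or EthogramThresholds()
    speed = frame_features["speed"].to_numpy()
    ang = frame_features["angular_speed"].to_numpy()
    labels = np.full(len(speed), "none", dtype=object)
    walk = speed >= thr.walk_speed_min
    turn = ang >= thr.turn_angspeed_min
    stop = speed <= thr.stop_speed_max
    labels[walk] = "walk"
    labels[turn & ~stop] = "turn"
    labels[stop] = "stop"
    return pd.Series(labels, index=frame_features.index, name="locomotion")


def detect_chase(pair_features: pd.DataFrame, frame_features: pd.DataFrame,
                 thresholds: EthogramThresholds | None = None
                 ) -> dict[tuple, list[Bout]]:
    """Chase bouts per ordered pair (chaser, chased).

    i chases j on a frame when i's nose is within chase_dist_max of j's
    body, j lies within chase_align_max of i's heading, and both move at
    walking speed.  Bouts via run detection with chase_min_frames /
    chase_gap_frames.
    """
    thr = thresholds or EthogramThresholds()
    speed = frame_features.set_index(["frame", "id"])["speed"]
    f = pair_features
    n_frames = int(f["frame"].max()) + 1 if len(f) else 0
    si = speed.reindex(pd.MultiIndex.from_arrays([f["frame"], f["i"]])).to_numpy()
    sj = speed.reindex(pd.MultiIndex.from_arrays([f["frame"], f["j"]])).to_numpy()
    cond = ((f["dnose2ell"].to_numpy() <= thr.chase_dist_max)
            & (f["absanglefrom1to2"].to_numpy() <= thr.chase_align_max)
            & (si >= thr.walk_speed_min) & (sj >= thr.walk_speed_min))
    bouts: dict[tuple, list[Bout]] = {}
    for (i, j), sub in f.groupby(["i", "j"], sort=True):
        arr = np.zeros(n_frames, dtype=bool)
        arr[sub["frame"].to_numpy()] = cond[sub.index.to_numpy()]
        bouts[(i, j)] = detect_bouts(arr, min_frames=thr.chase_min_frames,
                                     gap_frames=thr.chase_gap_frames)
    return bouts


def detect_sleep(table: pd.DataFrame, fps: float,
                 thresholds: EthogramThresholds | None = None
                 ) -> dict[object, list[Bout]]:
    """Sleep bouts per individual: maximal stationary intervals (every
    between-frame displacement <= move_eps) spanning at least
    sleep_min_s * fps frames, with no gap bridging.

    A stationary interval covering frames [s, e] (e - s + 1 frames) is
    delimited by the run of sub-threshold displacements s..e-1.
    """
    thr = thresholds or EthogramThresholds()
    min_frames = int(round(thr.sleep_min_s * fps))
    ids, X, Y, _, _, _ = trajectory_arrays(table)
    disp = np.hypot(np.diff(X, axis=0), np.diff(Y, axis=0))
    out: dict[object, list[Bout]] = {}
    for k, ind in enumerate(ids):
        inactive = disp[:, k] <= thr.move_eps if disp.size else np.zeros(0, bool)
        starts, ends = true_runs(inactive)
        bouts = []
        for s, e in zip(starts, ends):
            n = int(e - s + 2)  # stationary frames [s, e+1]
            if n >= min_frames:
                bouts.append(Bout(int(s), int(e + 1), n))
        out[ind] = bouts
    return out


def bout_metrics(bouts: list[Bout], n_frames: int, fps: float) -> dict:
    """Summary of one bout series: fraction of time, bout count, mean bout
    duration (s) and mean inter-bout interval (s; NaN if < 2 bouts)."""
    if n_frames < 1 or fps <= 0:
        raise ValueError("n_frames must be >= 1 and fps > 0")
    if not bouts:
        return {"fraction": 0.0, "count": 0, "mean_duration_s": 0.0,
                "mean_ibi_s": float("nan")}
    durations = np.array([b.n_frames for b in bouts], dtype=float)
    starts = np.array([b.start for b in bouts])
    ends = np.array([b.end for b in bouts])
    ibis = starts[1:] - ends[:-1] - 1
    return {
        "fraction": float(durations.sum() / n_frames),
        "count": len(bouts),
        "mean_duration_s": float(durations.mean() / fps),
        "mean_ibi_s": float(ibis.mean() / fps) if len(ibis) else float("nan"),
    }
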