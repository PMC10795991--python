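"""Run detection on boolean frame series: maximal runs, gap bridging,
minimum-duration filtering.  Shared by interaction-event detection and
the ethogram bout machinery."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["Bout", "true_runs", "detect_bouts"]


@dataclass(frozen=True)
class Bout:
    """Closed frame interval [start, end]; frames_true counts the frames on
    which the underlying condition held (gap frames bridged into the bout
    do not count)."""
    start: int
    end: int
    frames_true: int

    @property
    def n_frames(self) -> int:
        return self.end - self.start + 1


def true_runs(mask) -> tuple[np.ndarray, np.ndarray]:
    """Starts and (inclusive) ends of maximal True runs of a boolean series."""
    m = np.asarray(mask, dtype=bool)
    if m.size == 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    d = np.diff(m.astype(np.int8))
    starts = np.flatnonzero(d == 1) + 1
    ends = np.flatnonzero(d == -1)
    if m[0]:
        starts = np.concatenate(([0], starts))
    if m[-1]:
        ends = np.concatenate((ends, [m.size - 1]))
    return starts.astype(np.int64), ends.astype(np.int64)


def detect_bouts(mask, min_frames: int = 1, gap_frames: int = 1) -> list[Bout]:
    """Merge True runs separated by fewer than ``gap_frames`` False frames
    into candidates; keep candidates whose total True-frame count is at
    least ``min_frames``.  Candidate boundaries are the first and last True
    frames of the merged run group."""
    if min_frames < 1 or gap_frames < 1:
        raise ValueError("min_frames and gap_frames must be >= 1")
    starts, ends = true_runs(mask)
    bouts: list[Bout] = []
    if starts.size == 0:
        return bouts
    cs, ce = int(starts[0]), int(ends[0])
    cn = ce - cs + 1
    for s, e in zip(starts[1:], ends[1:]):
        if s - ce - 1 < gap_frames:
            ce = int(e)
            cn += int(e - s + 1)
        else:
            if cn >= min_frames:
                bouts.append(Bout(cs, ce, cn))
            cs, ce = int(s), int(e)
            cn = ce - cs + 1
    if cn >= min_frames:
        bouts.append(Bout(cs, ce, cn))
    return bouts
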