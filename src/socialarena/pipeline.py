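"""Preset-to-summary convenience composition: simulate one arena from a
cohort preset and reduce it to the per-recording summary row used in
cross-cohort comparisons (network metrics for both weight variants, mean
inter-individual distance, locomotion fractions)."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .ethogram import EthogramThresholds, classify_locomotion
from .features import trajectory_arrays
from .networks import InteractionParams, analyze_arena
from .simulate import ArenaSpec, cohort_preset, simulate_group

__all__ = ["locomotion_fractions", "preset_arena_summary"]


def locomotion_fractions(table: pd.DataFrame, fps: float,
                         thresholds: EthogramThresholds | None = None
                         ) -> dict[str, float]:
    """Fractions of defined frames labeled walk / stop / turn / none."""
    _, X, Y, TH, _, _ = trajectory_arrays(table)
    speed = np.hypot(np.diff(X, axis=0), np.diff(Y, axis=0)) * fps
    angspeed = np.abs(np.diff(TH, axis=0)) * fps
    ff = pd.DataFrame({"speed": speed.ravel(),
                       "angular_speed": angspeed.ravel()})
    labels = classify_locomotion(ff, thresholds)
    frac = labels.value_counts(normalize=True)
    return {f"frac_{k}": float(frac.get(k, 0.0))
            for k in ("walk", "stop", "turn", "none")}


def preset_arena_summary(preset: str, seed: int,
                         arena: ArenaSpec | None = None,
                         params: InteractionParams | None = None
                         ) -> dict[str, float]:
    """Simulate one arena from a cohort preset and summarize it."""
    arena = arena or ArenaSpec()
    table = simulate_group(arena, cohort_preset(preset, seed=seed))
    res = analyze_arena(table, params)
    out = dict(res.summary)
    out.update(locomotion_fractions(table, arena.fps))
    return out
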