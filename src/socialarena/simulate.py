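"""Agent-based generator of group trajectories in a circular arena.

Agents perform a correlated random walk with a social steering term:
per frame each agent draws a speed from a gamma distribution (keeping
speeds nonnegative without clipping), perturbs its heading with Gaussian
noise, and steers toward (attraction) or away from (avoidance) the
centroid of the other agents within its sensing radius.  A step that
would leave the arena instead re-aims the heading at the arena center
before moving, which avoids the oscillation artifacts of specular
reflection at the wall.

Cohort presets emulate three experimental groups of male flies that
differ in locomotor activity and social attraction/avoidance: males
with recent mating experience move least; sexually rejected males move
as much as socially naive ones but avoid their neighbors, which
downstream yields sparser interaction networks and larger
inter-individual distances.

Randomness contract: one integer seed per run; each agent owns an
independent stream derived as ``default_rng([seed, agent_index])``, so
adding agents never reshuffles the trajectories of existing ones.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .geometry import wrap_angle

__all__ = ["ArenaSpec", "AgentParams", "simulate_group", "cohort_preset",
           "load_presets", "PRESET_NAMES"]

PRESET_NAMES = ("mated_like", "naive_like", "rejected_like")


@dataclass(frozen=True)
class ArenaSpec:
    """Circular arena: radius (mm), frame rate (Hz), number of frames."""
    radius: float = 25.0
    fps: float = 30.0
    n_frames: int = 27_000

    def __post_init__(self):
        if not (np.isfinite(self.radius) and self.radius > 0):
            raise ValueError("radius must be finite and > 0")
        if not (np.isfinite(self.fps) and self.fps > 0):
            raise ValueError("fps must be finite and > 0")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")


@dataclass(frozen=True)
class AgentParams:
    """Locomotion and social-steering parameters of one cohort.

    mean_speed/speed_shape parametrize the per-frame gamma speed draw
    (mm/s); turn_sd is the heading-noise SD (rad/frame); social_coeff in
    [-1, 1] scales steering toward (+) or away from (-) the neighborhood
    centroid, saturated at max_turn rad/frame; sensing_radius bounds the
    neighborhood; body_a/body_b are the body-ellipse semi-axes (mm).
    """
    n_agents: int = 10
    mean_speed: float = 5.0
    speed_shape: float = 2.0
    turn_sd: float = 0.25
    social_coeff: float = 0.0
    sensing_radius: float = 16.0
    max_turn: float = 0.5
    body_a: float = 1.2
    body_b: float = 0.6
    seed: int = 0

    def __post_init__(self):
        fields = (self.mean_speed, self.speed_shape, self.turn_sd,
                  self.social_coeff, self.sensing_radius, self.max_turn,
                  self.body_a, self.body_b)
        if not all(math.isfinite(f) for f in fields):
            raise ValueError("agent parameters must be finite")
        if self.n_agents < 1:
            raise ValueError("n_agents must be >= 1")
        if self.mean_speed < 0:
            raise ValueError("mean_speed must be >= 0")
        if self.sensing_radius <= 0:
            raise ValueError("sensing_radius must be > 0")
        if abs(self.social_coeff) > 1:
            raise ValueError("|social_coeff| must be <= 1")
        if not (self.body_a >= self.body_b > 0):
            raise ValueError("body semi-axes must satisfy a >= b > 0")


def simulate_group(arena: ArenaSpec, params: AgentParams) -> pd.DataFrame:
    """Simulate a group of agents; returns a trajectory table.

    One row per (frame, agent) with columns frame,id,x,y,theta,a,b.
    Orientation theta is the heading of the last nonzero displacement.
    Identical (arena, params) including seed give bit-identical output.
    """
    n, nf = params.n_agents, arena.n_frames
    rngs = [np.random.default_rng([params.seed, k]) for k in range(n)]

    pos = np.empty((n, 2))
    heading = np.empty(n)
    speeds = np.empty((n, nf))
    noise = np.empty((n, nf))
    for k, rng in enumerate(rngs):
        ang = rng.uniform(0.0, 2.0 * np.pi)
        rad = arena.radius * np.sqrt(rng.uniform())
        pos[k] = rad * np.cos(ang), rad * np.sin(ang)
        heading[k] = rng.uniform(-np.pi, np.pi)
        if params.mean_speed > 0:
            speeds[k] = rng.gamma(params.speed_shape,
                                  params.mean_speed / params.speed_shape, nf)
        else:
            speeds[k] = 0.0
        noise[k] = rng.normal(0.0, params.turn_sd, nf)

    theta = heading.copy()
    xs = np.empty((nf, n))
    ys = np.empty((nf, n))
    ths = np.empty((nf, n))
    s, r2 = params.social_coeff, params.sensing_radius ** 2

    for t in range(nf):
        xs[t], ys[t], ths[t] = pos[:, 0], pos[:, 1], theta
        if t == nf - 1:
            break
        turn = noise[:, t].copy()
        if n > 1 and s != 0.0:
            diff = pos[None, :, :] - pos[:, None, :]
            d2 = np.einsum("ijk,ijk->ij", diff, diff)
            near = (d2 <= r2)
            np.fill_diagonal(near, False)
            cnt = near.sum(axis=1)
            has = cnt > 0
            if has.any():
                cx = (near @ pos[:, 0]) / np.maximum(cnt, 1)
                cy = (near @ pos[:, 1]) / np.maximum(cnt, 1)
                dev = wrap_angle(np.arctan2(cy - pos[:, 1], cx - pos[:, 0])
                                 - heading)
                turn += np.where(
                    has, s * np.clip(dev, -params.max_turn, params.max_turn),
                    0.0)
        heading = wrap_angle(heading + turn)
        step = speeds[:, t] / arena.fps
        nxt = pos + step[:, None] * np.column_stack(
            (np.cos(heading), np.sin(heading)))
        out = np.hypot(nxt[:, 0], nxt[:, 1]) > arena.radius
        if out.any():
            heading = np.where(
                out, np.arctan2(-pos[:, 1], -pos[:, 0]), heading)
            nxt = pos + step[:, None] * np.column_stack(
                (np.cos(heading), np.sin(heading)))
            nrm = np.hypot(nxt[:, 0], nxt[:, 1])
            over = nrm > arena.radius
            if over.any():  # overshot past the center to the far wall
                scale = np.where(over, arena.radius / np.maximum(nrm, 1e-300),
                                 1.0)
                nxt *= scale[:, None]
        moved = step > 0
        theta = np.where(moved, heading, theta)
        pos = nxt

    frames = np.repeat(np.arange(nf), n)
    ids = np.tile(np.arange(n), nf)
    return pd.DataFrame({
        "frame": frames, "id": ids,
        "x": xs.ravel(), "y": ys.ravel(), "theta": wrap_angle(ths.ravel()),
        "a": params.body_a, "b": params.body_b,
    })


def _parse_presets(text: str) -> dict[str, dict[str, float]]:
    presets: dict[str, dict[str, float]] = {}
    for raw in text.splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        key, _, value = line.partition("=")
        name, _, field = key.strip().partition(".")
        presets.setdefault(name, {})[field] = float(value)
    return presets


def load_presets() -> dict[str, dict[str, float]]:
    """Read the packaged preset table (presets are data, not code)."""
    text = resources.files(__package__).joinpath("presets.cfg").read_text()
    return _parse_presets(text)


def cohort_preset(name: str, seed: int = 0) -> AgentParams:
    """Parameters for one of the cohort presets.

    ``mated_like`` moves least; ``naive_like`` and ``rejected_like``
    share a higher speed; only ``rejected_like`` has social_coeff < 0.
    """
    presets = load_presets()
    if name not in presets:
        raise ValueError(
            f"unknown preset {name!r}; valid presets: {sorted(presets)}")
    fields = dict(presets[name])
    fields["n_agents"] = int(fields["n_agents"])
    return AgentParams(seed=seed, **fields)
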