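"""Pairwise interaction events and the weighted social networks built
from them.

An interaction frame for the ordered pair (i, j) requires that i can see
j (the angle j subtends in i's field of view is > 0) and that i's nose
is within ``dist_max`` of any point of j's body ellipse.  The pair-level
condition is the union of the two directions.  True runs separated by
fewer than ``gap_frames`` condition-false frames are bridged into one
candidate event, which qualifies if it accumulates at least
``min_frames`` condition-true frames.

Two symmetric weight matrices summarize a recording: duration weights
(frames interacting / total frames, emphasizing long-lasting contacts)
and count weights (number of separate events / maximum possible number
of events, emphasizing short repeated contacts).  Network metrics are
density, per-vertex strength, walktrap community modularity and
weighted betweenness centrality, with their across-vertex SDs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import igraph as ig
import networkx as nx
import numpy as np
import pandas as pd

from .bouts import Bout, detect_bouts
from .features import pair_distance_condition, trajectory_arrays
from .geometry import TWO_PI, angle_subtended

__all__ = [
    "InteractionParams", "SocialNetwork", "ArenaAnalysis",
    "pair_condition", "interaction_conditions", "detect_events",
    "max_possible_interactions", "build_weight_matrices",
    "network_density", "node_strength", "sd_strength",
    "walktrap_modularity", "weighted_betweenness", "network_metrics",
    "analyze_arena",
]


@dataclass(frozen=True)
class InteractionParams:
    """Thresholds of the interaction definition: nose-to-ellipse distance
    cutoff (mm), minimum interaction frames, minimum gap frames (4 s at
    30 fps), and the visual field of view (rad)."""
    dist_max: float = 8.0
    min_frames: int = 60
    gap_frames: int = 120
    fov: float = TWO_PI
    symmetrize: str = "or"  # "or": either direction counts; "and": both

    def __post_init__(self):
        if self.dist_max <= 0:
            raise ValueError("dist_max must be > 0")
        if self.min_frames < 1 or self.gap_frames < 1:
            raise ValueError("min_frames and gap_frames must be >= 1")
        if not 0 < self.fov <= TWO_PI:
            raise ValueError("fov must be in (0, 2*pi]")
        if self.symmetrize not in ("or", "and"):
            raise ValueError("symmetrize must be 'or' or 'and'")


def pair_condition(features: pd.DataFrame,
                   params: InteractionParams) -> dict[tuple, np.ndarray]:
    """Per-frame boolean interaction condition per unordered pair, from a
    directed pair-feature table (columns frame, i, j, dnose2ell, anglesub).

    The directed condition is anglesub > 0 AND dnose2ell <= dist_max
    (inclusive); directions are combined by union (default) or
    intersection.
    """
    f = features
    cond_dir = (f["anglesub"].to_numpy() > 0) & \
               (f["dnose2ell"].to_numpy() <= params.dist_max)
    frames = f["frame"].to_numpy()
    n_frames = int(frames.max()) + 1 if len(f) else 0
    series: dict[tuple, np.ndarray] = {}
    for (i, j), sub in f.groupby(["i", "j"], sort=True):
        try:
            key = (i, j) if i <= j else (j, i)
        except TypeError:
            key = tuple(sorted((i, j), key=str))
        arr = np.zeros(n_frames, dtype=bool)
        arr[sub["frame"].to_numpy()] = cond_dir[sub.index.to_numpy()]
        if key in series:
            if params.symmetrize == "or":
                series[key] |= arr
            else:
                series[key] &= arr
        else:
            series[key] = arr
    return series


def interaction_conditions(table: pd.DataFrame,
                           params: InteractionParams) -> dict[tuple, np.ndarray]:
    """Pair-level interaction condition computed directly from a trajectory
    table (fast path; equals running pair_condition on pair_frame_features).
    """
    ids, X, Y, TH, A, B = trajectory_arrays(table)
    dist_ok = pair_distance_condition(X, Y, TH, A, B, params.dist_max)
    if params.fov >= TWO_PI - 1e-12:
        # a full-surround field of view always sees any other body
        cond_dir = dist_ok
    else:
        cond_dir = np.zeros_like(dist_ok)
        f, i, j = np.nonzero(dist_ok)
        if f.size:
            asub = angle_subtended(X[f, i], Y[f, i], TH[f, i], A[f, i],
                                   X[f, j], Y[f, j], TH[f, j], A[f, j],
                                   B[f, j], params.fov)
            cond_dir[f, i, j] = asub > 0
    both = cond_dir | cond_dir.transpose(0, 2, 1) if params.symmetrize == "or" \
        else cond_dir & cond_dir.transpose(0, 2, 1)
    return {(ids[ii], ids[jj]): both[:, ii, jj]
            for ii, jj in combinations(range(len(ids)), 2)}


def detect_events(cond, params: InteractionParams) -> list[Bout]:
    """Interaction events of one pair from its per-frame condition series."""
    return detect_bouts(cond, min_frames=params.min_frames,
                        gap_frames=params.gap_frames)


def max_possible_interactions(n_frames: int, min_frames: int,
                              gap_frames: int) -> float:
    """Maximum number of separate interaction events that fit in a
    recording: ((n_frames - min_frames) / (min_frames + gap_frames)) + 1,
    evaluated as real-valued arithmetic (no rounding)."""
    if min_frames + gap_frames <= 0:
        raise ValueError("min_frames + gap_frames must be > 0")
    if n_frames < min_frames:
        raise ValueError("n_frames must be >= min_frames")
    return (n_frames - min_frames) / (min_frames + gap_frames) + 1.0


def build_weight_matrices(events: dict[tuple, list[Bout]], ids,
                          n_frames: int, params: InteractionParams):
    """Duration- and count-weight matrices from per-pair event lists.

    W_duration[i, j] = (sum of condition-true frames over events) / n_frames;
    W_count[i, j] = (number of events) / max_possible_interactions.
    Both symmetric with zero diagonal, vertex order = order of ``ids``.
    """
    ids = list(ids)
    index = {v: k for k, v in enumerate(ids)}
    n = len(ids)
    w_dur = np.zeros((n, n))
    w_cnt = np.zeros((n, n))
    maxpos = max_possible_interactions(n_frames, params.min_frames,
                                       params.gap_frames)
    for (i, j), evs in events.items():
        ii, jj = index[i], index[j]
        dur = sum(e.frames_true for e in evs) / n_frames
        cnt = len(evs) / maxpos
        w_dur[ii, jj] = w_dur[jj, ii] = dur
        w_cnt[ii, jj] = w_cnt[jj, ii] = cnt
    return w_dur, w_cnt


def _check_weights(W) -> np.ndarray:
    W = np.asarray(W, dtype=float)
    if W.ndim != 2 or W.shape[0] != W.shape[1]:
        raise ValueError("weight matrix must be square")
    if not np.allclose(W, W.T):
        raise ValueError("weight matrix must be symmetric")
    if (W < 0).any():
        raise ValueError("weights must be nonnegative")
    return W


def network_density(W, convention: str = "pairs") -> float:
    """Mean edge weight over all possible undirected pairs.

    ``pairs`` (default): sum of the n(n-1)/2 distinct pair weights divided
    by n(n-1)/2, so a fully saturated unit-weight network has density 1.
    ``literal`` applies the alternative operator-precedence reading
    sum / (n(n-1)) * 0.5, a constant factor 1/4 smaller; it does not
    affect between-group comparisons.
    """
    W = _check_weights(W)
    n = W.shape[0]
    if n < 2:
        raise ValueError("need at least 2 vertices")
    total = W[np.triu_indices(n, k=1)].sum()
    if convention == "pairs":
        return float(total / (n * (n - 1) / 2.0))
    if convention == "literal":
        return float(total / (n * (n - 1)) * 0.5)
    raise ValueError("convention must be 'pairs' or 'literal'")


def node_strength(W) -> np.ndarray:
    """Per-vertex sum of incident edge weights."""
    return _check_weights(W).sum(axis=1)


def sd_strength(W) -> float:
    """Sample SD of vertex strengths."""
    return float(np.std(node_strength(W), ddof=1))


def modularity_value(W, membership) -> float:
    """Newman-Girvan modularity of a partition on a weighted graph:
    Q = sum_c [ w_c / m - (d_c / 2m)^2 ] with m the total edge weight,
    w_c the intra-community weight and d_c the community strength sum."""
    W = _check_weights(W)
    membership = np.asarray(membership)
    m = W[np.triu_indices(W.shape[0], k=1)].sum()
    if m == 0:
        return 0.0
    strength = W.sum(axis=1)
    q = 0.0
    for c in np.unique(membership):
        mask = membership == c
        w_c = W[np.ix_(mask, mask)][np.triu_indices(mask.sum(), k=1)].sum()
        d_c = strength[mask].sum()
        q += w_c / m - (d_c / (2.0 * m)) ** 2
    return float(q)


def walktrap_modularity(W, steps: int = 4) -> tuple[np.ndarray, float]:
    """Walktrap community detection (random walks of length ``steps``,
    dendrogram cut at maximum modularity) and the modularity Q of the
    returned partition.  Q is always recomputed from the partition with
    the explicit formula.  An edgeless graph is a single community, Q = 0.
    """
    W = _check_weights(W)
    n = W.shape[0]
    src, dst = np.nonzero(np.triu(W, k=1))
    if src.size == 0:
        return np.zeros(n, dtype=int), 0.0
    g = ig.Graph(n=n, edges=list(zip(src.tolist(), dst.tolist())))
    g.es["weight"] = W[src, dst].tolist()
    clustering = g.community_walktrap(weights="weight", steps=steps) \
                  .as_clustering()
    membership = np.asarray(clustering.membership, dtype=int)
    return membership, modularity_value(W, membership)


def weighted_betweenness(W) -> np.ndarray:
    """Shortest-path betweenness centrality with edge length = 1 / weight
    (weights are affinities: a stronger tie is a shorter path).  Zero-weight
    pairs are non-edges; equal-length geodesics split the pair count."""
    W = _check_weights(W)
    n = W.shape[0]
    G = nx.Graph()
    G.add_nodes_from(range(n))
    src, dst = np.nonzero(np.triu(W, k=1))
    for i, j in zip(src, dst):
        G.add_edge(int(i), int(j), length=1.0 / W[i, j])
    bc = nx.betweenness_centrality(G, weight="length", normalized=False)
    return np.array([bc[i] for i in range(n)])


@dataclass
class SocialNetwork:
    """A weighted social network and its metric summary."""
    ids: list
    weights: np.ndarray
    variant: str  # "duration" or "count"
    density: float = field(init=False)
    strength: np.ndarray = field(init=False)
    sd_strength: float = field(init=False)
    communities: np.ndarray = field(init=False)
    modularity: float = field(init=False)
    betweenness: np.ndarray = field(init=False)
    sd_betweenness: float = field(init=False)

    def __post_init__(self):
        self.weights = _check_weights(self.weights)
        self.density = network_density(self.weights)
        self.strength = node_strength(self.weights)
        self.sd_strength = float(np.std(self.strength, ddof=1))
        self.communities, self.modularity = walktrap_modularity(self.weights)
        self.betweenness = weighted_betweenness(self.weights)
        self.sd_betweenness = float(np.std(self.betweenness, ddof=1))

    def summary(self) -> dict[str, float]:
        v = self.variant
        return {
            f"density_{v}": self.density,
            f"mean_strength_{v}": float(self.strength.mean()),
            f"sd_strength_{v}": self.sd_strength,
            f"modularity_{v}": self.modularity,
            f"sd_betweenness_{v}": self.sd_betweenness,
        }


def network_metrics(W, variant: str = "duration") -> dict[str, float]:
    """Metric summary of one weight matrix (vertex ids 0..n-1)."""
    return SocialNetwork(list(range(W.shape[0])), W, variant).summary()


@dataclass
class ArenaAnalysis:
    """End-to-end result for one recording: events, both networks and a
    flat per-group summary row."""
    ids: list
    n_frames: int
    events: dict
    duration_network: SocialNetwork
    count_network: SocialNetwork
    mean_pair_distance: float
    summary: dict[str, float]


def analyze_arena(table: pd.DataFrame,
                  params: InteractionParams | None = None) -> ArenaAnalysis:
    """Detect interaction events in a trajectory table and build the
    duration- and count-weighted networks with their metrics."""
    params = params or InteractionParams()
    ids, X, Y, TH, A, B = trajectory_arrays(table)
    n_frames = X.shape[0]
    conds = interaction_conditions(table, params)
    events = {pair: detect_events(c, params) for pair, c in conds.items()}
    w_dur, w_cnt = build_weight_matrices(events, ids, n_frames, params)
    net_d = SocialNetwork(list(ids), w_dur, "duration")
    net_c = SocialNetwork(list(ids), w_cnt, "count")

    iu, ju = np.triu_indices(len(ids), k=1)
    dists = np.hypot(X[:, iu] - X[:, ju], Y[:, iu] - Y[:, ju])
    mean_dist = float(dists.mean()) if dists.size else float("nan")

    summary = {**net_d.summary(), **net_c.summary(),
               "mean_pair_distance": mean_dist,
               "n_events": float(sum(len(e) for e in events.values()))}
    return ArenaAnalysis(list(ids), n_frames, events, net_d, net_c,
                         mean_dist, summary)
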