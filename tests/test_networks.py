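"""Weight matrices and network metrics: closed forms, exhaustive oracles
and the end-to-end arena analysis."""

import numpy as np
import pytest

import networkx as nx

from socialarena import (InteractionParams, analyze_arena,
                         build_weight_matrices, interaction_conditions,
                         max_possible_interactions, network_density,
                         node_strength, pair_condition, pair_frame_features,
                         sd_strength, walktrap_modularity,
                         weighted_betweenness)
from socialarena.bouts import Bout
from socialarena.networks import modularity_value
from conftest import make_trajectory


# ---------------------------------------------------------------- conditions

def test_pair_condition_union_and_inclusive_boundary(random_walk_table):
    import pandas as pd
    pf = pd.DataFrame({
        "frame": [0, 0, 1, 1, 2, 2],
        "i": [0, 1, 0, 1, 0, 1],
        "j": [1, 0, 1, 0, 1, 0],
        # frame 0: i->j only; frame 1: neither; frame 2: boundary 8.0 mm
        "dnose2ell": [5.0, 20.0, 20.0, 20.0, 8.0, 9.0],
        "anglesub": [0.5, 0.5, 0.0, 0.0, 0.5, 0.0],
    })
    series = pair_condition(pf, InteractionParams())
    assert list(series[(0, 1)]) == [True, False, True]
    series_and = pair_condition(pf, InteractionParams(symmetrize="and"))
    assert list(series_and[(0, 1)]) == [False, False, False]


def test_fast_condition_path_equals_feature_route(random_walk_table):
    params = InteractionParams(dist_max=8.0)
    fast = interaction_conditions(random_walk_table, params)
    slow = pair_condition(pair_frame_features(random_walk_table), params)
    assert fast.keys() == slow.keys()
    for k in fast:
        assert (fast[k] == slow[k]).all()


# ------------------------------------------------------------ weight matrices

def test_duration_weight_arithmetic():
    events = {(0, 1): [Bout(0, 5399, 5400)]}
    w_dur, w_cnt = build_weight_matrices(events, [0, 1, 2], 54_000,
                                         InteractionParams())
    assert w_dur[0, 1] == pytest.approx(0.1, abs=1e-15)
    assert w_dur[1, 0] == w_dur[0, 1] and w_dur[2, :].sum() == 0


def test_count_weight_arithmetic():
    events = {(0, 1): [Bout(0, 99, 100), Bout(300, 400, 90),
                       Bout(700, 800, 80)]}
    _, w_cnt = build_weight_matrices(events, [0, 1], 54_000,
                                     InteractionParams())
    assert w_cnt[0, 1] == pytest.approx(3 / (53_940 / 180 + 1), rel=1e-12)


def test_no_events_gives_zero_matrices():
    w_dur, w_cnt = build_weight_matrices({}, [0, 1, 2], 1000,
                                         InteractionParams())
    assert not w_dur.any() and not w_cnt.any()


# ------------------------------------------------------------------- metrics

def test_density_closed_forms():
    n = 10
    full = np.ones((n, n)) - np.eye(n)
    assert network_density(full) == pytest.approx(1.0, abs=1e-15)
    assert network_density(np.zeros((4, 4))) == 0.0
    w = np.zeros((3, 3))
    w[0, 1] = w[1, 0] = 0.5
    w[0, 2] = w[2, 0] = 0.25
    assert network_density(w) == pytest.approx(0.25, abs=1e-15)
    assert network_density(w, convention="literal") == \
        pytest.approx(0.0625, abs=1e-15)
    with pytest.raises(ValueError):
        network_density(np.zeros((1, 1)))


def test_strength_arithmetic_and_handshake(rng):
    w = np.zeros((3, 3))
    w[0, 1] = w[1, 0] = 0.5
    w[0, 2] = w[2, 0] = 0.25
    assert np.allclose(node_strength(w), [0.75, 0.5, 0.25])
    r = rng.random((6, 6))
    W = np.triu(r, 1) + np.triu(r, 1).T
    assert node_strength(W).sum() == pytest.approx(
        2 * W[np.triu_indices(6, 1)].sum(), rel=1e-12)
    assert sd_strength(np.ones((4, 4)) - np.eye(4)) == 0.0


def _two_triangles():
    w = np.zeros((6, 6))
    for (i, j) in [(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)]:
        w[i, j] = w[j, i] = 1.0
    return w


def test_walktrap_two_triangles():
    w = _two_triangles()
    membership, q = walktrap_modularity(w)
    assert len(set(membership[:3])) == 1 and len(set(membership[3:])) == 1
    assert membership[0] != membership[3]
    assert q == pytest.approx(0.5, abs=1e-12)


def test_single_community_modularity_zero():
    w = _two_triangles()
    assert modularity_value(w, np.zeros(6)) == pytest.approx(0.0, abs=1e-15)


def test_all_zero_matrix_single_community():
    membership, q = walktrap_modularity(np.zeros((5, 5)))
    assert q == 0.0 and len(set(membership)) == 1


def test_walktrap_q_equals_formula_and_near_optimal(rng):
    """On random small graphs the returned Q equals the explicit formula
    exactly; versus brute-force partition enumeration walktrap is a
    heuristic, so shortfalls are tolerated but counted."""
    def all_partitions(items):
        if not items:
            yield []
            return
        first, rest = items[0], items[1:]
        for part in all_partitions(rest):
            for i, block in enumerate(part):
                yield part[:i] + [block + [first]] + part[i + 1:]
            yield [[first]] + part

    shortfalls = 0
    for _ in range(20):
        n = int(rng.integers(4, 8))
        mask = rng.random((n, n)) < 0.5
        w = np.triu(mask * rng.random((n, n)), 1)
        w = w + w.T
        membership, q = walktrap_modularity(w)
        assert q == pytest.approx(modularity_value(w, membership), abs=1e-12)
        best = -np.inf
        for part in all_partitions(list(range(n))):
            memb = np.empty(n, dtype=int)
            for c, block in enumerate(part):
                memb[block] = c
            best = max(best, modularity_value(w, memb))
        if q < best - 1e-9:
            shortfalls += 1
    assert shortfalls <= 6  # heuristic, usually optimal on tiny graphs


def brute_force_betweenness(W):
    """All-pairs enumeration of shortest paths with edge length 1/weight;
    equal-length geodesics split the pair count."""
    n = W.shape[0]
    G = nx.Graph()
    G.add_nodes_from(range(n))
    for i in range(n):
        for j in range(i + 1, n):
            if W[i, j] > 0:
                G.add_edge(i, j, length=1.0 / W[i, j])
    bc = np.zeros(n)
    for s in range(n):
        for t in range(s + 1, n):
            best, paths = np.inf, []
            for path in nx.all_simple_paths(G, s, t):
                ln = sum(G[u][v]["length"] for u, v in zip(path, path[1:]))
                if ln < best - 1e-12:
                    best, paths = ln, [path]
                elif abs(ln - best) <= 1e-12:
                    paths.append(path)
            for path in paths:
                for v in path[1:-1]:
                    bc[v] += 1.0 / len(paths)
    return bc


def test_betweenness_closed_forms():
    w = np.zeros((3, 3))
    w[0, 1] = w[1, 0] = 1.0
    w[1, 2] = w[2, 1] = 1.0
    assert np.allclose(weighted_betweenness(w), [0, 1, 0])
    full = np.ones((5, 5)) - np.eye(5)
    assert np.allclose(weighted_betweenness(full), 0.0)


def test_betweenness_matches_exhaustive_oracle(rng):
    for _ in range(30):
        n = int(rng.integers(3, 8))
        mask = rng.random((n, n)) < 0.6
        w = np.triu(mask * rng.uniform(0.1, 2.0, (n, n)), 1)
        w = w + w.T
        got = weighted_betweenness(w)
        want = brute_force_betweenness(w)
        assert np.allclose(got, want, atol=1e-9)


# ------------------------------------------------------------------ pipeline

def test_scripted_pair_duration_weight():
    """Two agents nose-to-tail within range for exactly 90 frames of a
    27,000-frame recording: duration weight 90/27000."""
    nf = 27_000
    pos = np.zeros((nf, 2, 2))
    pos[:, 1, 0] = 40.0  # far apart by default
    pos[5000:5090, 1, 0] = 4.0  # within 8 mm for 90 frames
    table = make_trajectory(pos, thetas=0.0)
    res = analyze_arena(table, InteractionParams())
    assert res.duration_network.weights[0, 1] == pytest.approx(90 / nf,
                                                               rel=1e-12)
    assert len(res.events[(0, 1)]) == 1
    assert res.events[(0, 1)][0].frames_true == 90


def test_distant_stationary_agents_empty_network():
    pos = np.array([[[0, 0], [20, 0], [-20, 0]]] * 300, dtype=float)
    res = analyze_arena(make_trajectory(pos))
    assert res.summary["density_duration"] == 0.0
    assert res.summary["n_events"] == 0.0
    assert not res.duration_network.weights.any()


def test_duration_weights_bounded_and_events_disjoint(random_walk_table):
    res = analyze_arena(random_walk_table,
                        InteractionParams(min_frames=5, gap_frames=10))
    W = res.duration_network.weights
    assert np.all((W >= 0) & (W <= 1)) and np.allclose(np.diag(W), 0)
    for evs in res.events.values():
        for prev, nxt in zip(evs, evs[1:]):
            assert nxt.start - prev.end - 1 >= 10
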