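"""Kaplan-Meier estimation and log-rank comparisons against closed forms,
empirical survivor fractions and an exact permutation oracle."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from socialarena import (km_curve, logrank_test, median_survival,
                         pairwise_logrank_fdr, renyi_test)
from socialarena.stats import bh_adjust


def test_km_no_censoring_stepwise():
    c = km_curve([1, 2, 3, 4])
    assert np.allclose(c.times, [1, 2, 3, 4])
    assert np.allclose(c.survival, [0.75, 0.5, 0.25, 0.0])
    assert np.allclose(c.at_risk, [4, 3, 2, 1])


def test_km_all_censored_stays_at_one():
    c = km_curve([1, 2, 3], events=[0, 0, 0])
    assert c.times.size == 0  # no event steps; S identically 1
    assert np.isnan(median_survival(c))


def test_km_equals_empirical_survivor_fraction(rng):
    """With no censoring S(t_i) is the fraction of individuals surviving
    past t_i."""
    for _ in range(20):
        t = np.round(rng.exponential(10, size=int(rng.integers(5, 40))), 3)
        c = km_curve(t)
        for ti, si in zip(c.times, c.survival):
            assert si == pytest.approx((t > ti).mean(), abs=1e-12)


def test_median_survival_definitions():
    c = km_curve([1, 2, 3, 4])
    assert median_survival(c) == 2.0
    # S never reaches 0.5: 1 death among 10 (rest censored)
    c2 = km_curve([1] + [5] * 9, events=[1] + [0] * 9)
    assert np.isnan(median_survival(c2))


def test_median_equals_order_statistic_for_even_n(rng):
    for _ in range(20):
        n = 2 * int(rng.integers(3, 15))
        t = rng.permutation(rng.uniform(1, 100, n))
        # S first reaches 0.5 at the (n/2)-th death time
        assert median_survival(km_curve(t)) == \
            pytest.approx(np.sort(t)[n // 2 - 1])


def manual_logrank_statistic(ta, tb, ea, eb):
    """Explicit O-E / hypergeometric-variance computation."""
    times = np.concatenate([ta, tb])
    events = np.concatenate([ea, eb]).astype(bool)
    grp = np.r_[np.zeros(len(ta), bool), np.ones(len(tb), bool)]
    u = v = 0.0
    for t in np.unique(times[events]):
        at_risk = times >= t
        n = at_risk.sum()
        n_a = (at_risk & ~grp).sum()
        d = (events & (times == t)).sum()
        d_a = (events & (times == t) & ~grp).sum()
        u += d_a - d * n_a / n
        if n > 1:
            v += d * (n_a / n) * (1 - n_a / n) * (n - d) / (n - 1)
    return u, v


def test_logrank_identical_groups_p_one():
    t = [1.0, 2.0, 3.0, 5.0]
    stat, p = logrank_test(t, t)
    assert stat == pytest.approx(0.0, abs=1e-12)
    assert p == pytest.approx(1.0, abs=1e-12)


def test_logrank_separated_groups_significant():
    stat, p = logrank_test([1, 2, 3], [10, 11, 12])
    assert p < 0.05


def test_logrank_statistic_matches_formula(rng):
    for _ in range(20):
        na, nb = rng.integers(4, 15, 2)
        ta = rng.exponential(10, na)
        tb = rng.exponential(14, nb)
        ea = rng.random(na) < 0.8
        eb = rng.random(nb) < 0.8
        if not (ea.any() or eb.any()):
            continue
        stat, _ = logrank_test(ta, tb, ea, eb)
        u, v = manual_logrank_statistic(ta, tb, ea, eb)
        if v > 0:
            assert stat == pytest.approx(u * u / v, rel=1e-6)


def test_logrank_symmetric_in_group_order(rng):
    ta, tb = rng.exponential(10, 8), rng.exponential(5, 9)
    s1, p1 = logrank_test(ta, tb)
    s2, p2 = logrank_test(tb, ta)
    assert s1 == pytest.approx(s2, rel=1e-12)
    assert p1 == pytest.approx(p2, rel=1e-12)


def exact_permutation_p(ta, tb):
    """Exact permutation distribution of the log-rank statistic over all
    C(n_a + n_b, n_a) label assignments (no censoring, distinct times),
    vectorized over assignments.  With d = 1 at every distinct event time
    the statistic reduces to U = sum(l_r - E_r), V = sum(E_r (1 - E_r))
    with E_r the fraction of the risk set belonging to group A at the
    r-th smallest time and l_r the group indicator of that death."""
    pooled = np.concatenate([ta, tb])
    n_total, n_a = len(pooled), len(ta)
    order = np.argsort(pooled)
    idx = np.array(list(combinations(range(n_total), n_a)))
    member = np.zeros((len(idx), n_total), bool)
    member[np.arange(len(idx))[:, None], idx] = True
    labels = member[:, order]

    def stats(lab):
        at_risk_a = np.cumsum(lab[:, ::-1], axis=1)[:, ::-1].astype(float)
        n_r = np.arange(n_total, 0, -1, dtype=float)
        e = at_risk_a / n_r
        u = (lab - e).sum(axis=1)
        v = (e * (1 - e)).sum(axis=1)
        return u * u / np.maximum(v, 1e-300)

    all_stats = stats(labels)
    obs_mask = np.zeros(n_total, bool)
    obs_mask[:n_a] = True
    obs = stats(obs_mask[order][None, :])[0]
    return float((all_stats >= obs - 1e-12).mean())


def test_logrank_p_agrees_with_exact_permutation(rng):
    """Chi-square p versus the exact permutation p (all 184,756 label
    assignments at 10 vs 10); the chi-square reference is asymptotic, so
    agreement is to 0.05 absolute."""
    for _ in range(5):
        ta = rng.exponential(10, 10)
        tb = rng.exponential(20, 10)
        stat, p = logrank_test(ta, tb)
        p_perm = exact_permutation_p(ta, tb)
        assert p == pytest.approx(p_perm, abs=0.05)


def test_pairwise_logrank_two_groups_adjusted_equals_raw(rng):
    rec = pd.DataFrame({
        "group": ["a"] * 10 + ["b"] * 10,
        "time_h": np.r_[rng.exponential(10, 10), rng.exponential(10, 10)],
        "event": 1,
    })
    out = pairwise_logrank_fdr(rec)
    assert len(out) == 1
    assert out["p_adj"].iloc[0] == pytest.approx(out["p_raw"].iloc[0])


def test_pairwise_logrank_identical_groups_near_one(rng):
    base = rng.exponential(20, 30)
    rec = pd.DataFrame({
        "group": np.repeat(["a", "b", "c"], 30),
        "time_h": np.tile(base, 3),
        "event": 1,
    })
    out = pairwise_logrank_fdr(rec)
    assert (out["p_adj"] > 0.99).all()
    assert np.allclose(out["p_adj"], bh_adjust(out["p_raw"]))


def test_renyi_reserved():
    with pytest.raises(NotImplementedError):
        renyi_test()
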