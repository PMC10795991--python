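"""Kaplan-Meier estimation and pairwise log-rank comparisons with FDR.

Survival records carry one row per individual: group label, time to
event in hours, and an event flag (death observed vs right-censored).
The product-limit estimator and the log-rank test are delegated to
lifelines; this module fixes the conventions used throughout (censored
individuals at time t leave the risk set after the events at t;
interval-recorded deaths are treated as exact at the recorded time) and
adds the pairwise Benjamini-Hochberg layer used for multi-cohort stress
and longevity assays.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank

from .stats import bh_adjust

__all__ = ["SurvivalCurve", "km_curve", "median_survival", "logrank_test",
           "pairwise_logrank_fdr", "renyi_test"]


@dataclass(frozen=True)
class SurvivalCurve:
    """Product-limit estimate: distinct event times, S(t) just after each,
    number at risk and number of deaths at each."""
    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    deaths: np.ndarray


def _as_arrays(times, events):
    t = np.asarray(times, dtype=float)
    if events is None:
        e = np.ones(t.shape, dtype=bool)
    else:
        e = np.asarray(events).astype(bool)
    if t.size == 0:
        raise ValueError("no survival records")
    if (t <= 0).any():
        raise ValueError("times must be > 0")
    return t, e


def km_curve(times, events=None) -> SurvivalCurve:
    """Kaplan-Meier curve for one group: S(t) = prod(1 - d_i/n_i) over
    event times <= t.  ``events`` defaults to all-observed."""
    t, e = _as_arrays(times, events)
    kmf = KaplanMeierFitter().fit(t, e)
    tab = kmf.event_table
    ev = tab[tab["observed"] > 0]
    ev_times = ev.index.to_numpy(dtype=float)
    surv = kmf.survival_function_at_times(ev_times).to_numpy()
    return SurvivalCurve(times=ev_times, survival=surv,
                         at_risk=ev["at_risk"].to_numpy(dtype=float),
                         deaths=ev["observed"].to_numpy(dtype=float))


def median_survival(curve: SurvivalCurve) -> float:
    """Smallest event time with S(t) <= 0.5; NaN if never reached.

    A 1e-12 tolerance absorbs round-off in the product-limit estimate
    (e.g. 6 deaths among 6 give S = 0.5 + eps at the third)."""
    hit = curve.survival <= 0.5 + 1e-12
    return float(curve.times[hit][0]) if hit.any() else float("nan")


def logrank_test(times_a, times_b, events_a=None, events_b=None
                 ) -> tuple[float, float]:
    """Two-group log-rank test; returns (chi-square statistic, p).

    Statistic is (sum O-E)^2 / V with hypergeometric variance summed over
    distinct event times, referred to chi-square with 1 df.
    """
    ta, ea = _as_arrays(times_a, events_a)
    tb, eb = _as_arrays(times_b, events_b)
    if not (ea.any() or eb.any()):
        raise ValueError("log-rank undefined: no events in either group")
    res = _ll_logrank(ta, tb, event_observed_A=ea, event_observed_B=eb)
    return float(res.test_statistic), float(res.p_value)


def pairwise_logrank_fdr(records: pd.DataFrame, group_col: str = "group",
                         time_col: str = "time_h", event_col: str = "event"
                         ) -> pd.DataFrame:
    """Log-rank test for every unordered pair of groups with BH adjustment
    across pairs.  Returns group_a, group_b, statistic, p_raw, p_adj."""
    groups = sorted(records[group_col].unique(), key=str)
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    rows = []
    for a, b in combinations(groups, 2):
        ra = records[records[group_col] == a]
        rb = records[records[group_col] == b]
        stat, p = logrank_test(ra[time_col], rb[time_col],
                               ra[event_col], rb[event_col])
        rows.append({"group_a": a, "group_b": b, "statistic": stat,
                     "p_raw": p})
    out = pd.DataFrame(rows)
    out["p_adj"] = bh_adjust(out["p_raw"])
    return out


def renyi_test(*args, **kwargs):
    """Supremum-type (Renyi) survival test; reserved, not implemented."""
    raise NotImplementedError(
        "the Renyi-type supremum test is not implemented; use logrank_test")
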