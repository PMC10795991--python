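"""Behavioral-signature normalization and per-feature group comparisons.

A feature table has one row per arena/replicate: a group label plus the
named behavioral parameters (kinetic features, behavior fractions,
network metrics).  Signatures are z-scored per feature over ALL
replicates pooled across groups, so group differences read directly as
effect sizes on a common scale.  Group comparisons follow the standard
normality-gated scheme: Shapiro-Wilk on residuals decides between
one-way ANOVA + Tukey HSD and Kruskal-Wallis + Dunn post-hoc, and
Benjamini-Hochberg FDR adjustment is applied across features within
each pairwise contrast.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = ["zscore_signature", "percent_diff_from_average",
           "compare_groups", "bh_adjust", "ComparisonResults"]


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (NaNs passed through)."""
    p = np.asarray(pvalues, dtype=float)
    out = np.full(p.shape, np.nan)
    ok = np.isfinite(p)
    if ok.any():
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out


def zscore_signature(table: pd.DataFrame, group_col: str = "group"
                     ) -> tuple[pd.DataFrame, list[str]]:
    """Z-score every numeric feature over all replicates pooled across
    groups (sample SD).  Constant features become all-zero and are
    returned in the degeneracy list; features with fewer than two
    non-missing values are dropped with a warning.
    """
    out = table.copy()
    degenerate: list[str] = []
    for col in table.columns:
        if col == group_col:
            continue
        x = pd.to_numeric(table[col], errors="coerce")
        n = x.notna().sum()
        if n < 2:
            warnings.warn(f"feature {col!r} has < 2 values; excluded")
            out = out.drop(columns=col)
            continue
        sd = x.std(ddof=1)
        if sd == 0 or not np.isfinite(sd):
            out[col] = np.where(x.notna(), 0.0, np.nan)
            degenerate.append(col)
        else:
            out[col] = (x - x.mean()) / sd
    return out, degenerate


def percent_diff_from_average(values, batch=None) -> np.ndarray:
    """100 * (x - mean) / mean, per experiment batch if given."""
    x = np.asarray(values, dtype=float)
    if batch is None:
        m = np.nanmean(x)
        if m == 0:
            raise ValueError("mean is zero; percent difference undefined")
        return 100.0 * (x - m) / m
    batch = np.asarray(batch)
    out = np.empty_like(x)
    for b in np.unique(batch):
        mask = batch == b
        out[mask] = percent_diff_from_average(x[mask])
    return out


def _dunn_pairwise(groups: list[np.ndarray]) -> dict[tuple[int, int], float]:
    """Dunn's post-hoc z-tests on pooled ranks with tie correction."""
    pooled = np.concatenate(groups)
    n_total = pooled.size
    ranks = sps.rankdata(pooled)
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = (counts ** 3 - counts).sum() / (12.0 * (n_total - 1))
    var_base = n_total * (n_total + 1) / 12.0 - tie_term
    mean_ranks = []
    pos = 0
    for g in groups:
        mean_ranks.append(ranks[pos:pos + g.size].mean())
        pos += g.size
    out = {}
    for a, b in combinations(range(len(groups)), 2):
        se = np.sqrt(var_base * (1.0 / groups[a].size + 1.0 / groups[b].size))
        z = (mean_ranks[a] - mean_ranks[b]) / se if se > 0 else 0.0
        out[(a, b)] = float(2.0 * sps.norm.sf(abs(z)))
    return out


@dataclass
class ComparisonResults:
    """Omnibus and pairwise results of compare_groups.

    omnibus: one row per feature (test name, p, normality flag);
    pairwise: one row per feature x contrast with raw and BH-adjusted p.
    """
    omnibus: pd.DataFrame
    pairwise: pd.DataFrame
    skipped: list[str] = field(default_factory=list)


def compare_groups(table: pd.DataFrame, group_col: str = "group",
                   alpha: float = 0.05, normality_on: str = "residuals",
                   fdr_family: str = "per_contrast") -> ComparisonResults:
    """Per-feature group comparison with normality-gated test selection.

    Residuals (per-group mean removed; or raw values with
    ``normality_on='raw'``) are tested with Shapiro-Wilk at ``alpha``;
    normal features get one-way ANOVA + Tukey HSD, the rest
    Kruskal-Wallis + Dunn.  BH adjustment runs across features within
    each pairwise contrast (default) or over all features x contrasts
    (``fdr_family='global'``).  Features with any group below 3
    replicates are skipped with a warning.
    """
    if normality_on not in ("residuals", "raw"):
        raise ValueError("normality_on must be 'residuals' or 'raw'")
    if fdr_family not in ("per_contrast", "global"):
        raise ValueError("fdr_family must be 'per_contrast' or 'global'")
    group_labels = sorted(table[group_col].unique(), key=str)
    if len(group_labels) < 2:
        raise ValueError("need at least 2 groups")

    omnibus_rows, pairwise_rows, skipped = [], [], []
    for col in table.columns:
        if col == group_col:
            continue
        x = pd.to_numeric(table[col], errors="coerce")
        groups = [x[table[group_col] == g].dropna().to_numpy()
                  for g in group_labels]
        if any(len(g) < 3 for g in groups):
            warnings.warn(f"feature {col!r}: group with < 3 replicates; skipped")
            skipped.append(col)
            continue
        pooled = np.concatenate(groups)
        if np.ptp(pooled) == 0:  # degenerate: identical values everywhere
            omnibus_rows.append({"feature": col, "test": "degenerate",
                                 "p": 1.0, "normal": True})
            for a, b in combinations(range(len(groups)), 2):
                pairwise_rows.append({
                    "feature": col, "group_a": group_labels[a],
                    "group_b": group_labels[b], "p_raw": 1.0})
            continue
        resid = (pooled if normality_on == "raw" else
                 np.concatenate([g - g.mean() for g in groups]))
        if np.ptp(resid) == 0:
            normal = True  # zero within-group variance; Shapiro undefined
        else:
            normal = sps.shapiro(resid).pvalue >= alpha
        if normal:
            omnibus_p = float(sps.f_oneway(*groups).pvalue)
            test_name = "anova"
            tk = sps.tukey_hsd(*groups)
            pair_p = {(a, b): float(tk.pvalue[a, b])
                      for a, b in combinations(range(len(groups)), 2)}
        else:
            omnibus_p = float(sps.kruskal(*groups).pvalue)
            test_name = "kruskal"
            pair_p = _dunn_pairwise(groups)
        omnibus_rows.append({"feature": col, "test": test_name,
                             "p": omnibus_p, "normal": normal})
        for (a, b), p in pair_p.items():
            pairwise_rows.append({
                "feature": col, "group_a": group_labels[a],
                "group_b": group_labels[b], "p_raw": p})

    omnibus = pd.DataFrame(omnibus_rows,
                           columns=["feature", "test", "p", "normal"])
    pairwise = pd.DataFrame(
        pairwise_rows, columns=["feature", "group_a", "group_b", "p_raw"])
    if len(pairwise):
        if fdr_family == "per_contrast":
            pairwise["p_adj"] = np.nan
            for _, idx in pairwise.groupby(["group_a", "group_b"]).groups.items():
                pairwise.loc[idx, "p_adj"] = bh_adjust(
                    pairwise.loc[idx, "p_raw"])
        else:
            pairwise["p_adj"] = bh_adjust(pairwise["p_raw"])
    else:
        pairwise["p_adj"] = pd.Series(dtype=float)
    return ComparisonResults(omnibus, pairwise, skipped)
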