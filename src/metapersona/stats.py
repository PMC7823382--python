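"""Statistical comparison of reaction activity across phenotype groups.

Fisher's exact test (two-sided, probability-ordering rule) on per-reaction
activity contingency tables, Benjamini-Hochberg FDR across reactions,
hypergeometric subsystem enrichment of the significant reactions, Wilcoxon
rank-sum for per-gene knockout effects, and Pearson chi-squared for
cluster-phenotype association tables.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "fisher_exact",
    "bh_fdr",
    "differential_reactions",
    "subsystem_enrichment",
    "wilcoxon_rank_sum",
    "chi_squared",
    "essentiality_comparison",
]


def fisher_exact(table) -> tuple[float, float]:
    """Two-sided Fisher exact test on a 2x2 count table.

    Returns ``(odds_ratio, p)``.  The two-sided p sums hypergeometric
    probabilities of all tables (same margins) no more probable than the
    observed one.  Odds ratio is ``(a d)/(b c)`` with the usual inf/NaN
    conventions for zero cells.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if np.any(t < 0):
        raise ValueError("counts must be nonnegative")
    a, b, c, d = t.ravel()
    if t.sum() == 0:
        return float("nan"), 1.0
    res = sps.fisher_exact(t.astype(int), alternative="two-sided")
    if b * c == 0:
        odds = float("nan") if a * d == 0 else float("inf")
    else:
        odds = (a * d) / (b * c)
    return odds, float(res.pvalue)


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values (capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def differential_reactions(activity: pd.DataFrame, groups: pd.Series,
                           group_a, group_b) -> pd.DataFrame:
    """Per-reaction Fisher test of activity (reactions x samples, 0/1)
    between two sample groups, BH-corrected across reactions.

    Output columns: the four 2x2 counts (active/inactive x A/B), odds
    ratio, p, q.
    """
    groups = groups.reindex(activity.columns)
    in_a = (groups == group_a).to_numpy()
    in_b = (groups == group_b).to_numpy()
    if not in_a.any() or not in_b.any():
        raise ValueError(f"empty group among {group_a!r}/{group_b!r}")
    act = activity.to_numpy()
    a = act[:, in_a].sum(axis=1)
    b = act[:, in_b].sum(axis=1)
    c = in_a.sum() - a
    d = in_b.sum() - b
    odds = np.empty(len(a))
    pvals = np.empty(len(a))
    for i in range(len(a)):
        odds[i], pvals[i] = fisher_exact([[a[i], b[i]], [c[i], d[i]]])
    out = pd.DataFrame({
        "active_a": a, "active_b": b, "inactive_a": c, "inactive_b": d,
        "odds_ratio": odds, "p": pvals, "q": bh_fdr(pvals),
    }, index=activity.index)
    out.index.name = "reaction"
    return out


def subsystem_enrichment(differential: pd.DataFrame, subsystem_map: pd.Series,
                         p_threshold: float = 0.05) -> pd.DataFrame:
    """Subsystem over-representation among significantly differential reactions.

    ``differential`` is the output of :func:`differential_reactions`;
    reactions with ``p < p_threshold`` form the significant set.  Each
    subsystem is tested with a Fisher 2x2 (significant vs not) x (in
    subsystem vs not), BH-corrected across subsystems.
    """
    subsystem_map = subsystem_map.reindex(differential.index)
    if subsystem_map.dropna().empty:
        raise ValueError("empty subsystem map")
    sig = differential["p"] < p_threshold
    records = []
    for sub, members in subsystem_map.groupby(subsystem_map):
        in_sub = subsystem_map == sub
        a = int((sig & in_sub).sum())
        b = int((sig & ~in_sub).sum())
        c = int((~sig & in_sub).sum())
        d = int((~sig & ~in_sub).sum())
        odds, p = fisher_exact([[a, b], [c, d]])
        records.append((sub, a, b, c, d, odds, p))
    out = pd.DataFrame(records, columns=[
        "subsystem", "sig_in", "sig_out", "nonsig_in", "nonsig_out",
        "odds_ratio", "p"]).set_index("subsystem")
    out["q"] = bh_fdr(out["p"].to_numpy())
    return out.sort_values("p")


def wilcoxon_rank_sum(x, y) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney U) test.

    Exact enumeration when ``n + m <= 10`` and there are no ties; otherwise
    the tie-corrected normal approximation.  Identical constant samples
    give p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return float(x.size * y.size / 2), 1.0
    has_ties = len(np.unique(pooled)) < pooled.size
    method = "exact" if (x.size + y.size <= 10 and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def chi_squared(contingency) -> tuple[float, float]:
    """Pearson chi-squared test of independence on an r x c count table.

    Zero-margin rows/columns are dropped with a warning.
    """
    t = np.asarray(contingency, dtype=float)
    if t.ndim != 2 or min(t.shape) < 2:
        raise ValueError("need an r x c table with r, c >= 2")
    if np.any(t < 0):
        raise ValueError("counts must be nonnegative")
    keep_r = t.sum(axis=1) > 0
    keep_c = t.sum(axis=0) > 0
    if not keep_r.all() or not keep_c.all():
        warnings.warn("dropping zero-margin rows/columns from contingency table")
        t = t[keep_r][:, keep_c]
        if min(t.shape) < 2:
            return 0.0, 1.0
    stat, p, _, _ = sps.chi2_contingency(t, correction=False)
    return float(stat), float(p)


def essentiality_comparison(gr_ratios: pd.DataFrame, groups: pd.Series,
                            group_a, group_b) -> pd.DataFrame:
    """Per-gene Wilcoxon rank-sum of per-sample grRatio vectors between two
    groups of context networks (e.g. cancer vs normal), BH-corrected.

    ``gr_ratios`` is genes x samples.
    """
    groups = groups.reindex(gr_ratios.columns)
    in_a = (groups == group_a).to_numpy()
    in_b = (groups == group_b).to_numpy()
    if not in_a.any() or not in_b.any():
        raise ValueError(f"empty group among {group_a!r}/{group_b!r}")
    vals = gr_ratios.to_numpy()
    stats_u = np.empty(vals.shape[0])
    pvals = np.empty(vals.shape[0])
    mean_a = vals[:, in_a].mean(axis=1)
    mean_b = vals[:, in_b].mean(axis=1)
    for i in range(vals.shape[0]):
        stats_u[i], pvals[i] = wilcoxon_rank_sum(vals[i, in_a], vals[i, in_b])
    out = pd.DataFrame({
        "mean_grratio_a": mean_a, "mean_grratio_b": mean_b,
        "u_statistic": stats_u, "p": pvals, "q": bh_fdr(pvals),
    }, index=gr_ratios.index)
    out.index.name = "gene"
    return out.sort_values("p")
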