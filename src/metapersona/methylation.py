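"""Joint expression-methylation divergence.

CpG beta values (proportion methylated, in (0,1)) are divergence-coded with
the same rank/baseline machinery as expression, against the normal samples'
methylation as baseline.  For each CpG mapped to a gene, the joint
divergence proportion is the fraction of shared tumor samples divergent
(code != 0) in both the gene's expression and the CpG's methylation
simultaneously; CpGs are reported in genomic order with their promoter
flags.  Spearman correlation between a CpG's betas and its gene's
expression is computed separately per phenotype group.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .divergence import encode_divergence, estimate_baseline, rank_transform
from .drugs import spearman

__all__ = [
    "methylation_divergence",
    "joint_divergence_proportion",
    "expr_meth_correlation",
]


def _check_cpg_map(cpg_map: pd.DataFrame) -> pd.DataFrame:
    required = {"gene", "promoter", "chrom", "pos"}
    missing = required - set(cpg_map.columns)
    if missing:
        raise ValueError(f"CpG map missing columns {sorted(missing)}")
    return cpg_map


def methylation_divergence(beta: pd.DataFrame, normal_ids: list[str],
                           gamma: float = 0.9) -> pd.DataFrame:
    """Ternary divergence coding of beta values against the normal baseline.

    All normal samples present in ``beta`` serve as the reference; the
    returned coding covers the remaining (tumor) columns.
    """
    vals = beta.to_numpy(dtype=float)
    if np.any((vals < 0) | (vals > 1)):
        raise ValueError("beta values must lie in [0, 1]")
    normal_ids = [s for s in normal_ids if s in beta.columns]
    if len(normal_ids) < 2:
        raise ValueError("need at least two normal samples for the baseline")
    ranks = rank_transform(beta)
    baseline = estimate_baseline(ranks[normal_ids], gamma)
    tumor_cols = [c for c in beta.columns if c not in set(normal_ids)]
    return encode_divergence(ranks[tumor_cols], baseline)


def joint_divergence_proportion(expr_ternary: pd.DataFrame,
                                meth_ternary: pd.DataFrame,
                                cpg_map: pd.DataFrame,
                                genes: list[str] | None = None,
                                signed: bool = False) -> pd.DataFrame:
    """Per-CpG fraction of shared tumor samples divergent in both spaces.

    By default "divergent" is any nonzero code in both the CpG and its
    mapped gene; with ``signed=True`` only sign-concordant double
    divergence counts.  CpGs whose gene is absent from the expression
    coding are skipped with a warning.  Output rows are ordered by
    (chrom, pos) and carry the promoter flag.
    """
    cpg_map = _check_cpg_map(cpg_map)
    shared = [s for s in meth_ternary.columns if s in set(expr_ternary.columns)]
    if not shared:
        raise ValueError("no shared tumor samples between expression and methylation")
    if genes is not None:
        cpg_map = cpg_map[cpg_map["gene"].isin(set(genes))]
    records = []
    skipped = 0
    for cpg, row in cpg_map.iterrows():
        gene = row["gene"]
        if cpg not in meth_ternary.index or gene not in expr_ternary.index:
            skipped += 1
            continue
        e = expr_ternary.loc[gene, shared].to_numpy(dtype=int)
        m = meth_ternary.loc[cpg, shared].to_numpy(dtype=int)
        if signed:
            both = (e != 0) & (m != 0) & (np.sign(e) == np.sign(m))
        else:
            both = (e != 0) & (m != 0)
        records.append((cpg, gene, bool(row["promoter"]), row["chrom"],
                        int(row["pos"]), float(both.mean()),
                        float((e != 0).mean()), float((m != 0).mean())))
    if skipped:
        warnings.warn(f"skipped {skipped} CpGs with unmapped gene or missing data")
    out = pd.DataFrame(records, columns=[
        "cpg", "gene", "promoter", "chrom", "pos", "joint_proportion",
        "expr_proportion", "meth_proportion"]).set_index("cpg")
    return out.sort_values(["chrom", "pos"])


def expr_meth_correlation(expression: pd.DataFrame, beta: pd.DataFrame,
                          cpg_map: pd.DataFrame,
                          groups: pd.Series | None = None) -> pd.DataFrame:
    """Spearman correlation of each CpG's betas with its gene's expression.

    Computed over shared samples, separately per phenotype group when
    ``groups`` is given (otherwise one "all" group).  Constant vectors
    yield NaN with a warning (from :func:`metapersona.drugs.spearman`).
    """
    cpg_map = _check_cpg_map(cpg_map)
    shared = [s for s in beta.columns if s in set(expression.columns)]
    if len(shared) < 3:
        raise ValueError("need at least three shared samples")
    if groups is None:
        groups = pd.Series("all", index=shared)
    groups = groups.reindex(shared)
    records = []
    for g in groups.dropna().unique():
        cols = [s for s in shared if groups[s] == g]
        if len(cols) < 3:
            continue
        for cpg, row in cpg_map.iterrows():
            gene = row["gene"]
            if cpg not in beta.index or gene not in expression.index:
                continue
            rho, p = spearman(beta.loc[cpg, cols].to_numpy(),
                              expression.loc[gene, cols].to_numpy())
            records.append((cpg, gene, g, rho, p, len(cols)))
    return pd.DataFrame(records, columns=["cpg", "gene", "group", "rho", "p", "n"])
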