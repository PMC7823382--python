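"""Drug-association scoring of per-sample essential gene sets against a
cell-line mutation x drug-IC50 screen.

For each patient sample, the sample's essential gene set is turned into a
binary "hit" vector over screen cell lines (1 iff the line carries a
protein-changing mutation in at least one essential gene).  The hit vector
is Spearman-correlated with each drug's IC50 values across cell lines; a
negative rho means mutated lines are more sensitive (lower IC50).  Drugs
are ranked by the number of samples whose correlation p-value falls below
an uncorrected alpha (default 1e-3).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.stats import rankdata

__all__ = [
    "DrugScreen",
    "DrugScoreTable",
    "mutation_hit_vector",
    "spearman",
    "drug_association",
]


@dataclass
class DrugScreen:
    """Paired screen matrices sharing a cell-line index.

    mutation : cell lines x genes, binary (protein-changing mutation calls)
    ic50     : cell lines x drugs, real (any monotone scale; NaN = untested)
    """

    mutation: pd.DataFrame
    ic50: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.mutation.index.equals(self.ic50.index):
            raise ValueError("mutation and ic50 must share the cell-line index")
        vals = self.mutation.to_numpy()
        if not np.isin(vals, (0, 1)).all():
            raise ValueError("mutation matrix must be binary")

    def restrict(self, cell_lines) -> "DrugScreen":
        keep = [c for c in cell_lines if c in self.mutation.index]
        return DrugScreen(self.mutation.loc[keep], self.ic50.loc[keep])


@dataclass
class DrugScoreTable:
    per_sample: pd.DataFrame  # long: sample, drug, rho, p, n
    ranking: pd.DataFrame  # per drug: n_significant_samples, median_rho, rank
    alpha: float


def mutation_hit_vector(essential_genes: set[str], screen: DrugScreen) -> pd.Series:
    """Binary vector over cell lines: 1 iff the line has >= 1 mutated gene
    from the essential set (any-hit rule; monotone in the gene set)."""
    genes = [g for g in essential_genes if g in screen.mutation.columns]
    if essential_genes and not genes:
        warnings.warn("essential gene set has no overlap with screen genes")
    if not genes:
        return pd.Series(0, index=screen.mutation.index, dtype=np.int8)
    hits = (screen.mutation[genes].to_numpy().sum(axis=1) > 0).astype(np.int8)
    return pd.Series(hits, index=screen.mutation.index)


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation with two-sided p.

    rho is the Pearson correlation of tie-averaged ranks.  For n <= 8 the
    p-value is exact (full enumeration of pairings, valid under ties);
    otherwise the t approximation is used.  Zero variance in either vector
    leaves rho undefined (NaN, with a warning).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have the same length")
    n = x.size
    if n < 3 or np.all(x == x[0]) or np.all(y == y[0]):
        warnings.warn("Spearman undefined: fewer than 3 pairs or zero variance")
        return float("nan"), float("nan")
    rx = rankdata(x)
    ry = rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if n <= 8:
        # exact permutation distribution of rho (handles ties correctly)
        rx_c = rx - rx.mean()
        ry_c = ry - ry.mean()
        denom = np.sqrt((rx_c ** 2).sum() * (ry_c ** 2).sum())
        obs = abs(rho)
        count = 0
        total = 0
        for perm in itertools.permutations(range(n)):
            r = float(rx_c @ ry_c[list(perm)]) / denom
            if abs(r) >= obs - 1e-12:
                count += 1
            total += 1
        return rho, count / total
    res = sps.spearmanr(x, y)
    return rho, float(res.pvalue)


def drug_association(essential_sets: dict[str, set[str]], screen: DrugScreen,
                     alpha: float = 1e-3,
                     cell_lines: list[str] | None = None) -> DrugScoreTable:
    """Score every (sample, drug) pair and rank drugs.

    For each sample the mutation hit vector is Spearman-correlated with
    each drug's IC50s over pairwise-complete cell lines.  Per drug, the
    count of samples with p < ``alpha`` (uncorrected) drives the ranking;
    ties are broken by median |rho| then drug id.  ``cell_lines`` optionally
    restricts the screen to a cohort (e.g. BRCA lines only).
    """
    if not essential_sets:
        raise ValueError("need at least one sample")
    if cell_lines is not None:
        screen = screen.restrict(cell_lines)
    if screen.mutation.shape[0] == 0:
        raise ValueError("no overlapping cell lines after restriction")
    drugs = list(screen.ic50.columns)
    ic50 = screen.ic50.to_numpy(dtype=float)
    records = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for sample, genes in essential_sets.items():
            hits = mutation_hit_vector(genes, screen).to_numpy(dtype=float)
            for d, drug in enumerate(drugs):
                yv = ic50[:, d]
                ok = np.isfinite(yv)
                rho, p = spearman(hits[ok], yv[ok]) if ok.sum() >= 3 else (np.nan, np.nan)
                records.append((sample, drug, rho, p, int(ok.sum())))
    per_sample = pd.DataFrame(records, columns=["sample", "drug", "rho", "p", "n"])
    sig = per_sample[per_sample["p"] < alpha]
    n_sig = sig.groupby("drug").size().reindex(drugs, fill_value=0)
    med_rho = (per_sample.assign(abs_rho=per_sample["rho"].abs())
               .groupby("drug")["abs_rho"].median().reindex(drugs))
    ranking = pd.DataFrame({
        "n_significant_samples": n_sig.astype(int),
        "median_abs_rho": med_rho,
    })
    ranking["median_rho"] = per_sample.groupby("drug")["rho"].median().reindex(drugs)
    ranking = ranking.sort_values(
        by=["n_significant_samples", "median_abs_rho"],
        ascending=[False, False],
        kind="mergesort",
    )
    ranking = ranking.loc[
        ranking.reset_index()
        .sort_values(["n_significant_samples", "median_abs_rho", "drug"],
                     ascending=[False, False, True], kind="mergesort")["drug"]
    ]
    ranking["rank"] = np.arange(1, len(ranking) + 1)
    ranking.index.name = "drug"
    return DrugScoreTable(per_sample=per_sample, ranking=ranking, alpha=alpha)
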