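"""Univariate divergence coding of omics profiles.

Each sample profile (one column of a features x samples matrix) is replaced
by within-profile normalized ranks, a per-feature baseline interval is
estimated from a reference population of normal samples, and every value is
coded ternary: +1 above the baseline interval, -1 below it, 0 inside.  The
coding is a single-sample property — unlike a differential-expression call
it needs no tumor cohort — and depends only on within-sample ranks, so it is
invariant to any monotone per-sample transform (library-size scaling, log).

The baseline interval for a feature is the central ``gamma`` quantile
interval of the reference samples' rank values; ``gamma`` (default 0.9) is
the fraction of reference mass the baseline is meant to cover.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = [
    "BaselineRegions",
    "rank_transform",
    "split_reference",
    "estimate_baseline",
    "encode_divergence",
    "divergence_pipeline",
]


@dataclass
class BaselineRegions:
    """Per-feature rank-space baseline interval [lower, upper]."""

    lower: pd.Series
    upper: pd.Series
    gamma: float
    reference_ids: list[str]

    def __post_init__(self) -> None:
        if not self.lower.index.equals(self.upper.index):
            raise ValueError("lower/upper indices differ")
        if np.any(self.lower.values > self.upper.values):
            raise ValueError("baseline lower exceeds upper")


def rank_transform(matrix: pd.DataFrame) -> pd.DataFrame:
    """Within-sample normalized average ranks, values in (0, 1].

    Each column's entries are replaced by their average rank within the
    column (ties share the mean rank) divided by the number of features.
    """
    if matrix.shape[0] < 1:
        raise ValueError("need at least one feature")
    values = matrix.to_numpy(dtype=float)
    if np.any(values < 0):
        raise ValueError("expression values must be nonnegative")
    ranks = rankdata(values, method="average", axis=0) / matrix.shape[0]
    return pd.DataFrame(ranks, index=matrix.index, columns=matrix.columns)


def split_reference(normal_sample_ids: list[str], seed: int) -> tuple[list[str], list[str]]:
    """Split normal samples into a baseline reference half and a held-out half.

    With an odd count the reference gets the extra sample.  Deterministic
    given ``seed``.
    """
    ids = list(normal_sample_ids)
    if len(ids) < 2:
        raise ValueError("need at least two normal samples to split")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(ids))
    n_ref = (len(ids) + 1) // 2
    reference = [ids[i] for i in sorted(order[:n_ref])]
    heldout = [ids[i] for i in sorted(order[n_ref:])]
    return reference, heldout


def estimate_baseline(reference: pd.DataFrame, gamma: float = 0.9) -> BaselineRegions:
    """Central ``gamma`` empirical quantile interval per feature.

    ``reference`` is a rank-transformed features x reference-samples matrix;
    the interval is [q_{(1-gamma)/2}, q_{1-(1-gamma)/2}] of each feature's
    reference values, so gamma=1 gives the full observed range.
    """
    if reference.shape[1] < 2:
        raise ValueError("need at least two reference samples")
    if not (0 < gamma <= 1):
        raise ValueError("gamma must be in (0, 1]")
    alpha = (1.0 - gamma) / 2.0
    vals = reference.to_numpy(dtype=float)
    lower = np.quantile(vals, alpha, axis=1)
    upper = np.quantile(vals, 1.0 - alpha, axis=1)
    return BaselineRegions(
        lower=pd.Series(lower, index=reference.index),
        upper=pd.Series(upper, index=reference.index),
        gamma=gamma,
        reference_ids=list(reference.columns),
    )


def encode_divergence(data: pd.DataFrame, baseline: BaselineRegions) -> pd.DataFrame:
    """Ternary code: +1 above the baseline interval, -1 below, 0 inside.

    Boundary values are inside (the interval is closed).  ``data`` must be
    rank-transformed and share the baseline's feature index.
    """
    if not data.index.equals(baseline.lower.index):
        raise ValueError("feature index mismatch between data and baseline")
    vals = data.to_numpy(dtype=float)
    lo = baseline.lower.to_numpy()[:, None]
    hi = baseline.upper.to_numpy()[:, None]
    codes = np.zeros(vals.shape, dtype=np.int8)
    codes[vals > hi] = 1
    codes[vals < lo] = -1
    return pd.DataFrame(codes, index=data.index, columns=data.columns)


def divergence_pipeline(expression: pd.DataFrame, normal_ids: list[str],
                        gamma: float = 0.9, seed: int = 0,
                        ) -> tuple[pd.DataFrame, BaselineRegions, list[str]]:
    """Full coding workflow: rank-transform, split normals, estimate the
    baseline on the reference half, and code every non-reference sample.

    Returns (ternary matrix over non-reference samples, baseline, heldout
    normal ids).
    """
    normal_ids = [s for s in normal_ids if s in expression.columns]
    ranks = rank_transform(expression)
    reference, heldout = split_reference(normal_ids, seed)
    baseline = estimate_baseline(ranks[reference], gamma)
    rest = [c for c in expression.columns if c not in set(reference)]
    ternary = encode_divergence(ranks[rest], baseline)
    return ternary, baseline, heldout
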