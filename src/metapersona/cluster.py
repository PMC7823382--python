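"""Flux-profile clustering and survival contrasts.

Cancer samples are clustered on their context networks' FVA maximum-flux
profiles (samples x reactions, over the full model's reaction index so
columns are comparable).  K-means runs on per-reaction z-scored profiles
with k-means++ initialization and multiple restarts; the 1 - Pearson
correlation distance matrix is computed for diagnostics and an optional
classical-MDS embedding mode.  The number of clusters is guided by the
within-cluster sum-of-squares (wss) elbow; survival differences between
cluster groupings are summarized with Kaplan-Meier product-limit curves.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

__all__ = [
    "ClusterAssignment",
    "pearson_distance",
    "kmeans_cluster",
    "elbow_wss",
    "knee_by_second_difference",
    "pca_embed",
    "kaplan_meier",
    "merge_clusters",
]

NORMAL_CLUSTER = 0


@dataclass
class ClusterAssignment:
    labels: pd.Series  # sample -> cluster (0 reserved for normals)
    k: int
    wss: float
    seed: int


def _zscore(profiles: pd.DataFrame) -> np.ndarray:
    vals = profiles.to_numpy(dtype=float)
    mu = vals.mean(axis=0)
    sd = vals.std(axis=0)
    sd[sd == 0] = 1.0  # constant reactions carry no signal either way
    return (vals - mu) / sd


def pearson_distance(profiles: pd.DataFrame) -> pd.DataFrame:
    """Sample x sample distance ``1 - r`` on flux profiles (samples as rows).

    Constant profiles correlate with nothing; their off-diagonal distances
    are set to 1 with a warning.
    """
    vals = profiles.to_numpy(dtype=float)
    if profiles.shape[0] < 2:
        raise ValueError("need at least two samples")
    if not np.all(np.isfinite(vals)):
        raise ValueError("flux profiles contain non-finite entries")
    sd = vals.std(axis=1)
    flat = sd == 0
    if flat.any():
        warnings.warn(f"{int(flat.sum())} constant profiles; distance set to 1")
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(vals)
    d = 1.0 - r
    d[np.isnan(d)] = 1.0
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2.0
    return pd.DataFrame(d, index=profiles.index, columns=profiles.index)


def kmeans_cluster(profiles: pd.DataFrame, k: int, seed: int = 0,
                   n_init: int = 25, standardize: bool = True,
                   mode: str = "euclidean") -> ClusterAssignment:
    """K-means on flux profiles; labels are 1..k (0 is reserved for normals).

    ``mode="euclidean"`` (default) clusters z-scored profiles directly;
    ``mode="pearson-mds"`` first embeds the 1 - Pearson distance matrix by
    classical multidimensional scaling, then clusters the embedding.
    Labels are identifiable only up to permutation.
    """
    if not (1 <= k <= profiles.shape[0]):
        raise ValueError("require 1 <= k <= number of samples")
    if mode == "euclidean":
        X = _zscore(profiles) if standardize else profiles.to_numpy(dtype=float)
    elif mode == "pearson-mds":
        X = _classical_mds(pearson_distance(profiles).to_numpy())
    else:
        raise ValueError(f"unknown mode {mode!r}")
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    labels = km.fit_predict(X) + 1
    return ClusterAssignment(
        labels=pd.Series(labels, index=profiles.index, name="cluster"),
        k=k, wss=float(km.inertia_), seed=seed)


def _classical_mds(d: np.ndarray, n_components: int = 10) -> np.ndarray:
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d ** 2) @ j
    w, v = np.linalg.eigh(b)
    order = np.argsort(w)[::-1][:min(n_components, n)]
    w = np.clip(w[order], 0, None)
    return v[:, order] * np.sqrt(w)


def elbow_wss(profiles: pd.DataFrame, k_range=range(1, 9), seed: int = 0,
              n_init: int = 25, standardize: bool = True) -> pd.Series:
    """Best-of-restarts wss for each candidate k (non-increasing in k)."""
    ks = list(k_range)
    if not ks:
        raise ValueError("empty k range")
    wss = {}
    for k in ks:
        wss[k] = kmeans_cluster(profiles, k, seed=seed, n_init=n_init,
                                standardize=standardize).wss
    out = pd.Series(wss, name="wss")
    out.index.name = "k"
    return out


def knee_by_second_difference(wss: pd.Series) -> int:
    """Elbow heuristic: the k maximizing the discrete second difference
    wss(k-1) - 2 wss(k) + wss(k+1) over interior candidates."""
    if len(wss) < 3:
        raise ValueError("need at least three k values for a knee")
    ks = list(wss.index)
    vals = wss.to_numpy()
    second = vals[:-2] - 2 * vals[1:-1] + vals[2:]
    return int(ks[1 + int(np.argmax(second))])


def pca_embed(matrix: pd.DataFrame, n_components: int = 2) -> tuple[pd.DataFrame, np.ndarray]:
    """Centered-SVD principal component scores (samples as rows).

    Component signs follow the convention that each component's
    largest-magnitude loading is positive.  Returns (scores, explained
    variance ratio).
    """
    if matrix.shape[0] < 2:
        raise ValueError("need at least two samples")
    n_components = min(n_components, matrix.shape[0] - 1, matrix.shape[1])
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(matrix.to_numpy(dtype=float))
    for c in range(scores.shape[1]):
        load = pca.components_[c]
        if load[np.argmax(np.abs(load))] < 0:
            scores[:, c] *= -1
    cols = [f"PC{i + 1}" for i in range(scores.shape[1])]
    return (pd.DataFrame(scores, index=matrix.index, columns=cols),
            pca.explained_variance_ratio_)


def kaplan_meier(survival: pd.DataFrame, groups: pd.Series) -> pd.DataFrame:
    """Product-limit survival curves per group.

    ``survival`` has columns ``time`` (>= 0) and ``event`` (1 event, 0
    censored); ``groups`` maps sample -> group label.  Returns a long frame
    (group, time, survival, at_risk) with one row per distinct event or
    censoring time, including the S(0) = 1 anchor.
    """
    if np.any(survival["time"].to_numpy() < 0):
        raise ValueError("negative survival times")
    groups = groups.reindex(survival.index)
    frames = []
    for g, idx in groups.groupby(groups).groups.items():
        sub = survival.loc[idx]
        if sub.empty:
            continue
        kmf = KaplanMeierFitter()
        kmf.fit(sub["time"], event_observed=sub["event"])
        surv = kmf.survival_function_.iloc[:, 0]
        at_risk = kmf.event_table["at_risk"].reindex(surv.index)
        frames.append(pd.DataFrame({
            "group": g,
            "time": surv.index.to_numpy(dtype=float),
            "survival": surv.to_numpy(dtype=float),
            "at_risk": at_risk.to_numpy(dtype=float),
        }))
    return pd.concat(frames, ignore_index=True)


def merge_clusters(labels: pd.Series, merge_map: dict) -> pd.Series:
    """Relabel clusters by a merge map, e.g. {1: "A", 4: "A", 2: "B", 3: "B"}.

    Every observed label must be covered.
    """
    observed = set(labels.unique())
    uncovered = observed - set(merge_map)
    if uncovered:
        raise ValueError(f"merge map does not cover labels {sorted(uncovered)}")
    return labels.map(merge_map).rename(labels.name)
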