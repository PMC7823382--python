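"""Clustering, elbow selection, PCA, Kaplan-Meier, and cluster merging."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from metapersona import (elbow_wss, kaplan_meier, kmeans_cluster,
                         knee_by_second_difference, merge_clusters, pca_embed,
                         pearson_distance)
from oracles import km_product_limit


def blobs(n_per=20, k=4, sep=10.0, d=12, seed=0):
    rng = np.random.default_rng(seed)
    rows, labels = [], []
    for c in range(k):
        center = np.zeros(d)
        center[c % d] = sep * (c + 1)
        rows.append(center + rng.standard_normal((n_per, d)))
        labels += [c] * n_per
    X = np.vstack(rows)
    idx = [f"s{i}" for i in range(len(X))]
    return pd.DataFrame(X, index=idx), np.array(labels)


class TestPearsonDistance:
    def test_identical_profiles_distance_zero(self):
        prof = pd.DataFrame([[1, 2, 3], [1, 2, 3]], index=["a", "b"])
        d = pearson_distance(prof)
        assert d.loc["a", "b"] == pytest.approx(0.0)

    def test_anticorrelated_distance_two(self):
        prof = pd.DataFrame([[1, 2, 3], [3, 2, 1]], index=["a", "b"])
        assert pearson_distance(prof).loc["a", "b"] == pytest.approx(2.0)

    def test_matches_brute_force_formula(self):
        rng = np.random.default_rng(4)
        prof = pd.DataFrame(rng.random((5, 10)))
        d = pearson_distance(prof)
        for i in range(5):
            for j in range(5):
                x, y = prof.iloc[i], prof.iloc[j]
                r = np.sum((x - x.mean()) * (y - y.mean())) / (
                    np.sqrt(np.sum((x - x.mean()) ** 2))
                    * np.sqrt(np.sum((y - y.mean()) ** 2)))
                assert d.iloc[i, j] == pytest.approx(1 - r, abs=1e-10)

    def test_constant_profile_warns(self):
        prof = pd.DataFrame([[1.0, 1.0, 1.0], [1, 2, 3]], index=["flat", "b"])
        with pytest.warns(UserWarning, match="constant"):
            d = pearson_distance(prof)
        assert d.loc["flat", "b"] == 1.0


class TestKmeans:
    def test_separated_blobs_recovered(self):
        prof, truth = blobs(sep=10.0, seed=1)
        out = kmeans_cluster(prof, 4, seed=0)
        assert adjusted_rand_score(truth, out.labels.to_numpy()) == 1.0

    def test_k_equal_samples_zero_wss(self):
        prof, _ = blobs(n_per=2, k=2)
        out = kmeans_cluster(prof, prof.shape[0], seed=0, n_init=1)
        assert out.wss == pytest.approx(0.0, abs=1e-9)

    def test_same_seed_identical_labels(self):
        prof, _ = blobs(seed=2)
        a = kmeans_cluster(prof, 4, seed=9)
        b = kmeans_cluster(prof, 4, seed=9)
        assert a.labels.equals(b.labels)

    def test_k_larger_than_samples_rejected(self):
        prof, _ = blobs(n_per=2, k=2)
        with pytest.raises(ValueError):
            kmeans_cluster(prof, prof.shape[0] + 1, seed=0)

    def test_pearson_mds_mode_also_recovers(self):
        prof, truth = blobs(sep=10.0, seed=3)
        out = kmeans_cluster(prof, 4, seed=0, mode="pearson-mds")
        assert adjusted_rand_score(truth, out.labels.to_numpy()) > 0.9


class TestElbow:
    def test_wss_monotone_and_knee_at_planted_k(self):
        prof, _ = blobs(n_per=25, k=4, sep=12.0, seed=5)
        wss = elbow_wss(prof, range(1, 9), seed=0)
        vals = wss.to_numpy()
        assert np.all(np.diff(vals) <= 1e-6)
        assert knee_by_second_difference(wss) == 4

    def test_k1_wss_is_total_sum_of_squares(self):
        prof, _ = blobs(n_per=10, k=2, seed=6)
        wss = elbow_wss(prof, [1], seed=0, standardize=False)
        X = prof.to_numpy()
        tss = np.sum((X - X.mean(axis=0)) ** 2)
        assert wss[1] == pytest.approx(tss, rel=1e-9)


class TestPca:
    def test_rank_one_data_pc1_explains_everything(self):
        u = np.arange(6, dtype=float)[:, None]
        v = np.array([[1.0, -2.0, 0.5]])
        prof = pd.DataFrame(u @ v)
        _, evr = pca_embed(prof, n_components=2)
        assert evr[0] == pytest.approx(1.0, abs=1e-9)

    def test_two_group_separation_on_pc1(self):
        prof, truth = blobs(n_per=15, k=2, sep=20.0, seed=7)
        scores, _ = pca_embed(prof, n_components=2)
        pc1 = scores["PC1"].to_numpy()
        assert (pc1[truth == 0].max() < pc1[truth == 1].min()) or \
               (pc1[truth == 1].max() < pc1[truth == 0].min())


class TestKaplanMeier:
    def test_hand_product_limit(self):
        surv = pd.DataFrame({"time": [1.0, 2.0, 3.0], "event": [1, 1, 0]},
                            index=["a", "b", "c"])
        groups = pd.Series("g", index=surv.index)
        km = kaplan_meier(surv, groups)
        by_time = km.set_index("time")["survival"]
        assert by_time[1.0] == pytest.approx(2 / 3)
        assert by_time[2.0] == pytest.approx(1 / 3)
        assert by_time[3.0] == pytest.approx(1 / 3)  # censoring: no drop

    def test_no_events_flat_curve(self):
        surv = pd.DataFrame({"time": [5.0, 8.0], "event": [0, 0]},
                            index=["a", "b"])
        km = kaplan_meier(surv, pd.Series("g", index=surv.index))
        assert (km["survival"] == 1.0).all()

    def test_no_censoring_matches_empirical_survivor(self):
        """Without censoring the KM estimate is 1 - ECDF, checked against the
        hand product-limit oracle on random data."""
        rng = np.random.default_rng(8)
        for _ in range(5):
            times = rng.integers(1, 15, size=10).astype(float)
            surv = pd.DataFrame({"time": times, "event": 1},
                                index=[f"s{i}" for i in range(10)])
            km = kaplan_meier(surv, pd.Series("g", index=surv.index))
            oracle = dict(km_product_limit(times, np.ones(10, int)))
            for t, s in oracle.items():
                got = km.loc[km["time"] == t, "survival"].iloc[0]
                assert got == pytest.approx(s, abs=1e-10)
                ecdf = np.mean(times <= t)
                assert got == pytest.approx(1 - ecdf, abs=1e-10)

    def test_negative_times_rejected(self):
        surv = pd.DataFrame({"time": [-1.0], "event": [1]}, index=["a"])
        with pytest.raises(ValueError, match="negative"):
            kaplan_meier(surv, pd.Series("g", index=surv.index))


class TestMergeClusters:
    def test_pairwise_merge(self):
        labels = pd.Series([1, 2, 3, 4], index=list("abcd"))
        merged = merge_clusters(labels, {1: "A", 4: "A", 2: "B", 3: "B"})
        assert merged.tolist() == ["A", "B", "B", "A"]

    def test_identity_map(self):
        labels = pd.Series([1, 2], index=["a", "b"])
        assert merge_clusters(labels, {1: 1, 2: 2}).tolist() == [1, 2]

    def test_uncovered_label_rejected(self):
        labels = pd.Series([1, 2], index=["a", "b"])
        with pytest.raises(ValueError, match="cover"):
            merge_clusters(labels, {1: "A"})

    def test_merged_km_risk_sets_union(self):
        """KM on a merged group equals KM computed on the pooled samples."""
        rng = np.random.default_rng(9)
        times = rng.exponential(100, size=20)
        events = rng.integers(0, 2, size=20)
        idx = [f"s{i}" for i in range(20)]
        surv = pd.DataFrame({"time": times, "event": events}, index=idx)
        labels = pd.Series([1, 2] * 10, index=idx)
        merged = merge_clusters(labels, {1: "A", 2: "A"})
        km_merged = kaplan_meier(surv, merged)
        km_pooled = kaplan_meier(surv, pd.Series("A", index=idx))
        pd.testing.assert_frame_equal(km_merged, km_pooled)
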