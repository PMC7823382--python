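"""Statistics against combinatorial oracles: Fisher, BH-FDR, Wilcoxon,
chi-squared, and the activity-comparison wrappers."""

import numpy as np
import pandas as pd
import pytest

from metapersona import (bh_fdr, chi_squared, differential_reactions,
                         fisher_exact, subsystem_enrichment,
                         wilcoxon_rank_sum)
from metapersona.stats import essentiality_comparison
from oracles import bh_stepup, fisher_exact_enumeration, wilcoxon_exact_p


class TestFisher:
    def test_balanced_table_p_one(self):
        _, p = fisher_exact([[2, 2], [2, 2]])
        assert p == pytest.approx(1.0)

    def test_perfect_split_5v5(self):
        odds, p = fisher_exact([[5, 0], [0, 5]])
        assert p == pytest.approx(2 / 252, abs=1e-12)
        assert odds == np.inf

    def test_degenerate_all_zero(self):
        odds, p = fisher_exact([[0, 0], [0, 0]])
        assert p == 1.0 and np.isnan(odds)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact([[1, -1], [0, 2]])

    def test_matches_hypergeometric_enumeration(self):
        """Two-sided p equals direct enumeration of same-margin tables for
        all totals up to 30."""
        rng = np.random.default_rng(0)
        for _ in range(60):
            t = rng.integers(0, 8, size=(2, 2))
            if t.sum() == 0 or t.sum() > 30:
                continue
            _, p = fisher_exact(t)
            assert p == pytest.approx(fisher_exact_enumeration(t), abs=1e-10)


class TestBhFdr:
    def test_hand_step_up(self):
        q = bh_fdr([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert bh_fdr([0.37])[0] == pytest.approx(0.37)

    def test_identical_ps_unchanged(self):
        assert np.allclose(bh_fdr([0.2, 0.2, 0.2]), 0.2)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.5])

    def test_matches_brute_force_definition(self):
        rng = np.random.default_rng(1)
        for size in (1, 2, 10, 100):
            p = rng.random(size)
            assert np.allclose(bh_fdr(p), bh_stepup(p), atol=1e-12)


class TestWilcoxon:
    def test_separated_triples_exact(self):
        u, p = wilcoxon_rank_sum([1, 2, 3], [4, 5, 6])
        assert u == pytest.approx(0.0)
        assert p == pytest.approx(0.1, abs=1e-12)

    def test_identical_samples_p_one(self):
        _, p = wilcoxon_rank_sum([2.0, 2.0], [2.0, 2.0])
        assert p == 1.0

    def test_symmetric_in_arguments(self):
        _, p1 = wilcoxon_rank_sum([1, 5, 9], [2, 3, 8])
        _, p2 = wilcoxon_rank_sum([2, 3, 8], [1, 5, 9])
        assert p1 == pytest.approx(p2)

    def test_matches_enumeration_small_samples(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            x = rng.permutation(20)[:4].astype(float)
            y = rng.permutation(np.arange(20, 40))[:4].astype(float)
            _, p = wilcoxon_rank_sum(x, y)
            assert p == pytest.approx(wilcoxon_exact_p(x, y), abs=1e-10)


class TestChiSquared:
    def test_uniform_table(self):
        stat, p = chi_squared([[10, 10], [10, 10]])
        assert stat == pytest.approx(0.0) and p == pytest.approx(1.0)

    def test_diagonal_table_hand_value(self):
        stat, _ = chi_squared([[20, 0], [0, 20]])
        assert stat == pytest.approx(40.0)

    def test_row_order_invariant(self):
        s1, p1 = chi_squared([[5, 10], [12, 3]])
        s2, p2 = chi_squared([[12, 3], [5, 10]])
        assert s1 == pytest.approx(s2) and p1 == pytest.approx(p2)

    def test_zero_margin_dropped_with_warning(self):
        with pytest.warns(UserWarning, match="zero-margin"):
            stat, _ = chi_squared([[5, 10, 0], [12, 3, 0]])
        assert stat > 0


def activity_fixture():
    samples = [f"a{i}" for i in range(5)] + [f"b{i}" for i in range(5)]
    groups = pd.Series(["A"] * 5 + ["B"] * 5, index=samples)
    act = pd.DataFrame(0, index=["r_diff", "r_same", "r_flat"], columns=samples)
    act.loc["r_diff", groups == "A"] = 1  # active in all A, none of B
    act.loc["r_same"] = 1
    return act, groups


class TestDifferentialReactions:
    def test_fully_separated_reaction(self):
        act, groups = activity_fixture()
        out = differential_reactions(act, groups, "A", "B")
        assert out.loc["r_diff", "p"] == pytest.approx(2 / 252, abs=1e-10)
        assert out.loc["r_same", "p"] == pytest.approx(1.0)
        assert out.loc["r_flat", "p"] == pytest.approx(1.0)
        assert (out["q"] >= out["p"] - 1e-15).all()

    def test_missing_group_rejected(self):
        act, groups = activity_fixture()
        with pytest.raises(ValueError, match="empty group"):
            differential_reactions(act, groups, "A", "C")


class TestSubsystemEnrichment:
    def test_concentrated_subsystem_is_top(self):
        rng = np.random.default_rng(5)
        samples = [f"a{i}" for i in range(8)] + [f"b{i}" for i in range(8)]
        groups = pd.Series(["A"] * 8 + ["B"] * 8, index=samples)
        reactions = [f"r{i}" for i in range(20)]
        act = pd.DataFrame(rng.integers(0, 2, size=(20, 16)),
                           index=reactions, columns=samples)
        act.iloc[:5, :8] = 1  # first five reactions differential
        act.iloc[:5, 8:] = 0
        submap = pd.Series(["metab_X"] * 5 + ["metab_Y"] * 10 + ["metab_Z"] * 5,
                           index=reactions)
        diff = differential_reactions(act, groups, "A", "B")
        enr = subsystem_enrichment(diff, submap, p_threshold=0.05)
        assert enr.index[0] == "metab_X"
        assert enr["p"].iloc[0] < 0.05

    def test_no_differential_reactions_all_p_one(self):
        act, groups = activity_fixture()
        act.loc["r_diff"] = 1  # remove the signal
        diff = differential_reactions(act, groups, "A", "B")
        submap = pd.Series(["s1", "s1", "s2"], index=act.index)
        enr = subsystem_enrichment(diff, submap)
        assert (enr["p"] == 1.0).all()

    def test_empty_map_rejected(self):
        act, groups = activity_fixture()
        diff = differential_reactions(act, groups, "A", "B")
        with pytest.raises(ValueError, match="subsystem map"):
            subsystem_enrichment(diff, pd.Series(dtype=object))


class TestEssentialityComparison:
    def test_planted_essential_gene_detected(self):
        samples = [f"c{i}" for i in range(10)] + [f"n{i}" for i in range(10)]
        groups = pd.Series(["cancer"] * 10 + ["normal"] * 10, index=samples)
        gr = pd.DataFrame(1.0, index=["g_hit", "g_null"], columns=samples)
        gr.loc["g_hit", groups == "cancer"] = 0.1  # lethal only in cancer nets
        out = essentiality_comparison(gr, groups, "cancer", "normal")
        assert out.index[0] == "g_hit"
        assert out.loc["g_hit", "q"] < 0.05
        assert out.loc["g_null", "p"] == 1.0
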