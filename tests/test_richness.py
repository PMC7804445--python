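import numpy as np
import pandas as pd
import pytest

from soilbiome import CountMatrix, differential_richness_analysis, richness_matrix
from soilbiome.richness import (
    BalanceNode,
    BalanceTree,
    balance_tree,
    flag_differential_taxa,
    ilr_balances,
    ols_balance_test,
)


@pytest.fixture
def toy_taxonomy():
    return pd.DataFrame(
        {
            "phylum": ["P"] * 4,
            "class": ["C"] * 4,
            "order": ["O"] * 4,
            "family": ["F1", "F1", "F2", "F2"],
            "genus": ["g1", "g2", "g3", np.nan],
        },
        index=pd.Index(["spA", "spB", "spC", "spD"], name="species_id"),
    )


class TestRichnessMatrix:
    def test_counts_distinct_present_children(self, toy_taxonomy):
        cm = CountMatrix(pd.DataFrame([[5], [1], [0], [2]],
                                      index=["spA", "spB", "spC", "spD"], columns=["s1"]))
        r = richness_matrix(cm, toy_taxonomy, "family", "species")
        assert r.loc["F1", "s1"] == 2  # spA, spB present
        assert r.loc["F2", "s1"] == 1  # only spD

    def test_zero_family_gives_zero_richness(self, toy_taxonomy):
        cm = CountMatrix(pd.DataFrame([[5], [1], [0], [0]],
                                      index=["spA", "spB", "spC", "spD"], columns=["s1"]))
        r = richness_matrix(cm, toy_taxonomy, "family", "species")
        assert r.loc["F2", "s1"] == 0

    def test_species_missing_child_rank_excluded(self, toy_taxonomy):
        cm = CountMatrix(pd.DataFrame([[1], [1], [1], [1]],
                                      index=["spA", "spB", "spC", "spD"], columns=["s1"]))
        r = richness_matrix(cm, toy_taxonomy, "family", "genus")
        assert r.loc["F2", "s1"] == 1  # spD has no genus annotation

    def test_invalid_rank_order(self, toy_taxonomy, small_counts):
        with pytest.raises(ValueError, match="above"):
            richness_matrix(small_counts, toy_taxonomy, "species", "family")

    def test_matches_brute_force_on_tiny_fixture(self, tiny_bundle):
        counts, _, tax, *_ = tiny_bundle
        r = richness_matrix(counts, tax, "family", "species")
        for fam in r.index:
            members = tax.index[tax["family"] == fam]
            for s in counts.sample_ids:
                expected = int((counts.counts.loc[members, s] > 0).sum())
                assert r.loc[fam, s] == expected


class TestBalanceTree:
    def test_two_taxa_single_node(self):
        rich = pd.DataFrame([[1, 2], [3, 4]], index=["t1", "t2"], columns=["s1", "s2"])
        tree = balance_tree(rich)
        assert len(tree.nodes) == 1
        assert set(tree.nodes[0].left) | set(tree.nodes[0].right) == {"t1", "t2"}

    def test_identical_profiles_become_siblings(self):
        rich = pd.DataFrame(
            [[5, 5, 5], [5, 5, 5], [0, 9, 1]],
            index=["t1", "t2", "t3"], columns=["s1", "s2", "s3"],
        )
        tree = balance_tree(rich)
        # t1, t2 at distance 0 merge first: some node contrasts exactly {t1},{t2}
        sibling_nodes = [n for n in tree.nodes
                         if set(n.left) | set(n.right) == {"t1", "t2"}]
        assert len(sibling_nodes) == 1

    def test_taxon_permutation_gives_isomorphic_tree(self):
        rng = np.random.default_rng(0)
        rich = pd.DataFrame(rng.integers(0, 10, (6, 8)),
                            index=[f"t{i}" for i in range(6)],
                            columns=[f"s{j}" for j in range(8)])
        t1 = balance_tree(rich)
        t2 = balance_tree(rich.iloc[::-1])
        sets1 = {frozenset(n.left) | frozenset(n.right) for n in t1.nodes}
        sets2 = {frozenset(n.left) | frozenset(n.right) for n in t2.nodes}
        assert sets1 == sets2


class TestIlrBalances:
    def test_two_leaf_closed_form(self):
        rich = pd.DataFrame([[4], [1]], index=["t1", "t2"], columns=["s1"])
        tree = BalanceTree(taxa=["t1", "t2"],
                           nodes=[BalanceNode("y0", ("t1",), ("t2",))],
                           parent_of_leaf={"t1": "y0", "t2": "y0"})
        y = ilr_balances(rich, tree, pseudocount=1e-9).iloc[0, 0]
        assert y == pytest.approx(np.sqrt(0.5) * np.log(4), abs=1e-6)  # 0.9803

    def test_equal_leaves_give_zero_balances(self):
        rich = pd.DataFrame([[3], [3], [3], [3]],
                            index=list("abcd"), columns=["s1"])
        tree = balance_tree(rich + np.arange(4)[:, None] * 0)  # uniform
        y = ilr_balances(rich, tree, 0.5)
        assert np.allclose(y.to_numpy(), 0.0)

    def test_swapping_sides_flips_sign(self):
        rich = pd.DataFrame([[4, 2], [1, 7]], index=["t1", "t2"], columns=["s1", "s2"])
        n = BalanceNode("y0", ("t1",), ("t2",))
        flipped = BalanceNode("y0", ("t2",), ("t1",))
        tree = BalanceTree(["t1", "t2"], [n], {"t1": "y0", "t2": "y0"})
        tree_f = BalanceTree(["t1", "t2"], [flipped], {"t1": "y0", "t2": "y0"})
        np.testing.assert_allclose(ilr_balances(rich, tree, 0.5).to_numpy(),
                                   -ilr_balances(rich, tree_f, 0.5).to_numpy())

    def test_balances_are_orthonormal_contrasts(self):
        # sum of squared balances equals the squared ilr norm of the
        # centered log composition
        rng = np.random.default_rng(1)
        rich = pd.DataFrame(rng.integers(0, 12, (5, 6)),
                            index=[f"t{i}" for i in range(5)],
                            columns=[f"s{j}" for j in range(6)])
        tree = balance_tree(rich)
        y = ilr_balances(rich, tree, 0.5)
        logx = np.log(rich.to_numpy() + 0.5)
        clr = logx - logx.mean(axis=0, keepdims=True)
        np.testing.assert_allclose((y.to_numpy() ** 2).sum(axis=0),
                                   (clr ** 2).sum(axis=0), rtol=1e-9)


class TestOlsBalanceTest:
    def test_constant_balance_degenerate(self):
        balances = pd.DataFrame([[1.0, 1.0, 1.0, 1.0]], index=["y0"])
        res = ols_balance_test(balances, ["A", "A", "B", "B"])
        assert res.loc["y0", "degenerate"]
        assert res.loc["y0", "p"] == 1.0

    def test_matches_one_way_anova(self):
        from scipy import stats

        rng = np.random.default_rng(4)
        balances = pd.DataFrame(rng.normal(size=(3, 24)),
                                index=["y0", "y1", "y2"])
        groups = np.repeat(list("ABCD"), 6)
        res = ols_balance_test(balances, groups)
        for node in balances.index:
            v = balances.loc[node].to_numpy()
            f, p = stats.f_oneway(*(v[groups == g] for g in "ABCD"))
            assert res.loc[node, "F"] == pytest.approx(f)
            assert res.loc[node, "p"] == pytest.approx(p)


class TestFlagging:
    def _four_leaf_tree(self):
        # caterpillar: root separates d from {a, b, c}
        return BalanceTree(
            taxa=["a", "b", "c", "d"],
            nodes=[
                BalanceNode("y0", ("a", "b", "c"), ("d",)),
                BalanceNode("y1", ("a", "b"), ("c",)),
                BalanceNode("y2", ("a",), ("b",)),
            ],
            parent_of_leaf={"d": "y0", "c": "y1", "a": "y2", "b": "y2"},
        )

    def test_no_significant_balances_flags_nothing(self):
        tests = pd.DataFrame({"p": [0.5, 0.9, 0.2]}, index=["y0", "y1", "y2"])
        assert flag_differential_taxa(self._four_leaf_tree(), tests) == []

    def test_root_only_significant_flags_minority_side(self):
        tests = pd.DataFrame({"p": [1e-9, 0.9, 0.9]}, index=["y0", "y1", "y2"])
        assert flag_differential_taxa(self._four_leaf_tree(), tests, alpha=1e-6) == ["d"]

    def test_planted_family_recovered(self, default_bundle):
        counts, meta, tax, _, truth = default_bundle
        res = differential_richness_analysis(counts, tax, meta)
        shifted_family = tax.loc[truth.richness_shift[0]["species"][0], "family"]
        assert shifted_family in res["differential_taxa"]

    def test_pipeline_invariant_under_taxon_relabeling(self, tiny_bundle):
        counts, meta, tax, *_ = tiny_bundle
        res1 = differential_richness_analysis(counts, tax, meta, alpha=0.05)
        renamed = tax.copy()
        renamed["family"] = "X" + renamed["family"]
        res2 = differential_richness_analysis(counts, renamed, meta, alpha=0.05)
        assert sorted("X" + t for t in res1["differential_taxa"]) == sorted(
            res2["differential_taxa"]
        )
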