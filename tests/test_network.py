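from itertools import combinations

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from soilbiome import CountMatrix, mine_pair_rules, top_k_transactions
from soilbiome.network import (
    AssociationRulePair,
    build_network,
    classify_roles,
    girvan_newman_communities,
    minimum_spanning_forest,
    node_betweenness,
    rules_to_graph,
)


def brute_force_pair_rules(transactions, min_support, min_confidence):
    """Exhaustive enumeration over all item pairs (oracle, no pruning)."""
    n = len(transactions)
    items = sorted({i for t in transactions for i in t})
    out = set()
    for a, b in combinations(items, 2):
        n_ab = sum(1 for t in transactions if a in t and b in t)
        n_a = sum(1 for t in transactions if a in t)
        n_b = sum(1 for t in transactions if b in t)
        support = n_ab / n
        if n_ab == 0:
            continue
        confidence = max(n_ab / n_a, n_ab / n_b)
        if support > min_support and confidence > min_confidence:
            out.add((a, b, support, confidence))
    return out


def brute_force_min_forest_weight(graph):
    """Minimum spanning-forest weight by exhaustive search (<= 6 nodes)."""
    edges = list(graph.edges(data="weight"))
    n_needed = graph.number_of_nodes() - nx.number_connected_components(graph)
    best = np.inf
    for subset in combinations(edges, n_needed):
        g = nx.Graph()
        g.add_nodes_from(graph.nodes)
        g.add_weighted_edges_from(subset)
        if nx.number_connected_components(g) == nx.number_connected_components(graph):
            best = min(best, sum(w for *_, w in subset))
    return best if n_needed else 0.0


def brute_force_node_betweenness(tree):
    """Count unique tree paths through each internal node."""
    counts = {n: 0 for n in tree.nodes}
    nodes = sorted(tree.nodes)
    for a, b in combinations(nodes, 2):
        if nx.has_path(tree, a, b):
            path = nx.shortest_path(tree, a, b)
            for v in path[1:-1]:
                counts[v] += 1
    return counts


class TestTransactions:
    def _matrix(self, data, samples):
        return CountMatrix(pd.DataFrame(
            data, index=[f"sp{i:02d}" for i in range(len(data))], columns=samples))

    def test_top_k_selected_from_larger_sample(self):
        rng = np.random.default_rng(0)
        col = rng.permutation(np.arange(1, 26))  # 25 distinct nonzero counts
        cm = self._matrix(col[:, None], ["s1"])
        meta = pd.DataFrame({"group": ["A"]}, index=["s1"])
        (t,) = top_k_transactions(cm, meta, k=20)["A"]
        assert len(t) == 20
        kept = {f"sp{i:02d}" for i in np.argsort(col)[-20:]}
        assert t == kept

    def test_small_sample_contributes_all_nonzero(self):
        col = np.r_[np.arange(1, 13), np.zeros(13)]
        cm = self._matrix(col[:, None], ["s1"])
        meta = pd.DataFrame({"group": ["A"]}, index=["s1"])
        (t,) = top_k_transactions(cm, meta, k=20)["A"]
        assert len(t) == 12
        assert all(cm.counts.loc[sp, "s1"] > 0 for sp in t)

    def test_tie_at_rank_k_broken_lexicographically(self):
        # three species tied at the cut: the lexicographically smaller wins
        col = np.array([9, 9, 5, 5, 5])
        cm = self._matrix(col[:, None], ["s1"])
        meta = pd.DataFrame({"group": ["A"]}, index=["s1"])
        (t,) = top_k_transactions(cm, meta, k=3)["A"]
        assert t == {"sp00", "sp01", "sp02"}


class TestPairRules:
    def test_hand_count_support_confidence(self):
        # {A,B} in 4/10; A additionally alone once, B alone once
        tr = ([frozenset("AB")] * 4 + [frozenset("A")] + [frozenset("B")]
              + [frozenset("Z")] * 4)
        (rule,) = mine_pair_rules(tr, 0.3, 0.7)
        assert rule.support == pytest.approx(0.4)
        assert rule.confidence == pytest.approx(0.8)  # 4/5 both directions

    def test_strict_support_boundary(self):
        tr = [frozenset("AB")] * 3 + [frozenset("Z")] * 7
        assert mine_pair_rules(tr, 0.3, 0.7) == []  # support == 0.3, not >

    def test_empty_transactions_error(self):
        with pytest.raises(ValueError):
            mine_pair_rules([], 0.3, 0.7)

    @given(st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=100, deadline=None)
    def test_equals_exhaustive_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        items = [f"i{k}" for k in range(rng.integers(3, 16))]
        transactions = [
            frozenset(rng.choice(items, size=rng.integers(1, len(items) + 1),
                                 replace=False))
            for _ in range(50)
        ]
        min_s, min_c = rng.uniform(0.05, 0.5), rng.uniform(0.5, 0.9)
        mined = {(r.species_a, r.species_b, r.support, r.confidence)
                 for r in mine_pair_rules(transactions, min_s, min_c)}
        assert mined == brute_force_pair_rules(transactions, min_s, min_c)


class TestSpanningForest:
    def _graph(self, weighted_edges):
        rules = [AssociationRulePair(a, b, 1.0 - w, 1.0) for a, b, w in weighted_edges]
        return rules_to_graph(rules)

    def test_triangle_keeps_two_strongest_edges(self):
        g = self._graph([("a", "b", 0.1), ("b", "c", 0.2), ("a", "c", 0.3)])
        f = minimum_spanning_forest(g)
        assert set(map(tuple, map(sorted, f.edges))) == {("a", "b"), ("b", "c")}
        assert g.edges["a", "c"]["in_mst"] is False

    def test_disconnected_components_give_forest(self):
        g = self._graph([("a", "b", 0.1), ("b", "c", 0.1), ("a", "c", 0.2),
                         ("x", "y", 0.1)])
        f = minimum_spanning_forest(g)
        assert f.number_of_edges() == 5 - 2  # n - components

    @given(st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=40, deadline=None)
    def test_forest_weight_matches_exhaustive_minimum(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 7))
        nodes = [f"n{i}" for i in range(n)]
        edges = [
            (a, b, round(float(rng.uniform(0.05, 0.7)), 3))
            for a, b in combinations(nodes, 2)
            if rng.random() < 0.6
        ]
        g = self._graph(edges)
        if g.number_of_nodes() == 0:
            return
        f = minimum_spanning_forest(g)
        got = sum(d["weight"] for *_, d in f.edges(data=True))
        assert got == pytest.approx(brute_force_min_forest_weight(g))


class TestGirvanNewman:
    def test_two_stars_split_at_bridge(self):
        rules = [AssociationRulePair("hubA", leaf, 0.9, 1.0)
                 for leaf in ("a1", "a2", "a3", "a4")]
        rules += [AssociationRulePair("hubB", leaf, 0.9, 1.0)
                  for leaf in ("b1", "b2", "b3", "b4")]
        rules.append(AssociationRulePair("hubA", "hubB", 0.5, 1.0))
        forest = minimum_spanning_forest(rules_to_graph(rules))
        comm = girvan_newman_communities(forest)
        groups = {}
        for node, c in comm.items():
            groups.setdefault(c, set()).add(node)
        assert sorted(map(sorted, groups.values())) == [
            ["a1", "a2", "a3", "a4", "hubA"],
            ["b1", "b2", "b3", "b4", "hubB"],
        ]

    def test_single_edge_prefers_one_community(self):
        forest = minimum_spanning_forest(
            rules_to_graph([AssociationRulePair("a", "b", 0.9, 1.0)]))
        comm = girvan_newman_communities(forest)
        assert comm == {"a": 0, "b": 0}

    def test_partition_maximizes_modularity_over_dendrogram(self):
        rng = np.random.default_rng(12)
        nodes = [f"n{i}" for i in range(9)]
        g = nx.random_labeled_tree(9, seed=3)
        rules = [AssociationRulePair(nodes[a], nodes[b],
                                     round(float(rng.uniform(0.3, 0.95)), 2), 1.0)
                 for a, b in g.edges]
        forest = minimum_spanning_forest(rules_to_graph(rules))
        comm = girvan_newman_communities(forest)
        parts = {}
        for node, c in comm.items():
            parts.setdefault(c, set()).add(node)
        q_chosen = nx.community.modularity(forest, list(parts.values()))
        # recompute the full removal sequence and check no partition beats it
        work = forest.copy()
        best = nx.community.modularity(forest,
                                       list(nx.connected_components(forest)))
        while work.number_of_edges():
            ebc = nx.edge_betweenness_centrality(work, normalized=False)
            top = max(ebc.values())
            edge = min(tuple(sorted(e)) for e, v in ebc.items() if v == top)
            work.remove_edge(*edge)
            best = max(best, nx.community.modularity(
                forest, list(nx.connected_components(work))))
        assert q_chosen == pytest.approx(best)


class TestRolesAndBetweenness:
    def test_edge_betweenness_of_path(self):
        g = nx.Graph([("a", "b"), ("b", "c")])
        ebc = nx.edge_betweenness_centrality(g, normalized=False)
        assert ebc[("a", "b")] == 2  # paths a-b, a-c
        assert ebc[("b", "c")] == 2

    def test_star_center_is_hub(self):
        rules = [AssociationRulePair("x", leaf, 0.9, 1.0)
                 for leaf in ("a", "b", "c", "d")]
        forest = minimum_spanning_forest(rules_to_graph(rules))
        comm = girvan_newman_communities(forest)
        roles = classify_roles(forest, comm)
        assert roles["x"] == "hub"
        assert node_betweenness(forest)["x"] == 6  # C(4, 2)
        assert all(roles[leaf] == "member" for leaf in "abcd")

    def test_path_hub_tie_broken_lexicographically(self):
        rules = [AssociationRulePair("a", "b", 0.9, 1.0),
                 AssociationRulePair("b", "c", 0.9, 1.0),
                 AssociationRulePair("c", "d", 0.9, 1.0)]
        forest = minimum_spanning_forest(rules_to_graph(rules))
        roles = classify_roles(forest, {n: 0 for n in forest.nodes})
        assert roles == {"a": "member", "b": "hub", "c": "semi-hub", "d": "member"}

    def test_two_node_community_has_hub_and_member(self):
        forest = minimum_spanning_forest(
            rules_to_graph([AssociationRulePair("a", "b", 0.9, 1.0)]))
        roles = classify_roles(forest, {"a": 0, "b": 0})
        assert sorted(roles.values()) == ["hub", "member"]

    @given(st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=30, deadline=None)
    def test_tree_betweenness_matches_path_counting(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 13))
        tree = nx.random_labeled_tree(n, seed=int(rng.integers(0, 10 ** 6)))
        tree = nx.relabel_nodes(tree, {i: f"n{i}" for i in range(n)})
        if n > 4 and rng.random() < 0.5:  # sometimes a forest
            tree.remove_edge(*sorted(tree.edges)[0])
        got = node_betweenness(tree)
        expected = brute_force_node_betweenness(tree)
        assert {k: round(v) for k, v in got.items()} == expected


def test_stage_is_deterministic(default_bundle):
    counts, meta, *_ = default_bundle
    tx = top_k_transactions(counts, meta, k=20)
    a = build_network("G1", tx["G1"])
    b = build_network("G1", tx["G1"])
    assert sorted(a.forest.edges) == sorted(b.forest.edges)
    assert a.communities == b.communities
    assert a.roles == b.roles
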