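"""Per-group interspecific association networks.

Each sample contributes a *transaction*: its top-k most abundant species.
Pair rules are mined apriori-style (a pair is only scored if both
singletons clear the support threshold — which any qualifying pair's
members necessarily do) with strict support/confidence cut-offs.  The rule
graph is reduced to a minimum spanning forest (edge weight 1 - support),
communities are found by Girvan-Newman edge-betweenness removal choosing
the partition of maximum modularity, and nodes are classified as hub
(highest degree per community), semi-hub (internal non-hub, betweenness
> 0) or member.

Everything after the transactions is deterministic: ties are broken by
weight then lexicographic species ids throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import networkx as nx
import pandas as pd

from .types import CountMatrix

__all__ = [
    "top_k_transactions",
    "mine_pair_rules",
    "AssociationRulePair",
    "AssociationNetwork",
    "minimum_spanning_forest",
    "girvan_newman_communities",
    "classify_roles",
    "build_network",
    "build_group_networks",
]


def top_k_transactions(
    counts: CountMatrix, metadata: pd.DataFrame, k: int = 20
) -> dict[str, list[frozenset]]:
    """Top-k species per sample, grouped by the sample's group label.

    Samples with fewer than k species present contribute all their present
    species; ties at rank k are broken by lexicographically smaller id.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    missing = [s for s in counts.sample_ids if s not in metadata.index]
    if missing:
        raise ValueError(f"samples missing from metadata: {missing}")
    out: dict[str, list[frozenset]] = {}
    for s in counts.sample_ids:
        col = counts.counts[s]
        present = col[col > 0]
        ranked = sorted(present.items(), key=lambda kv: (-kv[1], kv[0]))
        chosen = frozenset(sp for sp, _ in ranked[:k])
        out.setdefault(str(metadata.loc[s, "group"]), []).append(chosen)
    return out


@dataclass(frozen=True)
class AssociationRulePair:
    """Undirected species pair with support and max directional confidence."""

    species_a: str
    species_b: str
    support: float
    confidence: float


def mine_pair_rules(
    transactions: list[frozenset],
    min_support: float = 0.3,
    min_confidence: float = 0.7,
) -> list[AssociationRulePair]:
    """Mine pairwise association rules with strict thresholds.

    support(a,b) = fraction of transactions containing both;
    confidence = max(support(ab)/support(a), support(ab)/support(b)).
    A pair is kept iff support > min_support AND confidence > min_confidence
    (both strict).  Apriori pruning: only items whose singleton support
    clears min_support can appear in a qualifying pair.
    """
    n = len(transactions)
    if n == 0:
        raise ValueError("empty transaction set")
    item_count: dict[str, int] = {}
    for t in transactions:
        for it in t:
            item_count[it] = item_count.get(it, 0) + 1
    frequent = {it for it, c in item_count.items() if c / n > min_support}
    pair_count: dict[tuple[str, str], int] = {}
    for t in transactions:
        items = sorted(it for it in t if it in frequent)
        for a, b in combinations(items, 2):
            pair_count[(a, b)] = pair_count.get((a, b), 0) + 1
    rules = []
    for (a, b), c in sorted(pair_count.items()):
        support = c / n
        if support <= min_support:
            continue
        confidence = max(c / item_count[a], c / item_count[b])
        if confidence <= min_confidence:
            continue
        rules.append(AssociationRulePair(a, b, support, confidence))
    return rules


@dataclass
class AssociationNetwork:
    """Association network for one group: rule graph, forest, communities, roles."""

    group: str
    graph: nx.Graph  # full rule graph; edges carry support/confidence/in_mst
    forest: nx.Graph  # the MST reduction (subgraph of `graph`)
    communities: dict[str, int] = field(default_factory=dict)
    roles: dict[str, str] = field(default_factory=dict)

    def to_graph(self) -> nx.Graph:
        """Rule graph annotated with node community/role/degree/betweenness."""
        g = self.graph.copy()
        bet = node_betweenness(self.forest) if self.forest.number_of_nodes() else {}
        for node in g.nodes:
            g.nodes[node]["degree"] = self.forest.degree(node) if node in self.forest else 0
            g.nodes[node]["betweenness"] = bet.get(node, 0.0)
            if node in self.communities:
                g.nodes[node]["community"] = int(self.communities[node])
            if node in self.roles:
                g.nodes[node]["role"] = self.roles[node]
        return g


def rules_to_graph(rules: list[AssociationRulePair]) -> nx.Graph:
    """Undirected rule graph; edge weight = 1 - support (stronger = shorter)."""
    g = nx.Graph()
    for r in sorted(rules, key=lambda r: (r.species_a, r.species_b)):
        g.add_edge(
            r.species_a,
            r.species_b,
            support=r.support,
            confidence=r.confidence,
            weight=1.0 - r.support,
        )
    return g


def minimum_spanning_forest(graph: nx.Graph) -> nx.Graph:
    """Kruskal minimum spanning forest, ties broken by (weight, lexicographic pair)."""
    forest = nx.Graph()
    forest.add_nodes_from(sorted(graph.nodes))
    uf = nx.utils.UnionFind(graph.nodes)
    edges = sorted(
        (tuple(sorted((a, b))) + (d,) for a, b, d in graph.edges(data=True)),
        key=lambda e: (e[2]["weight"], e[0], e[1]),
    )
    for a, b, data in edges:
        if uf[a] != uf[b]:
            uf.union(a, b)
            forest.add_edge(a, b, **data)
    for a, b in graph.edges:
        graph.edges[a, b]["in_mst"] = forest.has_edge(a, b)
    return forest


def _partition_from_components(g: nx.Graph) -> list[frozenset]:
    return sorted((frozenset(c) for c in nx.connected_components(g)), key=lambda c: min(c))


def girvan_newman_communities(forest: nx.Graph) -> dict[str, int]:
    """Girvan-Newman on the forest, returning the max-modularity partition.

    Edges are removed highest-edge-betweenness-first (ties: lexicographic
    endpoint pair); modularity of every partition along the dendrogram is
    evaluated on the intact forest, and the earliest partition with maximal
    Q wins (so a single community is preferred over needless splits).
    """
    if forest.number_of_nodes() == 0:
        return {}
    if forest.number_of_edges() == 0:
        parts = _partition_from_components(forest)
    else:
        work = forest.copy()
        partitions = [_partition_from_components(work)]
        while work.number_of_edges() > 0:
            ebc = nx.edge_betweenness_centrality(work, normalized=False)
            top = max(ebc.values())
            # among betweenness ties, remove the lexicographically smallest pair
            edge = min(tuple(sorted(e)) for e, v in ebc.items() if v == top)
            work.remove_edge(*edge)
            part = _partition_from_components(work)
            if part != partitions[-1]:
                partitions.append(part)
        scores = [nx.community.modularity(forest, p) for p in partitions]
        best_q = max(scores)
        parts = partitions[scores.index(best_q)]
    return {node: idx for idx, comm in enumerate(parts) for node in sorted(comm)}


def node_betweenness(forest: nx.Graph) -> dict[str, float]:
    """Unnormalized node betweenness (path counts; exact on trees)."""
    return nx.betweenness_centrality(forest, normalized=False)


def classify_roles(forest: nx.Graph, communities: dict[str, int]) -> dict[str, str]:
    """Hub / semi-hub / member per community.

    Within each community of >= 2 nodes the hub is the node of highest
    forest degree (ties: higher betweenness, then lexicographic id);
    semi-hubs are non-hub internal nodes (betweenness > 0); all remaining
    nodes — and singleton communities — are members.
    """
    bet = node_betweenness(forest)
    roles: dict[str, str] = {}
    by_comm: dict[int, list[str]] = {}
    for node, c in communities.items():
        by_comm.setdefault(c, []).append(node)
    for c, nodes in by_comm.items():
        if len(nodes) < 2:
            roles[nodes[0]] = "member"
            continue
        hub = min(nodes, key=lambda n: (-forest.degree(n), -bet[n], n))
        for n in sorted(nodes):
            if n == hub:
                roles[n] = "hub"
            elif bet[n] > 0:
                roles[n] = "semi-hub"
            else:
                roles[n] = "member"
    return roles


def build_network(
    group: str,
    transactions: list[frozenset],
    min_support: float = 0.3,
    min_confidence: float = 0.7,
) -> AssociationNetwork:
    """Full per-group stage: rules -> forest -> communities -> roles."""
    rules = mine_pair_rules(transactions, min_support, min_confidence)
    graph = rules_to_graph(rules)
    forest = minimum_spanning_forest(graph)
    communities = girvan_newman_communities(forest)
    roles = classify_roles(forest, communities)
    return AssociationNetwork(
        group=group, graph=graph, forest=forest, communities=communities, roles=roles
    )


def build_group_networks(
    counts: CountMatrix,
    metadata: pd.DataFrame,
    top_k: int = 20,
    min_support: float = 0.3,
    min_confidence: float = 0.7,
) -> dict[str, AssociationNetwork]:
    """Build one association network per sample group."""
    transactions = top_k_transactions(counts, metadata, k=top_k)
    return {
        g: build_network(g, t, min_support, min_confidence)
        for g, t in sorted(transactions.items())
    }
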