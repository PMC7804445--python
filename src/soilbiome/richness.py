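"""Differential taxonomic richness via ilr balances on a hierarchical tree.

The richness of a parent taxon (family, genus) in a sample is the number
of distinct child taxa observed there.  Richness profiles are placed on a
binary tree (average-linkage clustering of the taxa's proportion
profiles), each internal node defines an isometric log-ratio balance
between its two leaf sets, and a per-balance OLS/ANOVA F-test against the
group labels locates significant shifts.  A taxon is called differential
when the balance at the node separating it from its sibling set is
significant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .types import TAXONOMY_RANKS, CountMatrix

__all__ = [
    "richness_matrix",
    "BalanceTree",
    "BalanceNode",
    "balance_tree",
    "ilr_balances",
    "ols_balance_test",
    "flag_differential_taxa",
    "differential_richness_analysis",
]

_RANK_ORDER = TAXONOMY_RANKS + ("species",)


def richness_matrix(
    counts: CountMatrix,
    taxonomy: pd.DataFrame,
    parent_rank: str = "family",
    child_rank: str = "species",
) -> pd.DataFrame:
    """Parent-taxon x sample matrix of observed child-taxon richness.

    A cell counts the distinct child taxa (e.g. species of a family) with
    nonzero abundance in the sample.  Species lacking the parent (or a
    non-species child) rank annotation are excluded.
    """
    for r in (parent_rank, child_rank):
        if r not in _RANK_ORDER:
            raise ValueError(f"unknown rank {r!r}; expected one of {_RANK_ORDER}")
    if _RANK_ORDER.index(parent_rank) >= _RANK_ORDER.index(child_rank):
        raise ValueError(f"parent rank {parent_rank!r} must be above child rank {child_rank!r}")
    pairs = {}
    for sp in counts.species_ids:
        if sp not in taxonomy.index:
            continue
        p = taxonomy.loc[sp, parent_rank]
        c = sp if child_rank == "species" else taxonomy.loc[sp, child_rank]
        if pd.isna(p) or pd.isna(c):
            continue
        pairs[sp] = (str(p), str(c))
    if not pairs:
        raise ValueError("no species with the requested parent/child rank annotations")
    present = counts.counts.loc[list(pairs)] > 0
    keys = pd.MultiIndex.from_tuples(
        [pairs[sp] for sp in present.index], names=[parent_rank, child_rank]
    )
    present.index = keys
    child_present = present.groupby(level=[0, 1]).any()
    richness = child_present.groupby(level=0).sum().astype(int)
    return richness.sort_index()


@dataclass(frozen=True)
class BalanceNode:
    """One internal tree node: the contrast of its left vs right leaf sets."""

    node_id: str
    left: tuple[str, ...]
    right: tuple[str, ...]


@dataclass
class BalanceTree:
    """Full binary tree over taxa with root-first balance nodes."""

    taxa: list[str]
    nodes: list[BalanceNode]
    parent_of_leaf: dict[str, str]


def balance_tree(richness: pd.DataFrame) -> BalanceTree:
    """Average-linkage binary tree on Euclidean distance of proportion profiles."""
    if richness.shape[0] < 2:
        raise ValueError("need at least 2 taxa to build a tree")
    col_tot = richness.sum(axis=0).to_numpy(dtype=float)
    col_tot[col_tot == 0] = 1.0
    profiles = richness.to_numpy(dtype=float) / col_tot
    z = hierarchy.linkage(pdist(profiles, metric="euclidean"), method="average")
    root = hierarchy.to_tree(z)
    taxa = list(richness.index)

    nodes: list[BalanceNode] = []
    parent_of_leaf: dict[str, str] = {}

    def leaves(node) -> tuple[str, ...]:
        return tuple(taxa[i] for i in node.pre_order(lambda n: n.id))

    def walk(node) -> None:
        if node.is_leaf():
            return
        nid = f"y{len(nodes)}"
        left, right = leaves(node.left), leaves(node.right)
        nodes.append(BalanceNode(node_id=nid, left=left, right=right))
        if len(left) == 1:
            parent_of_leaf[left[0]] = nid
        if len(right) == 1:
            parent_of_leaf[right[0]] = nid
        walk(node.left)
        walk(node.right)

    walk(root)
    return BalanceTree(taxa=taxa, nodes=nodes, parent_of_leaf=parent_of_leaf)


def ilr_balances(
    richness: pd.DataFrame, tree: BalanceTree, pseudocount: float = 0.5
) -> pd.DataFrame:
    """Per-node ilr balances (balances x samples).

    For a node with left leaf set R (|R| = r) and right leaf set S (|S| = s):
    ``y = sqrt(r s / (r + s)) * ln(g(x_R) / g(x_S))`` with g the geometric
    mean of the pseudocount-shifted richness values (the closure constant
    cancels inside the ratio).
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    logx = np.log(richness.to_numpy(dtype=float) + pseudocount)
    logx_df = pd.DataFrame(logx, index=richness.index, columns=richness.columns)
    rows = {}
    for node in tree.nodes:
        r, s = len(node.left), len(node.right)
        coef = np.sqrt(r * s / (r + s))
        gm_left = logx_df.loc[list(node.left)].mean(axis=0)
        gm_right = logx_df.loc[list(node.right)].mean(axis=0)
        rows[node.node_id] = coef * (gm_left - gm_right)
    return pd.DataFrame(rows).T.loc[[n.node_id for n in tree.nodes]]


def ols_balance_test(balances: pd.DataFrame, groups) -> pd.DataFrame:
    """Per-balance one-way OLS F-test of the group effect.

    Regressing a balance on group indicators and F-testing the group
    effect is exactly the one-way ANOVA F; constant balances are flagged
    degenerate with p = 1.
    """
    groups = np.asarray(groups)
    labels = pd.unique(groups)
    if len(labels) < 2:
        raise ValueError("need at least 2 groups")
    rows = []
    for node_id, y in balances.iterrows():
        v = y.to_numpy(dtype=float)
        if np.ptp(v) == 0:
            rows.append({"balance": node_id, "F": 0.0, "p": 1.0, "degenerate": True})
            continue
        f, p = stats.f_oneway(*(v[groups == g] for g in labels))
        rows.append({"balance": node_id, "F": float(f), "p": float(p), "degenerate": False})
    return pd.DataFrame(rows).set_index("balance")


def flag_differential_taxa(
    tree: BalanceTree, tests: pd.DataFrame, alpha: float = 1e-6
) -> list[str]:
    """Taxa whose separating balance (at the leaf's parent node) has p < alpha."""
    flagged = []
    for taxon in tree.taxa:
        nid = tree.parent_of_leaf.get(taxon)
        if nid is not None and nid in tests.index and tests.loc[nid, "p"] < alpha:
            flagged.append(taxon)
    return flagged


def differential_richness_analysis(
    counts: CountMatrix,
    taxonomy: pd.DataFrame,
    metadata: pd.DataFrame,
    parent_rank: str = "family",
    child_rank: str = "species",
    pseudocount: float = 0.5,
    alpha: float = 1e-6,
) -> dict:
    """Full stage: richness matrix -> tree -> balances -> tests -> flags."""
    richness = richness_matrix(counts, taxonomy, parent_rank, child_rank)
    tree = balance_tree(richness)
    balances = ilr_balances(richness, tree, pseudocount=pseudocount)
    groups = metadata.loc[list(richness.columns), "group"].to_numpy()
    tests = ols_balance_test(balances, groups)
    flagged = flag_differential_taxa(tree, tests, alpha=alpha)
    return {
        "richness": richness,
        "tree": tree,
        "balances": balances,
        "tests": tests,
        "differential_taxa": flagged,
    }
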