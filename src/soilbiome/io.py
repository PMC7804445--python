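"""Readers and writers for the pipeline's tab-separated table formats.

TSV (UTF-8, '.' decimal) is the canonical on-disk format; graphs are
written as lexicographically sorted edge-list TSV or GraphML.  All readers
enforce the type invariants on entry; all writers are deterministic so
that identical runs produce byte-identical files.
"""

from __future__ import annotations

import csv
from pathlib import Path

import networkx as nx
import pandas as pd

from .types import (
    TAXONOMY_RANKS,
    CountMatrix,
    validate_gene_profiles,
    validate_metadata,
    validate_taxonomy,
)

__all__ = [
    "read_count_table",
    "write_count_table",
    "read_metadata",
    "write_metadata",
    "read_taxonomy",
    "write_taxonomy",
    "read_gene_profiles",
    "write_gene_profiles",
    "write_network",
    "read_network_edges",
    "attach_metadata",
]


def read_count_table(path) -> CountMatrix:
    """Read a species x sample TSV count table.

    First column holds species ids, header row holds sample ids, cells are
    non-negative integers.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype={0: str})
    if df.empty:
        raise ValueError(f"empty count table: {path}")
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        if coerced.isna().any():
            row = df.index[coerced.isna()][0]
            raise ValueError(f"non-numeric count at species {row!r}, sample {col!r} in {path}")
        df[col] = coerced
    return CountMatrix(df)


def write_count_table(counts: CountMatrix, path) -> None:
    counts.counts.to_csv(path, sep="\t", index_label="species_id")


def read_metadata(path) -> pd.DataFrame:
    """Read sample metadata TSV (columns: sample_id, group[, soil_class, ph, ...])."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    if "sample_id" not in df.columns:
        raise ValueError(
            f"metadata requires columns ['sample_id', 'group']; found {list(df.columns)}"
        )
    df = df.set_index("sample_id")
    return validate_metadata(df)


def write_metadata(meta: pd.DataFrame, path) -> None:
    meta.to_csv(path, sep="\t", index_label="sample_id")


def read_taxonomy(path) -> pd.DataFrame:
    """Read a taxonomy lineage TSV (species_id + the five ranks down to genus)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "species_id" not in df.columns:
        raise ValueError(
            f"taxonomy requires columns ['species_id', *{list(TAXONOMY_RANKS)}]; "
            f"found {list(df.columns)}"
        )
    return validate_taxonomy(df.set_index("species_id"))


def write_taxonomy(tax: pd.DataFrame, path) -> None:
    tax.to_csv(path, sep="\t", index_label="species_id")


def read_gene_profiles(path) -> dict[str, frozenset]:
    """Read species gene repertoires: TSV with columns species_id, genes.

    The ``genes`` cell is a ';'-separated list of gene symbols; symbols are
    canonicalized case-insensitively.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("species_id", "genes"):
        if col not in df.columns:
            raise ValueError(
                f"gene profile table requires columns ['species_id', 'genes']; "
                f"found {list(df.columns)}"
            )
    profiles: dict[str, set] = {}
    for sp, cell in zip(df["species_id"], df["genes"]):
        if sp in profiles:
            raise ValueError(f"duplicate species id in gene profiles: {sp!r}")
        genes = set() if pd.isna(cell) else {g for g in str(cell).split(";") if g.strip()}
        profiles[sp] = genes
    return validate_gene_profiles(profiles)


def write_gene_profiles(profiles: dict[str, frozenset], path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["species_id", "genes"])
        for sp in sorted(profiles):
            w.writerow([sp, ";".join(sorted(profiles[sp]))])


def attach_metadata(counts: CountMatrix, meta: pd.DataFrame) -> pd.DataFrame:
    """Align metadata to a count matrix; every sample must have a row."""
    missing = [s for s in counts.sample_ids if s not in meta.index]
    if missing:
        raise ValueError(f"samples missing from metadata: {missing}")
    return meta.loc[counts.sample_ids]


_EDGE_COLUMNS = ["species_a", "species_b", "support", "confidence", "in_mst"]
_NODE_ATTRS = ["community", "role", "degree", "betweenness"]


def write_network(network, path, format: str = "tsv") -> None:
    """Write an AssociationNetwork as an edge-list TSV or GraphML file.

    The edge list carries support/confidence/in_mst per edge in
    lexicographic row order; GraphML additionally carries per-node
    community/role/degree/betweenness attributes.
    """
    if format not in ("tsv", "graphml"):
        raise ValueError(f"unknown network format {format!r}; supported: 'tsv', 'graphml'")
    g = network.to_graph()
    if format == "tsv":
        rows = []
        for a, b, data in g.edges(data=True):
            a, b = sorted((a, b))
            rows.append([a, b, data["support"], data["confidence"], int(data["in_mst"])])
        rows.sort(key=lambda r: (r[0], r[1]))
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh, delimiter="\t", lineterminator="\n")
            w.writerow(_EDGE_COLUMNS)
            w.writerows(rows)
    else:
        # GraphML writer needs plain scalar attribute values
        out = nx.Graph()
        for n in sorted(g.nodes):
            attrs = {k: g.nodes[n][k] for k in _NODE_ATTRS if k in g.nodes[n]}
            out.add_node(n, **attrs)
        for a, b, data in sorted((tuple(sorted((a, b))) + (d,) for a, b, d in g.edges(data=True))):
            out.add_edge(a, b, support=float(data["support"]),
                         confidence=float(data["confidence"]), in_mst=bool(data["in_mst"]))
        nx.write_graphml(out, path)


def read_network_edges(path) -> pd.DataFrame:
    """Read back an edge-list TSV written by :func:`write_network`."""
    df = pd.read_csv(path, sep="\t", dtype={"species_a": str, "species_b": str})
    missing = [c for c in _EDGE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"edge list missing columns {missing}")
    df["in_mst"] = df["in_mst"].astype(bool)
    return df
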