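"""End-to-end orchestration of the analysis stages.

``run_pipeline`` executes normalization, alpha diversity, differential
richness, enrichment, association networks and functional profiling in
order, writes every stage's tables under an output directory, and leaves
a machine-readable ``summary.json``.  Stages are independent: a stage
failure is recorded in the summary without aborting the rest (stages that
need a failed stage's output are skipped with an explicit entry).
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import networkx
import numpy
import pandas
import scipy

from . import __version__
from .diversity import anova_tukey, diversity_table
from .enrichment import enrichment_analysis
from .functional import (
    community_pathway_completeness,
    functional_abundance_anova,
    gene_presence_counts,
    load_pathway_registry,
)
from .io import attach_metadata, write_network
from .network import build_group_networks, node_betweenness
from .normalization import gmpr_normalize
from .richness import differential_richness_analysis
from .types import CountMatrix, PipelineConfig

logger = logging.getLogger("soilbiome")

__all__ = ["run_pipeline"]


def _write_json(obj, path: Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def run_pipeline(
    config: PipelineConfig,
    counts: CountMatrix,
    metadata,
    taxonomy=None,
    genes=None,
    outdir="soilbiome_out",
    registry_path=None,
) -> dict:
    """Run every stage and write results under ``outdir``.

    Returns the in-memory result bundle: normalized matrix, diversity
    tables, differential-richness results, enrichment table, per-group
    association networks and the functional report (where inputs allow).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    metadata = attach_metadata(counts, metadata)  # hard error before any stage
    bundle: dict = {}
    status: dict[str, str] = {}

    def stage(name: str, fn, *deps):
        missing = [d for d in deps if d not in bundle]
        if missing:
            status[name] = f"skipped: requires {', '.join(missing)}"
            logger.warning("stage %s skipped (missing %s)", name, missing)
            return
        try:
            bundle[name] = fn()
            status[name] = "ok"
        except Exception as exc:  # keep unrelated stages running
            status[name] = f"failed: {exc}"
            logger.exception("stage %s failed", name)

    # --- normalization ---
    def _normalize():
        norm = gmpr_normalize(counts, min_shared=config.min_shared)
        norm.values.to_csv(outdir / "normalized.tsv", sep="\t", index_label="species_id")
        norm.size_factors.to_frame().to_csv(outdir / "size_factors.tsv", sep="\t",
                                            index_label="sample_id")
        return norm

    stage("normalize", _normalize)

    # --- alpha diversity ---
    def _diversity():
        table = diversity_table(counts, metadata)
        table.to_csv(outdir / "diversity.tsv", sep="\t")
        comparisons = {
            metric: anova_tukey(
                table[metric], table["group"], alpha=config.diversity_alpha
            ).to_dict()
            for metric in ("log10_chao1", "shannon")
        }
        _write_json(comparisons, outdir / "diversity_comparison.json")
        return {"table": table, "comparisons": comparisons}

    stage("diversity", _diversity)

    # --- differential richness ---
    if taxonomy is None:
        status["richness_shift"] = "skipped: no taxonomy table"
        logger.warning("stage richness_shift skipped: no taxonomy table")
    else:
        def _richness():
            res = differential_richness_analysis(
                counts,
                taxonomy,
                metadata,
                parent_rank=config.parent_rank,
                child_rank=config.child_rank,
                pseudocount=config.pseudocount,
                alpha=config.richness_alpha,
            )
            res["balances"].to_csv(outdir / "balances.tsv", sep="\t", index_label="balance")
            res["tests"].to_csv(outdir / "balance_tests.tsv", sep="\t")
            pandas.Series(res["differential_taxa"], name="taxon").to_csv(
                outdir / "differential_taxa.tsv", sep="\t", index=False
            )
            return res

        stage("richness_shift", _richness)

    # --- enrichment ---
    def _enrich():
        table = enrichment_analysis(
            bundle["normalize"],
            metadata,
            alpha=config.enrich_alpha,
            fence_multiplier=config.fence_multiplier,
            p_adjust_method=config.p_adjust_method,
            residual_mode=config.residual_mode,
            reference=config.fence_reference,
        )
        table.table.to_csv(outdir / "enrichment.tsv", sep="\t", index=False)
        table.table[table.table["enriched"]].to_csv(
            outdir / "enriched_species.tsv", sep="\t", index=False
        )
        return table

    stage("enrich", _enrich, "normalize")

    # --- association networks ---
    def _network():
        nets = build_group_networks(
            counts,
            metadata,
            top_k=config.top_k,
            min_support=config.min_support,
            min_confidence=config.min_confidence,
        )
        for g, net in sorted(nets.items()):
            rules = [
                {"species_a": a, "species_b": b, "support": d["support"],
                 "confidence": d["confidence"], "in_mst": d["in_mst"]}
                for a, b, d in sorted(
                    (tuple(sorted((a, b))) + (d,) for a, b, d in net.graph.edges(data=True))
                )
            ]
            pandas.DataFrame(
                rules, columns=["species_a", "species_b", "support", "confidence", "in_mst"]
            ).to_csv(outdir / f"rules_{g}.tsv", sep="\t", index=False)
            write_network(net, outdir / f"network_{g}.graphml", format="graphml")
            pandas.DataFrame(
                sorted(net.communities.items()), columns=["species_id", "community"]
            ).to_csv(outdir / f"communities_{g}.tsv", sep="\t", index=False)
            bet = node_betweenness(net.forest)
            pandas.DataFrame(
                [
                    {"species_id": n, "role": net.roles.get(n, "member"),
                     "degree": net.forest.degree(n), "betweenness": bet.get(n, 0.0)}
                    for n in sorted(net.forest.nodes)
                ]
            ).to_csv(outdir / f"roles_{g}.tsv", sep="\t", index=False)
        return nets

    stage("network", _network)

    # --- functional profiling ---
    if genes is None:
        status["functions"] = "skipped: no gene profile table"
        logger.warning("stage functions skipped: no gene profile table")
    else:
        def _functions():
            registry = load_pathway_registry(registry_path)
            enr = bundle["enrich"]
            species_groups: dict[str, set] = {}
            for sp, g in enr.enriched_pairs():
                species_groups.setdefault(g, set()).add(sp)
            heatmap = gene_presence_counts(
                species_groups, genes, taxonomy if taxonomy is not None else
                pandas.DataFrame(columns=["phylum"]), genes=sorted(registry.genes()),
            )
            heatmap.to_csv(outdir / "heatmap_counts.tsv", sep="\t", index=False)
            completeness = {}
            for g, net in sorted(bundle["network"].items()):
                comms: dict[int, set] = {}
                for node, c in net.communities.items():
                    comms.setdefault(c, set()).add(node)
                completeness[g] = {
                    str(c): {
                        sid: st.to_dict()
                        for sid, st in community_pathway_completeness(
                            members, genes, registry
                        ).items()
                    }
                    for c, members in sorted(comms.items())
                }
            _write_json(completeness, outdir / "community_completeness.json")
            enriched_all = {sp for sps in species_groups.values() for sp in sps}
            qualifying = {
                gene: {sp for sp in enriched_all if gene in genes.get(sp, frozenset())}
                for gene in sorted(registry.genes())
            }
            anova = functional_abundance_anova(
                bundle["normalize"], qualifying, metadata, alpha=config.functional_alpha
            )
            anova.to_csv(outdir / "functional_anova.tsv", sep="\t")
            return {"heatmap": heatmap, "completeness": completeness, "anova": anova}

        stage("functions", _functions, "normalize", "enrich", "network")

    summary = {
        "config": config.to_dict(),
        "stages": status,
        "versions": {
            "soilbiome": __version__,
            "numpy": numpy.__version__,
            "scipy": scipy.__version__,
            "pandas": pandas.__version__,
            "networkx": networkx.__version__,
        },
        "n_species": counts.shape[0],
        "n_samples": counts.shape[1],
        "groups": sorted(metadata["group"].unique().tolist()),
    }
    if "enrich" in bundle:
        summary["n_enriched_pairs"] = int(bundle["enrich"].table["enriched"].sum())
    if "richness_shift" in bundle:
        summary["n_differential_taxa"] = len(bundle["richness_shift"]["differential_taxa"])
    if "network" in bundle:
        summary["network_sizes"] = {
            g: {"nodes": net.forest.number_of_nodes(), "edges": net.graph.number_of_edges()}
            for g, net in sorted(bundle["network"].items())
        }
    _write_json(summary, outdir / "summary.json")
    bundle["summary"] = summary
    return bundle
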