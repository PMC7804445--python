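"""Biogeochemical gene-set profiling of species repertoires.

A pathway *step* (e.g. denitrification) is modeled as a conjunction of
requirement groups; each group is a set of alternative gene symbols of
which at least one ("any", default) or all ("all", operon-like sets) must
be present.  A community *completes* a step when the union of its members'
gene sets satisfies every group — so species can complement each other,
and a *bridging* species is one that uniquely satisfies some group
(removing it breaks completeness).

The built-in registry covers the nitrogen, sulfur, carbon and phosphorus
transformations of soil bacteriomes (nitrogenase nifDKH with vanadium
alternatives, nitrate/nitrite reduction, denitrification nirS/nirK ->
norBC -> nosZ, sulfate reduction and the SOX system, carbohydrate and
aromatic-compound utilisation, dct transporters, Pho/Pst phosphorus
uptake and the C-P lyase operon).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .types import NormalizedMatrix, canonical_gene

__all__ = [
    "GeneGroup",
    "PathwayStep",
    "PathwayRegistry",
    "builtin_registry",
    "load_pathway_registry",
    "gene_presence_counts",
    "community_pathway_completeness",
    "functional_abundance_anova",
]


@dataclass(frozen=True)
class GeneGroup:
    """One requirement group: alternative genes ('any') or an operon ('all')."""

    genes: frozenset
    mode: str = "any"  # 'any' or 'all'

    def __post_init__(self):
        if not self.genes:
            raise ValueError("empty gene group")
        if self.mode not in ("any", "all"):
            raise ValueError("group mode must be 'any' or 'all'")
        object.__setattr__(self, "genes", frozenset(canonical_gene(g) for g in self.genes))

    def satisfied_by(self, genes: frozenset) -> bool:
        if self.mode == "all":
            return self.genes <= genes
        return bool(self.genes & genes)


@dataclass(frozen=True)
class PathwayStep:
    """A pathway step: AND over its requirement groups."""

    step_id: str
    element: str  # N, S, C or P
    groups: tuple[GeneGroup, ...]

    def __post_init__(self):
        if not self.groups:
            raise ValueError(f"step {self.step_id!r} has no requirement groups")

    def complete(self, genes: frozenset) -> bool:
        return all(g.satisfied_by(genes) for g in self.groups)


@dataclass
class PathwayRegistry:
    """Ordered collection of pathway steps keyed by step id."""

    steps: dict[str, PathwayStep] = field(default_factory=dict)

    def add(self, step: PathwayStep) -> None:
        if step.step_id in self.steps:
            raise ValueError(f"duplicate step id: {step.step_id!r}")
        self.steps[step.step_id] = step

    def genes(self) -> set:
        return {g for s in self.steps.values() for grp in s.groups for g in grp.genes}

    def to_dict(self) -> dict:
        return {
            sid: {
                "element": s.element,
                "groups": [
                    {"genes": sorted(g.genes), "mode": g.mode} for g in s.groups
                ],
            }
            for sid, s in self.steps.items()
        }

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_dict(cls, d: dict) -> "PathwayRegistry":
        reg = cls()
        for sid, spec in d.items():
            groups = tuple(
                GeneGroup(genes=frozenset(g["genes"]), mode=g.get("mode", "any"))
                for g in spec["groups"]
            )
            reg.add(PathwayStep(step_id=sid, element=spec["element"], groups=groups))
        return reg


def _any(*genes) -> GeneGroup:
    return GeneGroup(frozenset(genes), "any")


def _all(*genes) -> GeneGroup:
    return GeneGroup(frozenset(genes), "all")


def builtin_registry() -> PathwayRegistry:
    """Default N/S/C/P pathway-step registry (editable via JSON round-trip)."""
    reg = PathwayRegistry()
    add = reg.add
    # --- nitrogen ---
    add(PathwayStep("nitrogen_fixation", "N", (
        _any("nifD", "vnfD"), _any("nifK", "vnfK"), _any("nifH", "vnfH"),
    )))
    add(PathwayStep("assimilatory_nitrate_reduction", "N", (
        _any("nasAB", "narB"), _any("nirA", "NIT-6"),
    )))
    add(PathwayStep("dissimilatory_nitrate_reduction", "N", (
        _all("narG", "narH", "narI"),
    )))
    add(PathwayStep("dissimilatory_nitrite_reduction", "N", (
        _any("nirB", "nrfA"), _any("nirD", "nrfH"),
    )))
    add(PathwayStep("dissimilatory_nitrate_to_ammonium", "N", (
        _all("narG", "narH", "narI"), _any("nirB", "nrfA"), _any("nirD", "nrfH"),
    )))
    add(PathwayStep("denitrification", "N", (
        _any("nirS", "nirK"), _all("norB", "norC"), _any("nosZ"),
    )))
    # --- sulfur ---
    add(PathwayStep("assimilatory_sulfate_reduction", "S", (
        _any("cysNC", "sat"), _any("cysH"), _any("cysJ", "sir"),
    )))
    add(PathwayStep("dissimilatory_sulfate_reduction", "S", (
        _any("sat"), _all("aprA", "aprB"), _all("dsrA", "dsrB"),
    )))
    add(PathwayStep("sox_thiosulfate_oxidation", "S", (
        _all("soxA", "soxX"), _any("soxB"), _any("soxC"), _any("soxD"),
    )))
    add(PathwayStep("sulfide_oxidation", "S", (
        _any("fccA", "fccB", "fsr"),
    )))
    # --- carbon ---
    add(PathwayStep("carbohydrate_utilisation", "C", (
        _any("malZ", "bglX", "melA", "lacZ", "manB", "cbhA", "pelA"),
    )))
    add(PathwayStep("aromatic_hydroxylation", "C", (
        _any("ethA", "nagG", "nagH"),
    )))
    add(PathwayStep("c4_dicarboxylate_transport", "C", (
        _any("dctA", "dctP", "dctM"),
    )))
    # --- phosphorus ---
    add(PathwayStep("pho_regulon", "P", (
        _any("phoR"), _any("phoB"),
    )))
    add(PathwayStep("pst_transport", "P", (
        _all("pstS", "pstC", "pstA", "pstB"),
    )))
    add(PathwayStep("alkaline_phosphatase", "P", (
        _any("phoD", "phoA"),
    )))
    add(PathwayStep("acid_phosphatase", "P", (
        _any("phoN"),
    )))
    add(PathwayStep("cp_lyase", "P", (
        _all("phnG", "phnH", "phnI", "phnJ", "phnL", "phnM"),
    )))
    return reg


def load_pathway_registry(path=None) -> PathwayRegistry:
    """Load a registry from a JSON config, or the built-in default."""
    if path is None:
        return builtin_registry()
    with open(path) as fh:
        return PathwayRegistry.from_dict(json.load(fh))


def gene_presence_counts(
    species_groups: dict[str, set],
    gene_profiles: dict[str, frozenset],
    taxonomy: pd.DataFrame,
    genes=None,
) -> pd.DataFrame:
    """Heat-map counts: species per (gene, phylum, group) possessing the gene.

    ``species_groups`` maps group label -> set of (e.g. enriched) species.
    Species absent from the gene table count as lacking every gene.
    Returns a long DataFrame (gene, phylum, group, n_species).
    """
    if genes is None:
        gene_list = sorted({g for gs in gene_profiles.values() for g in gs})
    else:
        gene_list = sorted(canonical_gene(g) for g in genes)
    rows = []
    for group in sorted(species_groups):
        for sp in sorted(species_groups[group]):
            phylum = (
                str(taxonomy.loc[sp, "phylum"])
                if sp in taxonomy.index and not pd.isna(taxonomy.loc[sp, "phylum"])
                else "unclassified"
            )
            repertoire = gene_profiles.get(sp, frozenset())
            for g in gene_list:
                if g in repertoire:
                    rows.append((g, phylum, group))
    counts = pd.DataFrame(rows, columns=["gene", "phylum", "group"])
    out = (
        counts.groupby(["gene", "phylum", "group"]).size().rename("n_species").reset_index()
        if len(rows)
        else pd.DataFrame(columns=["gene", "phylum", "group", "n_species"])
    )
    return out


@dataclass
class StepStatus:
    """Completeness of one pathway step within one community."""

    step_id: str
    complete: bool
    contributors: list[list[str]]  # per requirement group, species satisfying it
    missing_groups: list[list[str]]  # unsatisfied groups (their gene lists)
    bridging: list[str]  # species uniquely satisfying >= 1 group

    def to_dict(self) -> dict:
        return {
            "step_id": self.step_id,
            "complete": self.complete,
            "contributors": self.contributors,
            "missing_groups": self.missing_groups,
            "bridging": self.bridging,
        }


def community_pathway_completeness(
    community: set,
    gene_profiles: dict[str, frozenset],
    registry: PathwayRegistry,
) -> dict[str, StepStatus]:
    """Per-step completeness, contributing species and bridging species.

    A step is complete when every requirement group is satisfied by the
    community's pooled gene sets; note pooled satisfaction of an 'all'
    group may span species.  A bridging species uniquely satisfies some
    group among those satisfiable per-species; for pooled-only 'all'
    groups, bridging species are those whose removal breaks the pooled
    union.
    """
    if not community:
        raise ValueError("community is empty")
    members = sorted(str(s) for s in community)
    repertoire = {sp: gene_profiles.get(sp, frozenset()) for sp in members}
    pooled = frozenset().union(*repertoire.values())
    pooled_without = {
        sp: frozenset().union(*(repertoire[o] for o in members if o != sp), frozenset())
        for sp in members
    }
    statuses: dict[str, StepStatus] = {}
    for sid, step in registry.steps.items():
        contributors, missing, bridging = [], [], set()
        complete = True
        for grp in step.groups:
            if not grp.satisfied_by(pooled):
                complete = False
                contributors.append([])
                missing.append(sorted(grp.genes))
                continue
            contributors.append([sp for sp in members if repertoire[sp] & grp.genes])
            for sp in contributors[-1]:
                # sp bridges this group if the rest of the community cannot cover it
                if not grp.satisfied_by(pooled_without[sp]):
                    bridging.add(sp)
        statuses[sid] = StepStatus(
            step_id=sid,
            complete=complete,
            contributors=contributors,
            missing_groups=missing,
            bridging=sorted(bridging) if complete else [],
        )
    return statuses


def functional_abundance_anova(
    norm: NormalizedMatrix,
    qualifying_species: dict[str, set],
    metadata: pd.DataFrame,
    alpha: float = 1e-3,
) -> pd.DataFrame:
    """Between-group ANOVA of per-sample summed abundance of gene-bearing species.

    ``qualifying_species`` maps a gene (or step) label to the species that
    possess it; for each label the normalized abundances of those species
    are summed per sample and compared across groups by one-way ANOVA.
    Labels with no qualifying species present are skipped.
    """
    groups = metadata.loc[norm.sample_ids, "group"].to_numpy()
    labels = pd.unique(groups)
    if len(labels) < 2:
        raise ValueError("need at least 2 groups")
    rows = []
    for gene in sorted(qualifying_species):
        present = [s for s in sorted(qualifying_species[gene]) if s in norm.values.index]
        if not present:
            rows.append({"gene": gene, "n_species": 0, "F": np.nan, "p": np.nan,
                         "significant": False, "skipped": True})
            continue
        sums = norm.values.loc[present].sum(axis=0).to_numpy()
        if np.ptp(sums) == 0:
            rows.append({"gene": gene, "n_species": len(present), "F": 0.0, "p": 1.0,
                         "significant": False, "skipped": False})
            continue
        f, p = stats.f_oneway(*(sums[groups == g] for g in labels))
        rows.append({"gene": gene, "n_species": len(present), "F": float(f), "p": float(p),
                     "significant": bool(p < alpha), "skipped": False})
    return pd.DataFrame(rows).set_index("gene")
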