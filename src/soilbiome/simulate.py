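"""Synthetic soil-bacteriome datasets with planted, recoverable structure.

The generator emulates the features the pipeline is built to handle:
zero-inflated, overdispersed (negative-binomial) species counts across
sample groups with per-sample size factors; group-specific enriched
species with known fold multipliers; blocks of species boosted jointly
into a sample's top abundance ranks (rank-level co-occurrence, which is
what the association stage consumes); a balanced hierarchical taxonomy;
and per-species gene repertoires.  Everything drawn flows from a single
seeded generator in documented order, so a config + seed fully determines
the dataset, and the planted structure is recorded in a TruthRecord for
recovery testing.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .types import TAXONOMY_RANKS, CountMatrix, validate_gene_profiles, validate_metadata

__all__ = ["SimulationConfig", "TruthRecord", "simulate_dataset", "make_fixture"]

_SOIL_CLASSES = ("Acrisols", "Gleysols", "Ferralsols", "Nitisols", "Histosols")


@dataclass
class SimulationConfig:
    """Knobs of the generator; defaults give a mid-sized 4-group survey."""

    n_groups: int = 4
    samples_per_group: int = 30
    n_species: int = 300
    baseline_mean: float = 30.0
    dispersion: float = 30.0  # negative-binomial size; larger = closer to Poisson
    zero_inflation: float = 0.1
    species_effect_sigma: float = 0.8  # lognormal spread of per-species base abundance
    size_factor_sigma: float = 0.3  # lognormal spread of per-sample depth
    block_boost_mean: float = 600.0  # activated block species: NB mean high enough to rank top-k
    enriched_spec: list = field(default_factory=list)  # (species_idx, group_idx, fold >= 1)
    cooccur_blocks: list = field(default_factory=list)  # (group_idx, [species_idx...], activation)
    richness_shift_spec: list = field(default_factory=list)  # ([species_idx...], group_idx, fold)
    species_mean_scale: dict = field(default_factory=dict)  # species_idx -> multiplier
    species_effect_fixed: dict = field(default_factory=dict)  # species_idx -> effect (pins draw)
    taxonomy_branching: dict = field(
        default_factory=lambda: {"phylum": 5, "class": 2, "order": 2, "family": 2, "genus": 2}
    )
    gene_assignment: dict = field(default_factory=dict)  # species_idx -> [gene symbols]
    seed: int = 0

    def __post_init__(self):
        if self.n_groups < 1 or self.samples_per_group < 1 or self.n_species < 1:
            raise ValueError("n_groups, samples_per_group and n_species must be >= 1")
        if not (0 <= self.zero_inflation < 1):
            raise ValueError("zero_inflation must be in [0, 1)")
        if self.baseline_mean <= 0 or self.dispersion <= 0:
            raise ValueError("baseline_mean and dispersion must be > 0")
        for s, g, fold in self.enriched_spec:
            if fold < 1:
                raise ValueError(f"fold multiplier must be >= 1 (species {s}, group {g})")
            if not (0 <= s < self.n_species) or not (0 <= g < self.n_groups):
                raise ValueError(f"enriched pair ({s}, {g}) out of range")
        per_group_seen: dict[int, set] = {}
        for g, members, act in self.cooccur_blocks:
            members = list(members)
            if len(members) > self.n_species:
                raise ValueError("co-occurrence block larger than n_species")
            if not (0 <= g < self.n_groups):
                raise ValueError(f"block group index {g} out of range")
            if not (0 <= act <= 1):
                raise ValueError("block activation probability must be in [0, 1]")
            if any(not (0 <= s < self.n_species) for s in members):
                raise ValueError("block species index out of range")
            seen = per_group_seen.setdefault(g, set())
            if seen & set(members):
                raise ValueError(f"blocks within group {g} must be disjoint")
            seen |= set(members)


@dataclass
class TruthRecord:
    """Planted ground truth of one simulated dataset (JSON round-trippable)."""

    enriched: list  # [species_id, group_label, fold]
    blocks: list  # {"group": label, "species": [...], "activation": p}
    richness_shift: list  # {"group": label, "species": [...], "fold": f}
    activated_blocks: dict  # sample_id -> [block index...]
    size_factors: dict  # sample_id -> factor
    seed: int

    def enriched_pairs(self) -> set:
        return {(s, g) for s, g, _ in self.enriched}

    def block_pairs(self) -> set:
        """(species, group) pairs whose group abundance a planted block boosts."""
        return {(s, b["group"]) for b in self.blocks for s in b["species"]}

    def planted_pairs(self) -> set:
        """All (species, group) pairs whose group abundance any plant raises."""
        shift = {(s, r["group"]) for r in self.richness_shift for s in r["species"]}
        return self.enriched_pairs() | self.block_pairs() | shift

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "TruthRecord":
        d = json.loads(text)
        d["enriched"] = [tuple(e) for e in d["enriched"]]
        return cls(**d)


def _make_taxonomy(n_species: int, branching: dict) -> pd.DataFrame:
    """Balanced taxonomy: contiguous blocks of species per genus."""
    counts = [max(1, int(branching.get(r, 2))) for r in TAXONOMY_RANKS]
    totals = np.cumprod(counts)  # taxa per rank
    n_genera = int(totals[-1])
    per_genus = int(np.ceil(n_species / n_genera))
    rows = []
    for i in range(n_species):
        genus_idx = min(i // per_genus, n_genera - 1)
        lineage = {}
        idx = genus_idx
        for pos in range(len(TAXONOMY_RANKS) - 1, -1, -1):
            rank = TAXONOMY_RANKS[pos]
            lineage[rank] = f"{rank[0].upper()}{idx + 1:03d}"
            idx //= counts[pos]
        rows.append(lineage)
    tax = pd.DataFrame(rows, index=[f"sp{i + 1:04d}" for i in range(n_species)])
    tax.index.name = "species_id"
    return tax[list(TAXONOMY_RANKS)]


def simulate_dataset(config: SimulationConfig):
    """Generate (CountMatrix, metadata, taxonomy, gene profiles, TruthRecord).

    Draw order from the single generator stream: (1) per-species lognormal
    base-abundance effects, (2) per-sample lognormal size factors, (3)
    per-sample block activations, (4) negative-binomial counts, (5)
    zero-inflation dropout (activated block cells are exempt — a planted
    bloom dominates its sample by construction).
    """
    rng = np.random.default_rng(config.seed)
    n_sp, n_gr, n_per = config.n_species, config.n_groups, config.samples_per_group
    n_samples = n_gr * n_per
    species = [f"sp{i + 1:04d}" for i in range(n_sp)]
    groups = [f"G{g + 1}" for g in range(n_gr)]
    samples, sample_group = [], []
    for g, glab in enumerate(groups):
        for j in range(n_per):
            samples.append(f"{glab}_s{j + 1:02d}")
            sample_group.append(g)

    effects = rng.lognormal(mean=0.0, sigma=config.species_effect_sigma, size=n_sp)
    for idx, val in config.species_effect_fixed.items():
        effects[int(idx)] = float(val)
    for idx, scale in config.species_mean_scale.items():
        effects[int(idx)] *= float(scale)
    size_factors = rng.lognormal(mean=0.0, sigma=config.size_factor_sigma, size=n_samples)

    fold = np.ones((n_sp, n_gr))
    for s, g, f in config.enriched_spec:
        fold[int(s), int(g)] = float(f)
    for members, g, f in config.richness_shift_spec:
        for s in members:
            fold[int(s), int(g)] *= float(f)

    activated: dict[str, list[int]] = {s: [] for s in samples}
    boosted = np.zeros((n_sp, n_samples), dtype=bool)
    for b_idx, (g, members, act) in enumerate(config.cooccur_blocks):
        members = [int(m) for m in members]
        for i, smp in enumerate(samples):
            if sample_group[i] != g:
                continue
            if rng.random() < act:
                activated[smp].append(b_idx)
                boosted[members, i] = True

    mu = (
        config.baseline_mean
        * effects[:, None]
        * size_factors[None, :]
        * fold[:, np.asarray(sample_group)]
    )
    mu = np.where(boosted, config.block_boost_mean * size_factors[None, :], mu)
    size = config.dispersion
    p = size / (size + mu)
    counts = rng.negative_binomial(size, p)
    if config.zero_inflation > 0:
        drop = rng.random(counts.shape) < config.zero_inflation
        counts = np.where(drop & ~boosted, 0, counts)

    cm = CountMatrix(pd.DataFrame(counts, index=species, columns=samples))
    meta = pd.DataFrame(
        {
            "group": [groups[g] for g in sample_group],
            "soil_class": [_SOIL_CLASSES[g % len(_SOIL_CLASSES)] for g in sample_group],
            "ph": np.round(np.clip(rng.normal(6.5, 0.8, n_samples), 3.0, 9.0), 2),
        },
        index=pd.Index(samples, name="sample_id"),
    )
    meta = validate_metadata(meta)
    taxonomy = _make_taxonomy(n_sp, config.taxonomy_branching)
    profiles = validate_gene_profiles(
        {species[int(i)]: set(gs) for i, gs in config.gene_assignment.items()}
    )
    truth = TruthRecord(
        enriched=[[species[int(s)], groups[int(g)], float(f)] for s, g, f in config.enriched_spec],
        blocks=[
            {"group": groups[int(g)], "species": [species[int(m)] for m in members],
             "activation": float(act)}
            for g, members, act in config.cooccur_blocks
        ],
        richness_shift=[
            {"group": groups[int(g)], "species": [species[int(m)] for m in members],
             "fold": float(f)}
            for members, g, f in config.richness_shift_spec
        ],
        activated_blocks=activated,
        size_factors={s: float(f) for s, f in zip(samples, size_factors)},
        seed=config.seed,
    )
    return cm, meta, taxonomy, profiles, truth


# --- named fixtures -------------------------------------------------------

_FIXTURE_SEEDS = {"tiny": 101, "default": 202, "stress": 303}

# genes handed to the planted functional species (nitrogen fixation + Pho)
_FUNCTIONAL_GENES = ["nifD", "nifK", "nifH", "phoR", "phoB"]
_BACKGROUND_GENES = ["dctA", "pstS", "pstC", "pstA", "pstB", "malZ", "soxA", "soxX",
                     "narG", "narH", "narI", "nirB", "nirD", "nosZ", "phoD"]


def _default_config(seed: int) -> SimulationConfig:
    """The `default` fixture: 4 x 30 samples, 300 species, planted effects.

    Planted structure, one signal class per group pair so each recovery
    question has a clean reference population:

    * G1, G2 — four 6-species co-occurrence blocks (two per group,
      activation 0.9): the association-network signal.
    * G3, G4 — eight enriched species (sp0001-sp0004 fold 50 in G3,
      sp0005-sp0008 fold 50 in G4, base effects pinned to 1.0): the
      enrichment signal.
    * G4 — one rare family (sp0225-sp0232 = family F029, base mean scaled
      x0.02) shifted fold 30 into G4, so its members are largely absent
      elsewhere but nearly always detected in G4: the differential
      species-richness signal.
    * G3's enriched species carry nitrogenase + Pho-regulon genes: the
      functional-abundance signal.
    """
    enriched = [(s, 2, 50.0) for s in range(4)] + [(s, 3, 50.0) for s in range(4, 8)]
    family_species = list(range(224, 232))  # the 8 species of family F029
    blocks = [
        (0, list(range(50, 56)), 0.9),
        (0, list(range(60, 66)), 0.9),
        (1, list(range(70, 76)), 0.9),
        (1, list(range(80, 86)), 0.9),
    ]
    gene_assignment: dict[int, list] = {}
    for s in range(4):  # enriched in G3: planted functional-abundance effect
        gene_assignment[s] = list(_FUNCTIONAL_GENES)
    for j, s in enumerate(range(12, 42, 3)):  # background gene-bearing species
        gene_assignment[s] = [_BACKGROUND_GENES[j % len(_BACKGROUND_GENES)],
                              _BACKGROUND_GENES[(j + 3) % len(_BACKGROUND_GENES)]]
    fixed = {s: 1.0 for s in range(8)}
    fixed.update({s: 1.0 for s in family_species})
    # block members sit mid-pack when not activated, so activation alone
    # controls their top-k membership
    fixed.update({s: 1.0 for b in blocks for s in b[1]})
    return SimulationConfig(
        n_groups=4,
        samples_per_group=30,
        n_species=300,
        enriched_spec=enriched,
        cooccur_blocks=blocks,
        richness_shift_spec=[(family_species, 3, 30.0)],
        species_mean_scale={s: 0.02 for s in family_species},
        species_effect_fixed=fixed,
        gene_assignment=gene_assignment,
        seed=seed,
    )


def make_fixture(name: str, seed: int | None = None):
    """Named, versioned fixtures with fixed seeds.

    ``tiny``: 4 groups x 5 samples, 30 species (unit tests).
    ``default``: 4 x 30, 300 species with planted structure (recovery tests).
    ``stress``: 4 x 100, 2000 species (performance checks).
    Passing ``seed`` overrides the fixture's fixed seed (recovery tests
    replicate the same planted structure under fresh noise).
    """
    if name not in _FIXTURE_SEEDS:
        raise ValueError(f"unknown fixture {name!r}; choose from {sorted(_FIXTURE_SEEDS)}")
    seed = _FIXTURE_SEEDS[name] if seed is None else int(seed)
    if name == "tiny":
        cfg = SimulationConfig(
            n_groups=4,
            samples_per_group=5,
            n_species=30,
            enriched_spec=[(0, 0, 25.0), (1, 1, 25.0)],
            cooccur_blocks=[(0, [10, 11, 12], 0.9)],
            taxonomy_branching={"phylum": 2, "class": 2, "order": 1, "family": 2, "genus": 1},
            gene_assignment={0: ["nifD", "nifK", "nifH"], 1: ["phoR", "phoB"]},
            seed=seed,
        )
    elif name == "default":
        cfg = _default_config(seed)
    else:  # stress
        cfg = SimulationConfig(
            n_groups=4,
            samples_per_group=100,
            n_species=2000,
            enriched_spec=[(s, s % 4, 20.0) for s in range(16)],
            cooccur_blocks=[(0, list(range(100, 108)), 0.9)],
            seed=seed,
        )
    return simulate_dataset(cfg)
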