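"""Recovery and calibration harnesses over the synthetic fixtures.

These run the full pipeline stages against the generator's TruthRecord and
summarize how well each planted signal class is recovered: enrichment
sensitivity / false-discovery proportion, co-occurrence block recovery
(pairwise Rand index of community assignments restricted to block
species), richness-shift family detection, and the functional-abundance
ANOVA — plus null-calibration checks with no planted effects.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
from scipy import stats

from .enrichment import enrichment_analysis
from .functional import functional_abundance_anova
from .network import build_group_networks
from .normalization import gmpr_normalize
from .richness import differential_richness_analysis, ilr_balances, balance_tree, richness_matrix
from .simulate import SimulationConfig, make_fixture, simulate_dataset

__all__ = [
    "pairwise_rand_index",
    "evaluate_default_fixture",
    "recovery_summary",
    "enrichment_null_fraction",
    "balance_null_pvalues",
    "functional_null_rate",
]


def pairwise_rand_index(truth_labels, predicted_labels) -> float:
    """Rand index: fraction of item pairs on which two partitions agree."""
    items = list(range(len(truth_labels)))
    if len(items) < 2:
        return 1.0
    agree = total = 0
    for i, j in combinations(items, 2):
        same_t = truth_labels[i] == truth_labels[j]
        same_p = predicted_labels[i] == predicted_labels[j]
        agree += same_t == same_p
        total += 1
    return agree / total


def evaluate_default_fixture(seed: int) -> dict:
    """One replicate: run every stage on the default fixture, score vs truth."""
    counts, meta, tax, genes, truth = make_fixture("default", seed=seed)
    norm = gmpr_normalize(counts)

    enr = enrichment_analysis(norm, meta)
    called = enr.enriched_pairs()
    planted = truth.enriched_pairs()
    union = truth.planted_pairs()
    sensitivity = len(called & planted) / len(planted)
    fdp = len(called - union) / max(len(called), 1)

    nets = build_group_networks(counts, meta)
    rand_scores = []
    block_groups = sorted({b["group"] for b in truth.blocks})
    for g in block_groups:
        blocks = [b for b in truth.blocks if b["group"] == g]
        species = [sp for b in blocks for sp in b["species"]]
        truth_labels = [i for i, b in enumerate(blocks) for _ in b["species"]]
        comm = nets[g].communities
        pred = [comm.get(sp, -1 - k) for k, sp in enumerate(species)]
        rand_scores.append(pairwise_rand_index(truth_labels, pred))

    rich = differential_richness_analysis(counts, tax, meta)
    shifted = truth.richness_shift[0]
    family = tax.loc[shifted["species"][0], "family"]
    family_recovered = family in rich["differential_taxa"]

    bearers = {sp for sp, gs in genes.items() if "nifd" in gs}
    anova = functional_abundance_anova(norm, {"nifd": bearers}, meta, alpha=1e-3)
    functional_significant = bool(anova.loc["nifd", "significant"])

    return {
        "sensitivity": sensitivity,
        "fdp": fdp,
        "rand": float(np.mean(rand_scores)),
        "family_recovered": family_recovered,
        "functional_significant": functional_significant,
    }


def recovery_summary(n_seeds: int = 20, base_seed: int = 1) -> dict:
    """Aggregate recovery metrics over ``n_seeds`` fresh replicates."""
    reps = [evaluate_default_fixture(base_seed + k) for k in range(n_seeds)]
    return {
        "n_seeds": n_seeds,
        "enrichment_sensitivity": float(np.mean([r["sensitivity"] for r in reps])),
        "enrichment_fdp": float(np.mean([r["fdp"] for r in reps])),
        "block_rand_index": float(np.mean([r["rand"] for r in reps])),
        "richness_family_recovery_rate": float(np.mean([r["family_recovered"] for r in reps])),
        "functional_detection_rate": float(np.mean([r["functional_significant"] for r in reps])),
    }


def _null_config(seed: int) -> SimulationConfig:
    """No planted effects, near-Poisson noise (the chi-squared sampling model)."""
    return SimulationConfig(
        n_groups=4,
        samples_per_group=30,
        n_species=200,
        dispersion=1000.0,
        zero_inflation=0.0,
        seed=seed,
    )


def enrichment_null_fraction(seed: int = 0) -> dict:
    """Fraction of species with adjusted p < 0.05 under a no-effect simulation."""
    counts, meta, *_ = simulate_dataset(_null_config(seed))
    norm = gmpr_normalize(counts)
    enr = enrichment_analysis(norm, meta)
    per_species = enr.table.groupby("species_id")["p_adj"].first()
    frac = float((per_species < 0.05).mean())
    se = float(np.sqrt(0.05 * 0.95 / len(per_species)))
    return {"fraction": frac, "n_species": int(len(per_species)), "threshold": 0.05 + 3 * se}


def balance_null_pvalues(n_replicates: int = 500, seed: int = 0) -> np.ndarray:
    """Null p-values of the balance OLS test under shuffled group labels.

    One fixed dataset's balances; each replicate shuffles the group labels
    and records one balance's F-test p-value (rotating through balances to
    avoid re-testing a single contrast).
    """
    counts, meta, tax, *_ = simulate_dataset(
        SimulationConfig(n_groups=4, samples_per_group=15, n_species=120, seed=seed)
    )
    rich = richness_matrix(counts, tax, "family", "species")
    tree = balance_tree(rich)
    balances = ilr_balances(rich, tree, pseudocount=0.5).to_numpy()
    keep = np.ptp(balances, axis=1) > 0
    balances = balances[keep]
    groups = meta.loc[list(rich.columns), "group"].to_numpy()
    labels = np.unique(groups)
    rng = np.random.default_rng(seed + 1)
    pvals = np.empty(n_replicates)
    for r in range(n_replicates):
        perm = rng.permutation(groups)
        row = balances[r % balances.shape[0]]
        _, pvals[r] = stats.f_oneway(*(row[perm == g] for g in labels))
    return pvals


def functional_null_rate(n_replicates: int = 500, alpha: float = 1e-3, seed: int = 0) -> dict:
    """False-positive rate of the functional ANOVA under permuted labels."""
    counts, meta, _, genes, _ = make_fixture("default", seed=seed + 1000)
    norm = gmpr_normalize(counts)
    bearers = sorted(sp for sp, gs in genes.items() if "dcta" in gs)
    sums = norm.values.loc[bearers].sum(axis=0).to_numpy()
    groups = meta.loc[norm.sample_ids, "group"].to_numpy()
    labels = np.unique(groups)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_replicates):
        perm = rng.permutation(groups)
        _, p = stats.f_oneway(*(sums[perm == g] for g in labels))
        hits += p < alpha
    return {"rate": hits / n_replicates, "n_replicates": n_replicates, "alpha": alpha}
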