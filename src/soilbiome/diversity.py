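"""Per-sample alpha diversity and between-group comparison.

Chao1 (bias-corrected) and Shannon's index (natural log) are computed on
raw integer counts — richness estimators need untransformed frequencies.
Groups are compared by one-way ANOVA with Tukey HSD post-hoc pairs; a
compact letter display summarizes the pairwise pattern: two groups share a
letter if and only if their Tukey-adjusted p-value is >= alpha.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from skbio.diversity.alpha import chao1 as _skbio_chao1
from skbio.diversity.alpha import shannon as _skbio_shannon

from .types import CountMatrix

__all__ = ["chao1", "shannon", "diversity_table", "anova_tukey", "GroupComparison"]


def _as_counts(sample_counts) -> np.ndarray:
    x = np.asarray(sample_counts)
    if x.ndim != 1:
        raise ValueError("expected a 1-D vector of counts")
    if (x < 0).any():
        raise ValueError("counts must be non-negative")
    if not (x > 0).any():
        raise ValueError("all-zero sample: diversity undefined")
    return x


def chao1(sample_counts) -> float:
    """Bias-corrected Chao1 richness: S_obs + F1(F1-1) / (2(F2+1))."""
    return float(_skbio_chao1(_as_counts(sample_counts), bias_corrected=True))


def shannon(sample_counts) -> float:
    """Shannon diversity H = -sum p_k ln p_k (natural log)."""
    return float(_skbio_shannon(_as_counts(sample_counts), base=np.e))


def diversity_table(counts: CountMatrix, metadata: pd.DataFrame) -> pd.DataFrame:
    """Per-sample Chao1, log10(Chao1), and Shannon index with group labels."""
    rows = []
    for s in counts.sample_ids:
        c = counts.counts[s].to_numpy()
        c1 = chao1(c)
        rows.append(
            {
                "sample_id": s,
                "chao1": c1,
                "log10_chao1": float(np.log10(c1)),
                "shannon": shannon(c),
                "group": metadata.loc[s, "group"],
            }
        )
    return pd.DataFrame(rows).set_index("sample_id")


@dataclass
class GroupComparison:
    """One-way ANOVA with Tukey HSD pairs and a compact letter display."""

    anova_f: float
    anova_p: float
    tukey: pd.DataFrame  # columns: group_a, group_b, diff, q, p_adj
    letters: dict[str, str]
    alpha: float

    def to_dict(self) -> dict:
        return {
            "anova_f": self.anova_f,
            "anova_p": self.anova_p,
            "alpha": self.alpha,
            "tukey": self.tukey.to_dict(orient="records"),
            "letters": self.letters,
        }


def anova_tukey(values, groups, alpha: float = 1e-3) -> GroupComparison:
    """Compare a metric between groups: ANOVA F + Tukey HSD + letters.

    Tukey-adjusted p-values come from the exact studentized-range
    distribution (scipy), valid at stringent thresholds such as 0.001.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    labels = sorted(pd.unique(groups))
    if len(labels) < 2:
        raise ValueError("need at least 2 groups")
    per_group = {g: values[groups == g] for g in labels}
    for g, v in per_group.items():
        if len(v) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 values")

    if np.ptp(values) == 0:  # fully constant data: no variation to test
        f_stat, p = 0.0, 1.0
    else:
        f_stat, p = stats.f_oneway(*(per_group[g] for g in labels))
        f_stat, p = float(f_stat), float(p)

    k = len(labels)
    n_total = len(values)
    df_within = n_total - k
    mse = (
        sum(((v - v.mean()) ** 2).sum() for v in per_group.values()) / df_within
        if df_within > 0
        else 0.0
    )
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            a, b = labels[i], labels[j]
            va, vb = per_group[a], per_group[b]
            diff = float(vb.mean() - va.mean())
            se = np.sqrt(mse / 2.0 * (1.0 / len(va) + 1.0 / len(vb)))
            if se == 0:
                q = 0.0 if diff == 0 else np.inf
            else:
                q = abs(diff) / se
            p_adj = float(stats.studentized_range.sf(q, k, df_within)) if np.isfinite(q) else 0.0
            rows.append({"group_a": a, "group_b": b, "diff": diff, "q": float(q), "p_adj": p_adj})
    tukey = pd.DataFrame(rows)

    # letter display: maximal cliques of the non-significance graph
    ns = nx.Graph()
    ns.add_nodes_from(labels)
    for r in rows:
        if r["p_adj"] >= alpha:
            ns.add_edge(r["group_a"], r["group_b"])
    cliques = sorted((sorted(c) for c in nx.find_cliques(ns)), key=lambda c: (labels.index(c[0]), c))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    letters = {g: "" for g in labels}
    for idx, clique in enumerate(cliques):
        for g in clique:
            letters[g] += alphabet[idx % len(alphabet)]
    return GroupComparison(anova_f=f_stat, anova_p=p, tukey=tukey, letters=letters, alpha=alpha)
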