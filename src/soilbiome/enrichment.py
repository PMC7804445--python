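"""Species enrichment calling on GMPR-normalized group abundance.

A species is *enriched* in a group when (1) its observed group-summed
normalized abundance deviates from the margin-derived expectation by a
chi-squared test at a stringent adjusted threshold, and (2) its residual
in that group is a positive outlier beyond Q3 + fence_multiplier x IQR of
a reference residual population.  The two-stage rule separates "any
deviation" (the omnibus chi-squared) from "over-represented *here*"
(the per-group outlier fence).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .types import NormalizedMatrix

__all__ = [
    "contingency_matrix",
    "chisq_per_species",
    "adjust_pvalues",
    "pearson_residuals",
    "call_enriched",
    "EnrichmentTable",
]


def contingency_matrix(norm: NormalizedMatrix, metadata: pd.DataFrame) -> pd.DataFrame:
    """Species x group matrix of summed normalized abundance."""
    missing = [s for s in norm.sample_ids if s not in metadata.index]
    if missing:
        raise ValueError(f"samples missing from metadata: {missing}")
    groups = metadata.loc[norm.sample_ids, "group"]
    observed = norm.values.T.groupby(groups.to_numpy()).sum().T
    observed = observed[sorted(observed.columns)]
    if observed.to_numpy().sum() <= 0:
        raise ValueError("contingency matrix has zero grand total")
    return observed


def expected_matrix(observed: pd.DataFrame) -> pd.DataFrame:
    """Margin-product expectation E[s,g] = rowtotal(s) * coltotal(g) / grand."""
    row = observed.sum(axis=1).to_numpy()
    col = observed.sum(axis=0).to_numpy()
    grand = row.sum()
    if (col <= 0).any():
        bad = observed.columns[int(np.argmax(col <= 0))]
        raise ValueError(f"group {bad!r} has zero column total")
    return pd.DataFrame(
        np.outer(row, col) / grand, index=observed.index, columns=observed.columns
    )


def chisq_per_species(observed: pd.DataFrame) -> pd.DataFrame:
    """Per-species goodness-of-fit chi-squared against the margin expectation.

    Rows with zero total are excluded from testing (statistic/p set to NaN);
    df = n_groups - 1 for the tested rows.
    """
    expected = expected_matrix(observed)
    obs = observed.to_numpy(dtype=float)
    exp = expected.to_numpy(dtype=float)
    tested = obs.sum(axis=1) > 0
    df = observed.shape[1] - 1
    stat = np.full(obs.shape[0], np.nan)
    with np.errstate(invalid="ignore", divide="ignore"):
        stat[tested] = np.nansum((obs[tested] - exp[tested]) ** 2 / exp[tested], axis=1)
    p = np.where(tested, stats.chi2.sf(stat, df), np.nan)
    return pd.DataFrame(
        {"statistic": stat, "df": df, "p": p, "tested": tested}, index=observed.index
    )


def adjust_pvalues(p, method: str = "bh") -> np.ndarray:
    """Multiple-testing adjustment: Benjamini-Hochberg (default) or Bonferroni.

    NaN entries (untested species) are passed through as NaN.
    """
    p = np.asarray(p, dtype=float)
    key = {"bh": "fdr_bh", "fdr_bh": "fdr_bh", "bonferroni": "bonferroni"}.get(method)
    if key is None:
        raise ValueError(f"unknown adjustment method {method!r}; use 'bh' or 'bonferroni'")
    out = np.full_like(p, np.nan)
    mask = ~np.isnan(p)
    if mask.any():
        out[mask] = multipletests(p[mask], method=key)[1]
    return out


def pearson_residuals(observed: pd.DataFrame, mode: str = "standardized") -> pd.DataFrame:
    """Residual matrix: (O - E)/sqrt(E) (standardized, default) or O - E (raw)."""
    expected = expected_matrix(observed)
    diff = observed - expected
    if mode == "raw":
        return diff
    if mode != "standardized":
        raise ValueError("mode must be 'standardized' or 'raw'")
    with np.errstate(invalid="ignore", divide="ignore"):
        r = diff / np.sqrt(expected)
    return r.fillna(0.0)


@dataclass
class EnrichmentTable:
    """Long-format per-(species, group) enrichment results.

    ``table`` columns: species_id, group, observed, expected, residual, p,
    p_adj, significant, enriched.  ``fences`` holds (Q1, Q3, IQR, fence)
    per reference population.
    """

    table: pd.DataFrame
    fences: pd.DataFrame
    alpha: float
    fence_multiplier: float
    reference: str

    def enriched_pairs(self) -> set[tuple[str, str]]:
        flagged = self.table[self.table["enriched"]]
        return set(zip(flagged["species_id"], flagged["group"]))


def _fence(values: np.ndarray, multiplier: float) -> tuple[float, float, float, float]:
    q1, q3 = np.percentile(values, [25, 75])  # linear-interpolation (type-7) quantiles
    iqr = q3 - q1
    return float(q1), float(q3), float(iqr), float(q3 + multiplier * iqr)


def call_enriched(
    observed: pd.DataFrame,
    residuals: pd.DataFrame,
    p_adj: pd.Series,
    alpha: float = 1e-6,
    fence_multiplier: float = 1.0,
    reference: str = "group",
) -> EnrichmentTable:
    """Flag (species, group) cells enriched by significance + outlier fence.

    A cell is enriched iff the species' adjusted p < alpha AND its residual
    strictly exceeds Q3 + fence_multiplier * IQR of the reference residual
    population: all residuals of significant species within the same group
    (``reference='group'``, default), within the same species row
    (``'species'``), or over all significant cells (``'global'``).
    """
    if reference not in ("group", "species", "global"):
        raise ValueError("reference must be 'group', 'species' or 'global'")
    sig = (p_adj < alpha).fillna(False)
    long = observed.stack().rename("observed").reset_index()
    long.columns = ["species_id", "group", "observed"]
    exp_long = expected_matrix(observed).stack().to_numpy()
    res_long = residuals.stack().to_numpy()
    long["expected"] = exp_long
    long["residual"] = res_long
    long["p_adj"] = p_adj.reindex(long["species_id"]).to_numpy()
    long["significant"] = sig.reindex(long["species_id"]).to_numpy()

    fences = []
    enriched = np.zeros(len(long), dtype=bool)
    sig_rows = long[long["significant"]]
    if len(sig_rows) > 0:
        if reference == "group":
            scopes = [(g, sig_rows[sig_rows["group"] == g]) for g in observed.columns]
        elif reference == "species":
            scopes = [(s, sig_rows[sig_rows["species_id"] == s])
                      for s in sig_rows["species_id"].unique()]
        else:
            scopes = [("all", sig_rows)]
        for name, rows in scopes:
            if len(rows) == 0:
                continue
            q1, q3, iqr, fence = _fence(rows["residual"].to_numpy(), fence_multiplier)
            fences.append({"reference": name, "q1": q1, "q3": q3, "iqr": iqr, "fence": fence})
            enriched[rows.index[rows["residual"] > fence]] = True
    long["enriched"] = enriched
    fences_df = pd.DataFrame(fences, columns=["reference", "q1", "q3", "iqr", "fence"])
    return EnrichmentTable(
        table=long,
        fences=fences_df,
        alpha=alpha,
        fence_multiplier=fence_multiplier,
        reference=reference,
    )


def enrichment_analysis(
    norm: NormalizedMatrix,
    metadata: pd.DataFrame,
    alpha: float = 1e-6,
    fence_multiplier: float = 1.0,
    p_adjust_method: str = "bh",
    residual_mode: str = "standardized",
    reference: str = "group",
) -> EnrichmentTable:
    """Full enrichment stage: group sums -> chi-squared -> fence calling."""
    observed = contingency_matrix(norm, metadata)
    tests = chisq_per_species(observed)
    p_adj = pd.Series(adjust_pvalues(tests["p"], p_adjust_method), index=observed.index)
    residuals = pearson_residuals(observed, mode=residual_mode)
    return call_enriched(
        observed,
        residuals,
        p_adj,
        alpha=alpha,
        fence_multiplier=fence_multiplier,
        reference=reference,
    )
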