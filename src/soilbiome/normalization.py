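"""OTU aggregation and GMPR size-factor normalization.

GMPR (geometric mean of pairwise ratios) computes, for every ordered
sample pair (i, j), the median count ratio over the taxa observed in both,
and takes sample i's size factor as the geometric mean of these medians
over all valid partners j.  Unlike a straight geometric-mean (DESeq-style)
factor it never conditions on taxa shared by *all* samples, which makes it
robust on the zero-inflated matrices typical of environmental surveys.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .types import CountMatrix, NormalizedMatrix

__all__ = ["aggregate_otus", "gmpr_size_factors", "normalize", "gmpr_normalize"]


def aggregate_otus(otu_counts: CountMatrix, otu_to_species: dict[str, str]) -> CountMatrix:
    """Sum OTU-level read counts into species-level counts.

    Every OTU id must be mapped; column (per-sample) totals are preserved.
    Species rows appear in order of first OTU occurrence.
    """
    unmapped = [o for o in otu_counts.species_ids if o not in otu_to_species]
    if unmapped:
        raise ValueError(f"unmapped OTU ids: {unmapped}")
    species = [otu_to_species[o] for o in otu_counts.species_ids]
    grouped = otu_counts.counts.groupby(pd.Index(species, name="species_id"), sort=False).sum()
    return CountMatrix(grouped)


def gmpr_size_factors(counts: CountMatrix, min_shared: int = 1) -> pd.Series:
    """GMPR size factors, rescaled to geometric mean 1.

    For samples i, j let ``r_ij = median_k counts[k,i] / counts[k,j]`` over
    taxa k nonzero in both; ``s_i`` is the geometric mean of the ``r_ij``
    over all valid j — including the trivial self-ratio ``r_ii = 1``, as in
    the reference GMPR implementation, which makes the factors exactly
    scale-equivariant.  Pairs sharing fewer than ``min_shared`` taxa are
    excluded; a sample with no valid partner at all is an error.
    """
    x = counts.counts.to_numpy(dtype=float)
    n = x.shape[1]
    masked = np.where(x > 0, x, np.nan)
    log_medians = np.full((n, n), np.nan)
    for i in range(n):
        # count ratios of sample i against every other sample, NaN where not shared;
        # the median interpolates linearly (type-7) on the ratio scale
        ratios = masked[:, [i]] / masked  # species x samples
        shared = np.sum(~np.isnan(ratios), axis=0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            med = np.log(np.nanmedian(ratios, axis=0))
        med[shared < min_shared] = np.nan
        log_medians[i] = med
    np.fill_diagonal(log_medians, np.nan)
    valid = ~np.isnan(log_medians)
    n_partners = valid.sum(axis=1)
    if (n_partners == 0).any():
        bad = [s for s, k in zip(counts.sample_ids, n_partners) if k == 0]
        raise ValueError(
            f"samples sharing fewer than {min_shared} nonzero taxa with every other sample: {bad}"
        )
    # self-ratio log r_ii = 0 contributes to the mean's denominator
    log_s = np.nansum(np.where(valid, log_medians, 0.0), axis=1) / (n_partners + 1)
    log_s -= log_s.mean()  # rescale to geometric mean 1
    return pd.Series(np.exp(log_s), index=counts.sample_ids, name="size_factor")


def normalize(counts: CountMatrix, size_factors: pd.Series, min_shared: int = 1) -> NormalizedMatrix:
    """Divide each sample column by its size factor."""
    if list(size_factors.index) != counts.sample_ids:
        raise ValueError("size factors must be indexed by the matrix's sample ids")
    values = counts.counts.astype(float).div(size_factors, axis=1)
    return NormalizedMatrix(values=values, size_factors=size_factors, min_shared=min_shared)


def gmpr_normalize(counts: CountMatrix, min_shared: int = 1) -> NormalizedMatrix:
    """Convenience: GMPR size factors + normalization in one call."""
    s = gmpr_size_factors(counts, min_shared=min_shared)
    return normalize(counts, s, min_shared=min_shared)
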