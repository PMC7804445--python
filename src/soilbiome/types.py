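"""Core domain types shared across the pipeline.

The canonical in-memory containers are pandas objects with a documented
orientation: count matrices are species x samples, metadata is indexed by
sample id, taxonomy by species id.  Thin wrapper classes enforce the
invariants once, at construction, so downstream stages can assume them.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from typing import Mapping

import numpy as np
import pandas as pd

TAXONOMY_RANKS = ("phylum", "class", "order", "family", "genus")

__all__ = [
    "TAXONOMY_RANKS",
    "CountMatrix",
    "NormalizedMatrix",
    "PipelineConfig",
    "validate_metadata",
    "validate_taxonomy",
    "validate_gene_profiles",
]


def _check_unique(ids, what: str) -> None:
    seen = set()
    for i in ids:
        if i in seen:
            raise ValueError(f"duplicate {what} id: {i!r}")
        seen.add(i)


class CountMatrix:
    """Integer species x sample abundance table.

    Parameters
    ----------
    counts : pandas.DataFrame
        Rows indexed by species id, columns by sample id, non-negative
        integer cells.  Row/column order is preserved.
    """

    def __init__(self, counts: pd.DataFrame):
        if counts.shape[0] < 1 or counts.shape[1] < 1:
            raise ValueError("count matrix must have at least 1 species and 1 sample")
        _check_unique(counts.index, "species")
        _check_unique(counts.columns, "sample")
        values = counts.to_numpy()
        if not np.issubdtype(values.dtype, np.integer):
            # accept float dtypes only when every cell is an exact integer
            if not np.all(np.isfinite(values)) or not np.all(values == np.floor(values)):
                bad = np.argwhere(values != np.floor(values))
                r, c = bad[0] if len(bad) else (0, 0)
                raise ValueError(
                    f"non-integer count at species {counts.index[r]!r}, "
                    f"sample {counts.columns[c]!r}"
                )
            counts = counts.astype(np.int64)
            values = counts.to_numpy()
        if (values < 0).any():
            r, c = np.argwhere(values < 0)[0]
            raise ValueError(
                f"negative count at species {counts.index[r]!r}, sample {counts.columns[c]!r}"
            )
        self.counts = counts.copy()
        self.counts.index = self.counts.index.astype(str)
        self.counts.columns = self.counts.columns.astype(str)

    @property
    def species_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def __eq__(self, other) -> bool:
        return isinstance(other, CountMatrix) and self.counts.equals(other.counts)

    def __repr__(self) -> str:  # pragma: no cover
        return f"CountMatrix({self.shape[0]} species x {self.shape[1]} samples)"


@dataclass
class NormalizedMatrix:
    """GMPR-normalized abundance table.

    ``values[s, i] = counts[s, i] / size_factors[i]``; size factors are
    strictly positive and rescaled to geometric mean 1.
    """

    values: pd.DataFrame
    size_factors: pd.Series
    min_shared: int = 1

    def __post_init__(self):
        if (self.size_factors <= 0).any():
            bad = self.size_factors.index[self.size_factors <= 0][0]
            raise ValueError(f"non-positive size factor for sample {bad!r}")
        if list(self.values.columns) != list(self.size_factors.index):
            raise ValueError("size factor index must match sample columns")

    @property
    def species_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)


def validate_metadata(meta: pd.DataFrame) -> pd.DataFrame:
    """Validate a sample metadata table (index: sample_id).

    Requires a non-empty ``group`` column; ``soil_class`` and ``ph`` are
    optional pass-through annotations (``ph`` constrained to [0, 14] when
    present).  Extra columns are preserved untouched.
    """
    if "group" not in meta.columns:
        raise ValueError(f"metadata requires a 'group' column; found {list(meta.columns)}")
    _check_unique(meta.index, "sample")
    if meta["group"].isna().any() or (meta["group"].astype(str).str.len() == 0).any():
        raise ValueError("every sample must have a non-empty group label")
    if "ph" in meta.columns:
        ph = pd.to_numeric(meta["ph"], errors="coerce")
        ok = ph.isna() | ((ph >= 0) & (ph <= 14))
        if not ok.all():
            bad = meta.index[~ok][0]
            raise ValueError(f"pH outside [0, 14] for sample {bad!r}")
        meta = meta.assign(ph=ph)
    meta = meta.copy()
    meta.index = meta.index.astype(str)
    meta["group"] = meta["group"].astype(str)
    return meta


def validate_taxonomy(tax: pd.DataFrame) -> pd.DataFrame:
    """Validate a taxonomy lineage table (index: species_id).

    Requires the ``phylum`` column; lower ranks may be missing (NaN).
    """
    missing = [r for r in TAXONOMY_RANKS if r not in tax.columns]
    if missing:
        raise ValueError(f"taxonomy requires columns {list(TAXONOMY_RANKS)}; missing {missing}")
    _check_unique(tax.index, "species")
    tax = tax.copy()
    tax.index = tax.index.astype(str)
    return tax


def canonical_gene(symbol: str) -> str:
    """Canonical form for gene-symbol matching (case-insensitive)."""
    return symbol.strip().lower()


def validate_gene_profiles(profiles: Mapping[str, set]) -> dict[str, frozenset]:
    """Validate species -> gene-set profiles; symbols are canonicalized."""
    out: dict[str, frozenset] = {}
    for sp, genes in profiles.items():
        if sp in out:
            raise ValueError(f"duplicate species id in gene profiles: {sp!r}")
        out[str(sp)] = frozenset(canonical_gene(g) for g in genes if str(g).strip())
    return out


@dataclass
class PipelineConfig:
    """All stage thresholds in one place, serialized into every output.

    Defaults follow the published analysis: association rules kept at
    support > 0.3 and confidence > 0.7 over top-20 transactions, enrichment
    and balance-shift significance at adjusted/raw P < 1e-6, functional
    ANOVA at P < 0.001, and an outlier fence of Q3 + 1.0 x IQR.
    """

    top_k: int = 20
    min_support: float = 0.3
    min_confidence: float = 0.7
    enrich_alpha: float = 1e-6
    richness_alpha: float = 1e-6
    functional_alpha: float = 1e-3
    diversity_alpha: float = 1e-3
    fence_multiplier: float = 1.0
    p_adjust_method: str = "bh"
    min_shared: int = 1
    pseudocount: float = 0.5
    residual_mode: str = "standardized"
    fence_reference: str = "group"
    parent_rank: str = "family"
    child_rank: str = "species"
    seed: int = 0

    def __post_init__(self):
        if not (0 < self.min_support < 1):
            raise ValueError("min_support must be in (0, 1)")
        if not (0 < self.min_confidence < 1):
            raise ValueError("min_confidence must be in (0, 1)")
        if self.top_k < 2:
            raise ValueError("top_k must be >= 2")
        for name in ("enrich_alpha", "richness_alpha", "functional_alpha", "diversity_alpha"):
            a = getattr(self, name)
            if not (0 < a < 1):
                raise ValueError(f"{name} must be in (0, 1)")
        if self.p_adjust_method not in ("bh", "bonferroni"):
            raise ValueError("p_adjust_method must be 'bh' or 'bonferroni'")
        if self.residual_mode not in ("standardized", "raw"):
            raise ValueError("residual_mode must be 'standardized' or 'raw'")
        if self.fence_reference not in ("group", "species", "global"):
            raise ValueError("fence_reference must be 'group', 'species' or 'global'")
        if self.pseudocount <= 0:
            raise ValueError("pseudocount must be > 0")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        return cls(**d)
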