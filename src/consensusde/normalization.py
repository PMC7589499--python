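"""Low-count filtering, RLE (median-of-ratios) size factors, and log-CPM.

Normalization follows the relative log expression convention: a reference
pseudo-library is formed from the gene-wise geometric means over genes that
are positive in every library, each library's raw factor is the median of
its count-to-reference ratios, and factors are rescaled to geometric mean
one. The effective library size of library j is s_j times the geometric
mean of the raw library sums, which coincides with the usual
"raw sum × normalization factor" effective size of the count framework.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import NormalizationError
from .io import CountMatrix


@dataclass
class NormalizationFactors:
    """Per-library RLE size factors and effective library sizes."""

    library_ids: list[str]
    size_factors: np.ndarray      # geometric mean 1
    effective_lib_sizes: np.ndarray

    def __post_init__(self) -> None:
        self.size_factors = np.asarray(self.size_factors, dtype=float)
        self.effective_lib_sizes = np.asarray(self.effective_lib_sizes, dtype=float)
        if not np.all(np.isfinite(self.size_factors)) or np.any(self.size_factors <= 0):
            raise NormalizationError("size factors must be finite and positive")
        log_gm = np.mean(np.log(self.size_factors))
        if abs(log_gm) > 1e-10:
            raise NormalizationError("size factors must have geometric mean 1")


def filter_low_counts(counts: CountMatrix, min_total: int = 10) -> CountMatrix:
    """Drop genes whose total count across the supplied libraries is < ``min_total``.

    Filtering is relative to whatever library subset is passed in, so each
    analysis (every 4vs4 replicate selection, the full-design run) defines
    its own filtered gene universe.
    """
    totals = counts.counts.sum(axis=1)
    return counts.subset_genes(totals >= min_total)


def rle_factors(counts: CountMatrix) -> NormalizationFactors:
    """Median-of-ratios size factors, rescaled to geometric mean one.

    Raises :class:`NormalizationError` when no gene is positive in every
    library (the reference geometric means would all be zero).
    """
    c = counts.counts.astype(float)
    positive = np.all(c > 0, axis=1)
    if not positive.any():
        raise NormalizationError(
            "RLE normalization needs at least one gene with positive counts "
            "in every library; none found"
        )
    ref = np.exp(np.mean(np.log(c[positive]), axis=1))  # gene-wise geometric means
    ratios = c[positive] / ref[:, None]
    raw = np.median(ratios, axis=0)
    size_factors = raw / np.exp(np.mean(np.log(raw)))
    lib_sums = counts.counts.sum(axis=0).astype(float)
    geo_sum = np.exp(np.mean(np.log(lib_sums)))
    effective = size_factors * geo_sum
    return NormalizationFactors(list(counts.library_ids), size_factors, effective)


def log_cpm(counts: CountMatrix, factors: NormalizationFactors,
            prior: float = 0.5) -> np.ndarray:
    """log2 counts-per-million: log2((c + prior) / (effective_size + 1) * 1e6)."""
    if factors.library_ids != counts.library_ids:
        raise NormalizationError("factors were computed on different libraries")
    c = counts.counts.astype(float)
    denom = factors.effective_lib_sizes + 1.0
    return np.log2((c + prior) / denom[None, :] * 1e6)


def pseudo_counts(counts: CountMatrix, factors: NormalizationFactors) -> np.ndarray:
    """Counts rescaled to a common (mean) effective library size.

    Fractional values are rounded half-to-even, so equal-size libraries
    pass through unchanged. Used by the conditional-likelihood dispersion
    estimators and the exact test, which require exchangeable libraries.
    """
    if factors.library_ids != counts.library_ids:
        raise NormalizationError("factors were computed on different libraries")
    target = factors.effective_lib_sizes.mean()
    scale = target / factors.effective_lib_sizes
    return np.round(counts.counts * scale[None, :]).astype(np.int64)
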