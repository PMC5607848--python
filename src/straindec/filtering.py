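"""Coverage-based filtering of putative single-copy core genes.

Single-copy core genes of a target species should share one coverage
profile across samples; genes recruiting reads from unassembled relatives
show inflated coverage in some samples. The filter flags, per sample, genes
whose absolute deviation from the per-sample median coverage exceeds ``t``
times the median of those deviations (a median-absolute-deviation rule),
and keeps a gene only if it is unflagged in at least a fraction ``f`` of
samples. Samples whose mean core-gene coverage is at or below a floor can
be dropped entirely before haplotype inference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import CoverageMatrix


@dataclass
class FilterConfig:
    """Parameters of the core-gene coverage filter.

    t: outlier multiplier on the median absolute deviation (default 2.5).
    f: minimum fraction of samples in which a gene must be unflagged (0.8).
    min_mean_coverage: per-sample floor on mean core-gene coverage (5.0);
        samples at or below the floor are excluded (strict ``>``).
    """

    t: float = 2.5
    f: float = 0.8
    min_mean_coverage: float = 5.0

    def __post_init__(self) -> None:
        if self.t <= 0:
            raise ValueError("t must be positive")
        if not 0 < self.f <= 1:
            raise ValueError("f must be in (0, 1]")
        if self.min_mean_coverage < 0:
            raise ValueError("min_mean_coverage must be non-negative")


def mad_flags(values: np.ndarray, t: float) -> np.ndarray:
    """Boolean flag matrix (genes × samples) under the MAD outlier rule.

    A gene h is flagged in sample s iff |x_{h,s} − median_h x| exceeds
    t × median_h |x_{h,s} − median_h x|. When the median deviation is 0
    (identical-coverage cores) any nonzero deviation is flagged: perfectly
    concordant cores should agree exactly, and the strict ``>`` keeps the
    single-gene case unflagged.
    """
    x = np.asarray(values, dtype=float)
    med = np.median(x, axis=0)  # even-length vectors: mean of central pair
    div = np.abs(x - med)
    div_med = np.median(div, axis=0)
    return div > t * div_med


def mad_filter_genes(
    cov: CoverageMatrix, cfg: FilterConfig | None = None
) -> tuple[list[str], np.ndarray]:
    """Return (kept gene ids, flag matrix) under the MAD rule.

    A gene is kept iff it is unflagged in at least a fraction ``cfg.f`` of
    samples; removal is global (the gene is dropped for every sample).
    """
    cfg = cfg or FilterConfig()
    if cov.values.size == 0:
        raise ValueError("cannot filter an empty coverage matrix")
    flags = mad_flags(cov.values, cfg.t)
    frac_unflagged = 1.0 - flags.mean(axis=1)
    kept = [g for g, ok in zip(cov.gene_ids, frac_unflagged >= cfg.f) if ok]
    return kept, flags


def filter_low_coverage_samples(
    cov: CoverageMatrix, cfg: FilterConfig | None = None
) -> list[str]:
    """Samples whose mean core-gene coverage strictly exceeds the floor."""
    cfg = cfg or FilterConfig()
    means = cov.values.mean(axis=0) if cov.values.size else np.zeros(len(cov.samples))
    return [s for s, m in zip(cov.samples, means) if m > cfg.min_mean_coverage]
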