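"""Consecutive-SNP detection of runs of homozygosity (ROH).

A ROH is a maximal stretch of consecutive markers, starting and ending on a
homozygous call, that contains at most ``max_het_in_run`` heterozygous and
``max_missing_in_run`` missing calls, with no inter-marker gap above
``max_gap_bp``.  Runs must span at least ``min_length_bp`` and contain at
least ``min_snps`` markers.

The SNP-count floor is calibrated so that the expected number of
chance-homozygosity runs across the whole dataset stays below a false
positive budget ``alpha``:

    l = ceil( ln(alpha / (n_s * n_i)) / ln(1 - het_bar) )

where ``n_s`` is the number of genotyped SNPs per individual, ``n_i`` the
number of individuals, and ``het_bar`` the mean per-SNP heterozygosity —
the probability that ``l`` consecutive markers are homozygous by chance in
one individual is (1 - het_bar)^l, and there are about n_s * n_i places for
that to happen.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .datamodel import MISSING, GenotypeDataset

__all__ = [
    "ROHDetectionConfig",
    "ROHSegment",
    "min_snp_count",
    "detect_roh",
    "roh_length",
]


def min_snp_count(n_s: int, n_i: int, alpha: float, mean_het: float) -> int:
    """Minimum number of SNPs per run for a dataset-wide false-positive
    budget of ``alpha``.

    Returns ``ceil(ln(alpha / (n_s * n_i)) / ln(1 - mean_het))``, floored
    at 1.  Ceiling rounding because the result is a minimum count.
    """
    if n_s < 1 or n_i < 1:
        raise ValueError("n_s and n_i must be >= 1")
    if not (0 < alpha < 1):
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    if not (0 < mean_het < 1):
        raise ValueError(f"mean_het must be in (0, 1), got {mean_het}")
    l = (math.log(alpha) - math.log(n_s) - math.log(n_i)) / math.log1p(-mean_het)
    return max(1, math.ceil(l))


@dataclass(frozen=True)
class ROHDetectionConfig:
    """Detection thresholds.

    ``min_snps=None`` means: compute it from the data with
    :func:`min_snp_count`, using ``mean_het`` (itself computed from the
    data when ``None``).  ``max_gap_bp`` caps the physical distance between
    adjacent in-run markers so a run cannot bridge an assay desert.
    """

    alpha: float = 0.05
    mean_het: float | None = None
    min_length_bp: int = 500_000
    max_het_in_run: int = 1
    max_missing_in_run: int = 1
    min_snps: int | None = None
    max_gap_bp: int = 1_000_000

    def __post_init__(self):
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")
        if self.mean_het is not None and not (0 < self.mean_het < 1):
            raise ValueError("mean_het must be in (0, 1)")
        if self.min_length_bp <= 0:
            raise ValueError("min_length_bp must be positive")
        if self.min_snps is not None and self.min_snps < 1:
            raise ValueError("min_snps must be >= 1")
        if self.max_het_in_run < 0 or self.max_missing_in_run < 0:
            raise ValueError("allowances must be >= 0")

    def resolve(self, dataset: GenotypeDataset) -> "ROHDetectionConfig":
        """Fill in data-derived fields (mean_het, min_snps)."""
        het = self.mean_het
        if het is None:
            het = dataset.mean_heterozygosity()
            het = min(max(het, 1e-9), 1 - 1e-9)
        snps = self.min_snps
        if snps is None:
            snps = min_snp_count(dataset.n_markers, dataset.n_samples, self.alpha, het)
        return replace(self, mean_het=het, min_snps=snps)


@dataclass(frozen=True)
class ROHSegment:
    """One homozygous run in one individual.

    ``start_bp``/``end_bp`` are the positions of the first and last marker
    of the run (both homozygous calls); ``n_snps`` counts every marker
    spanned, including any tolerated heterozygous/missing ones.
    """

    sample_id: str
    chrom: str
    start_bp: int
    end_bp: int
    n_snps: int
    n_het: int = 0
    n_missing: int = 0

    def __post_init__(self):
        if self.end_bp <= self.start_bp:
            raise ValueError("segment end must exceed start")


def roh_length(segment: ROHSegment) -> int:
    """Physical run length in bp: end - start (no +1)."""
    return segment.end_bp - segment.start_bp


def _scan_block(
    calls: np.ndarray, bp: np.ndarray, cfg: ROHDetectionConfig
) -> list[tuple[int, int, int, int]]:
    """All maximal qualifying windows within one gap-free block of one
    chromosome for one individual.

    Returns (start_idx, end_idx, n_het, n_missing) tuples.  A window
    qualifies if it starts and ends on a homozygous call and respects the
    het/missing allowances; it is emitted only if no longer qualifying
    window contains it and it passes the SNP-count and length floors.
    """
    n = calls.size
    is_het = calls == 1
    is_miss = calls == MISSING
    is_hom = ~is_het & ~is_miss

    # prev_hom[j]: largest hom index <= j, or -1
    prev_hom = np.where(is_hom, np.arange(n), -1)
    np.maximum.accumulate(prev_hom, out=prev_hom)

    het_cum = np.concatenate([[0], np.cumsum(is_het)])
    miss_cum = np.concatenate([[0], np.cumsum(is_miss)])

    out: list[tuple[int, int, int, int]] = []
    best_end = -1
    j_raw = -1  # farthest index with counts within allowances for current i
    for i in range(n):
        if not is_hom[i]:
            continue
        if j_raw < i:
            j_raw = i
        while j_raw + 1 < n:
            if het_cum[j_raw + 2] - het_cum[i] > cfg.max_het_in_run:
                break
            if miss_cum[j_raw + 2] - miss_cum[i] > cfg.max_missing_in_run:
                break
            j_raw += 1
        j = int(prev_hom[j_raw])  # trim trailing non-hom calls
        if j <= best_end:
            continue  # contained in a previously emitted window
        best_end = j
        if j - i + 1 < cfg.min_snps:
            continue
        if bp[j] - bp[i] < cfg.min_length_bp:
            continue
        n_het = int(het_cum[j + 1] - het_cum[i])
        n_miss = int(miss_cum[j + 1] - miss_cum[i])
        out.append((i, j, n_het, n_miss))
    return out


def detect_roh(
    dataset: GenotypeDataset, config: ROHDetectionConfig | None = None
) -> list[ROHSegment]:
    """Detect ROH for every individual with the consecutive-SNP scan.

    Markers are processed per chromosome in map order; positions with an
    inter-marker gap above ``max_gap_bp`` split the chromosome into blocks
    a run cannot cross.  Output is sorted by (sample order, chrom order,
    start).
    """
    cfg = (config or ROHDetectionConfig()).resolve(dataset)
    chrom_cols = dataset.chrom_indices()
    bp_all = np.array([m.bp for m in dataset.markers], dtype=np.int64)

    segments: list[ROHSegment] = []
    for si, sid in enumerate(dataset.samples):
        row = dataset.calls[si]
        for chrom, cols in chrom_cols.items():
            bp = bp_all[cols]
            calls = row[cols]
            # split at oversized gaps
            breaks = np.flatnonzero(np.diff(bp) > cfg.max_gap_bp)
            starts = np.concatenate([[0], breaks + 1])
            ends = np.concatenate([breaks + 1, [bp.size]])
            for a, b in zip(starts, ends):
                for i, j, nh, nm in _scan_block(calls[a:b], bp[a:b], cfg):
                    segments.append(
                        ROHSegment(
                            sample_id=sid,
                            chrom=chrom,
                            start_bp=int(bp[a + i]),
                            end_bp=int(bp[a + j]),
                            n_snps=j - i + 1,
                            n_het=nh,
                            n_missing=nm,
                        )
                    )
    return segments


def segments_frame(segments: list[ROHSegment]):
    """Segments as a DataFrame with a length column (end - start)."""
    import pandas as pd

    return pd.DataFrame(
        {
            "sample_id": [s.sample_id for s in segments],
            "chrom": [s.chrom for s in segments],
            "start_bp": [s.start_bp for s in segments],
            "end_bp": [s.end_bp for s in segments],
            "length_bp": [roh_length(s) for s in segments],
            "n_snps": [s.n_snps for s in segments],
            "n_het": [s.n_het for s in segments],
            "n_missing": [s.n_missing for s in segments],
        }
    )
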