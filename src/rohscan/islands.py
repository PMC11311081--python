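"""ROH islands: per-SNP population support and threshold-based calling.

A marker's *support* is the fraction of retained individuals whose ROH
covers its position (closed interval on segment bounds).  Maximal runs of
consecutive same-chromosome markers with support at or above the threshold
become islands.  No minimum length or SNP count is applied to islands, and
adjacent qualifying markers merge regardless of the physical gap between
them — island extent is defined entirely by marker support.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datamodel import GenotypeDataset
from .roh_detect import ROHSegment

__all__ = ["SupportProfile", "IslandCall", "support_profile", "call_islands", "island_report"]


@dataclass
class SupportProfile:
    """Per-marker support values, aligned with the dataset's marker order."""

    chrom: np.ndarray  # str array
    bp: np.ndarray  # int64
    support: np.ndarray  # float in [0, 1]

    def __post_init__(self):
        self.bp = np.asarray(self.bp, dtype=np.int64)
        self.support = np.asarray(self.support, dtype=float)
        self.chrom = np.asarray(self.chrom, dtype=object)
        if not (self.chrom.size == self.bp.size == self.support.size):
            raise ValueError("profile arrays must be aligned")
        if ((self.support < 0) | (self.support > 1)).any():
            raise ValueError("support outside [0, 1]")

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"chrom": self.chrom, "bp": self.bp, "support": self.support}
        )


def roh_coverage_matrix(
    segments: list[ROHSegment], dataset: GenotypeDataset
) -> np.ndarray:
    """Boolean (samples x markers) matrix: True where the sample has a ROH
    covering the marker position (closed interval [start_bp, end_bp])."""
    cov = np.zeros((dataset.n_samples, dataset.n_markers), dtype=bool)
    sample_row = {s: i for i, s in enumerate(dataset.samples)}
    chrom_cols = dataset.chrom_indices()
    bp = np.array([m.bp for m in dataset.markers], dtype=np.int64)
    for seg in segments:
        if seg.sample_id not in sample_row:
            continue
        cols = chrom_cols.get(seg.chrom)
        if cols is None:
            continue
        cbp = bp[cols]
        lo = np.searchsorted(cbp, seg.start_bp, side="left")
        hi = np.searchsorted(cbp, seg.end_bp, side="right")
        cov[sample_row[seg.sample_id], cols[lo:hi]] = True
    return cov


def support_profile(
    segments: list[ROHSegment], dataset: GenotypeDataset
) -> SupportProfile:
    """Fraction of retained individuals whose ROH covers each marker.

    The denominator is every retained individual, with or without any ROH.
    """
    if dataset.n_samples == 0:
        raise ValueError("empty dataset")
    cov = roh_coverage_matrix(segments, dataset)
    return SupportProfile(
        chrom=np.array([m.chrom for m in dataset.markers], dtype=object),
        bp=np.array([m.bp for m in dataset.markers], dtype=np.int64),
        support=cov.mean(axis=0),
    )


@dataclass(frozen=True)
class IslandCall:
    """A contiguous stretch of markers whose support clears the threshold."""

    chrom: str
    start_bp: int
    end_bp: int
    n_snps: int
    peak_support: float
    mean_support: float

    @property
    def length_bp(self) -> int:
        return self.end_bp - self.start_bp

    def __post_init__(self):
        if self.n_snps < 1:
            raise ValueError("island must contain at least one marker")
        if self.end_bp < self.start_bp:
            raise ValueError("island end before start")


def call_islands(profile: SupportProfile, threshold: float) -> list[IslandCall]:
    """Maximal runs of consecutive same-chromosome markers with support >=
    threshold.  Single-marker islands are legitimate (no minimum size)."""
    if not (0 < threshold <= 1):
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    qual = profile.support >= threshold
    islands: list[IslandCall] = []
    n = qual.size
    i = 0
    while i < n:
        if not qual[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and qual[j + 1] and profile.chrom[j + 1] == profile.chrom[i]:
            j += 1
        sup = profile.support[i : j + 1]
        islands.append(
            IslandCall(
                chrom=str(profile.chrom[i]),
                start_bp=int(profile.bp[i]),
                end_bp=int(profile.bp[j]),
                n_snps=j - i + 1,
                peak_support=float(sup.max()),
                mean_support=float(sup.mean()),
            )
        )
        i = j + 1
    return islands


def island_report(islands: list[IslandCall]) -> tuple[pd.DataFrame, dict]:
    """Island table (chrom, start, end, length, SNPs) plus totals: island
    count, summed SNPs and summed length in bp."""
    rows = [
        {
            "chrom": isl.chrom,
            "start_bp": isl.start_bp,
            "end_bp": isl.end_bp,
            "length_bp": isl.length_bp,
            "n_snps": isl.n_snps,
            "peak_support": isl.peak_support,
            "mean_support": isl.mean_support,
        }
        for isl in islands
    ]
    df = pd.DataFrame(
        rows,
        columns=[
            "chrom",
            "start_bp",
            "end_bp",
            "length_bp",
            "n_snps",
            "peak_support",
            "mean_support",
        ],
    )
    totals = {
        "n_islands": len(islands),
        "total_snps": int(df["n_snps"].sum()) if len(df) else 0,
        "total_length_bp": int(df["length_bp"].sum()) if len(df) else 0,
    }
    return df, totals
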