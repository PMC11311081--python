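"""Descriptive ROH statistics: length-class summaries and per-chromosome
counts and coverage."""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .roh_detect import ROHSegment, roh_length

__all__ = [
    "LengthClassSummary",
    "ChromosomeCoverage",
    "summarize_length_classes",
    "chromosome_coverage",
]

DEFAULT_CLASS_BOUNDS_MB = [0.0, 0.5, 1.0, 2.0, 4.0, 8.0, 16.0]


@dataclass(frozen=True)
class LengthClassSummary:
    """Summary statistics of ROH lengths falling into one Mb class
    ``[lower_mb, upper_mb)``; the totals row spans all classes and has
    ``lower_mb = upper_mb = nan``.

    ``sd_mb`` uses the sample (n-1) denominator and is NaN for n < 2;
    all stats are NaN for empty classes.  ``percent`` is relative to every
    summarized length, classified or not.
    """

    class_label: str
    lower_mb: float
    upper_mb: float
    n: int
    percent: float
    mean_mb: float
    sd_mb: float
    min_mb: float
    max_mb: float


def _stats(lengths_mb: np.ndarray, n_total: int) -> tuple:
    n = lengths_mb.size
    pct = 100.0 * n / n_total if n_total else 0.0
    if n == 0:
        return n, pct, math.nan, math.nan, math.nan, math.nan
    sd = float(np.std(lengths_mb, ddof=1)) if n > 1 else math.nan
    return (
        n,
        pct,
        float(lengths_mb.mean()),
        sd,
        float(lengths_mb.min()),
        float(lengths_mb.max()),
    )


def summarize_length_classes(
    lengths_bp, class_bounds_mb=None, n_total: int | None = None
) -> list[LengthClassSummary]:
    """Bin ROH (or island) lengths into Mb classes and summarize each.

    Parameters
    ----------
    lengths_bp : sequence of positive int
        Segment lengths in bp; converted to Mb by /1e6.
    class_bounds_mb : strictly increasing floats
        Consecutive pairs define half-open classes [lo, hi).
    n_total : int, optional
        Denominator for the percent column; defaults to the number of
        lengths supplied.  Useful when summarizing a published subset of a
        larger collection whose total count is known.

    Returns class rows in bound order followed by a totals row over every
    input (label ``"Total"``), whether classified or not.
    """
    bounds = list(DEFAULT_CLASS_BOUNDS_MB if class_bounds_mb is None else class_bounds_mb)
    if any(b2 <= b1 for b1, b2 in zip(bounds, bounds[1:])):
        raise ValueError("class bounds must be strictly increasing")
    lengths_bp = np.asarray(list(lengths_bp), dtype=float)
    if (lengths_bp <= 0).any():
        raise ValueError("lengths must be positive")
    mb = lengths_bp / 1e6
    if n_total is None:
        n_total = mb.size

    rows: list[LengthClassSummary] = []
    for lo, hi in zip(bounds, bounds[1:]):
        sel = mb[(mb >= lo) & (mb < hi)]
        label = f"{lo:g}–{hi:g}"
        rows.append(LengthClassSummary(label, lo, hi, *_stats(sel, n_total)))
    rows.append(
        LengthClassSummary("Total", math.nan, math.nan, *_stats(mb, n_total))
    )
    return rows


def length_classes_frame(rows: list[LengthClassSummary]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in rows])


@dataclass(frozen=True)
class ChromosomeCoverage:
    """Per-chromosome ROH burden: total segment count and the mean over
    individuals of the percent of the chromosome extent covered."""

    chrom: str
    n_roh: int
    pct_covered: float


def chromosome_coverage(
    segments: list[ROHSegment],
    markers,
    n_individuals: int | None = None,
    extents: dict[str, int] | None = None,
) -> list[ChromosomeCoverage]:
    """Count ROH and compute mean per-individual percent coverage per
    chromosome.

    The chromosome extent defaults to the last mapped marker position
    (override per chromosome via ``extents``).  ``n_individuals`` defaults
    to the number of distinct sample ids among the segments; pass the
    retained cohort size to average over ROH-free individuals too.
    """
    last_bp: dict[str, int] = {}
    order: list[str] = []
    for m in markers:
        if m.chrom not in last_bp:
            order.append(m.chrom)
        last_bp[m.chrom] = max(last_bp.get(m.chrom, 0), m.bp)
    if extents:
        last_bp.update(extents)

    missing = {s.chrom for s in segments} - set(last_bp)
    if missing:
        raise ValueError(f"segments on chromosomes absent from map: {sorted(missing)}")

    if n_individuals is None:
        n_individuals = len({s.sample_id for s in segments})

    per_chrom_bp: dict[str, float] = {c: 0.0 for c in order}
    per_chrom_n: dict[str, int] = {c: 0 for c in order}
    for s in segments:
        per_chrom_bp[s.chrom] += roh_length(s)
        per_chrom_n[s.chrom] += 1

    out = []
    for c in order:
        if n_individuals == 0:
            pct = 0.0
        else:
            pct = 100.0 * per_chrom_bp[c] / (last_bp[c] * n_individuals)
        out.append(ChromosomeCoverage(c, per_chrom_n[c], pct))
    return out
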