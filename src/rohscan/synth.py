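"""Synthetic SNP-array populations with planted autozygous segments.

The generator emulates the statistical structure a ROH pipeline assumes:
markers at sorted random positions, per-marker allele frequencies drawn
uniformly over a minor-allele-frequency range, background genotypes in
Hardy-Weinberg proportions independent across markers (no linkage
disequilibrium), planted homozygous segments carried by a controlled
fraction of individuals, genotyping error that renders within-segment
calls heterozygous, uniform missingness, and an additive phenotype with
per-segment carrier effects on top of Gaussian noise.

Defaults mirror a beef-cattle cohort of 189 genotyped bulls on a
high-density array, scaled down in marker count.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datamodel import MISSING, GenotypeDataset, Marker

__all__ = [
    "ChromosomeSpec",
    "PlantedSegment",
    "PhenotypeModel",
    "SimulationConfig",
    "SimulationTruth",
    "simulate",
    "write_truth",
    "read_truth",
]


@dataclass(frozen=True)
class ChromosomeSpec:
    label: str
    n_markers: int
    extent_bp: int

    def __post_init__(self):
        if self.n_markers < 1 or self.extent_bp < self.n_markers:
            raise ValueError("extent must allow n_markers distinct positions")


@dataclass(frozen=True)
class PlantedSegment:
    """An autozygous interval forced homozygous in a random subset of
    individuals of size ceil(carrier_fraction * n)."""

    chrom: str
    start_bp: int
    end_bp: int
    carrier_fraction: float

    def __post_init__(self):
        if not (0 < self.carrier_fraction <= 1):
            raise ValueError("carrier_fraction must be in (0, 1]")
        if self.end_bp <= self.start_bp:
            raise ValueError("segment end must exceed start")


@dataclass(frozen=True)
class PhenotypeModel:
    """Additive trait: mu + sum(beta_k * carrier_k) + N(0, sigma^2)."""

    mu: float = 130.0
    sigma: float = 4.0
    effects: tuple[tuple[int, float], ...] = ()  # (planted index, beta)

    def __post_init__(self):
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")


@dataclass(frozen=True)
class SimulationConfig:
    """Study-scale defaults: 189 individuals, a scaled-down marker panel,
    MAF uniform on [0.05, 0.5], 0.5% missingness and 0.2% within-segment
    heterozygous error."""

    n_individuals: int = 189
    chromosomes: tuple[ChromosomeSpec, ...] = (
        ChromosomeSpec("1", 2000, 50_000_000),
    )
    maf_range: tuple[float, float] = (0.05, 0.5)
    missing_rate: float = 0.005
    het_error_rate: float = 0.002
    planted_segments: tuple[PlantedSegment, ...] = ()
    phenotype: PhenotypeModel | None = None
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must satisfy 0 < lo <= hi <= 0.5")
        for r in (self.missing_rate, self.het_error_rate):
            if not (0 <= r <= 1):
                raise ValueError("rates must be in [0, 1]")
        extents = {c.label: c.extent_bp for c in self.chromosomes}
        by_chrom: dict[str, list[PlantedSegment]] = {}
        for seg in self.planted_segments:
            if seg.chrom not in extents:
                raise ValueError(f"planted segment on unknown chromosome {seg.chrom}")
            if seg.end_bp > extents[seg.chrom]:
                raise ValueError("planted segment exceeds chromosome extent")
            by_chrom.setdefault(seg.chrom, []).append(seg)
        for segs in by_chrom.values():
            segs = sorted(segs, key=lambda s: s.start_bp)
            for a, b in zip(segs, segs[1:]):
                if b.start_bp <= a.end_bp:
                    raise ValueError(
                        "planted segments overlap on chromosome "
                        f"{a.chrom}: [{a.start_bp},{a.end_bp}] and "
                        f"[{b.start_bp},{b.end_bp}]"
                    )


@dataclass
class SimulationTruth:
    """Planted intervals with their carrier sample ids."""

    segments: list[PlantedSegment] = field(default_factory=list)
    carriers: list[list[str]] = field(default_factory=list)


def simulate(
    config: SimulationConfig,
) -> tuple[GenotypeDataset, SimulationTruth, pd.DataFrame | None]:
    """Draw a population; identical config (incl. seed) gives identical
    output.

    Returns the genotype dataset (orientation-canonical, so it PED
    round-trips exactly), the planted-segment truth, and a phenotype table
    (sample_id, value) or None when no phenotype model is configured.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_individuals
    samples = [f"S{i + 1:04d}" for i in range(n)]

    markers: list[Marker] = []
    for spec in config.chromosomes:
        pos = _distinct_sorted_positions(rng, spec.n_markers, spec.extent_bp)
        markers.extend(
            Marker(spec.label, f"snp_{spec.label}_{k + 1}", 0.0, int(p))
            for k, p in enumerate(pos)
        )
    m = len(markers)
    bp = np.array([mk.bp for mk in markers], dtype=np.int64)
    chrom = np.array([mk.chrom for mk in markers], dtype=object)

    maf = rng.uniform(*config.maf_range, size=m)
    # HWE background: code counts copies of the minor allele
    p_hom_major = (1 - maf) ** 2
    p_het = 2 * maf * (1 - maf)
    u = rng.random((n, m))
    calls = np.full((n, m), 2, dtype=np.int8)
    calls[u < p_hom_major + p_het] = 1
    calls[u < p_hom_major] = 0

    truth = SimulationTruth()
    seg_marker_masks: list[np.ndarray] = []
    carrier_idx_sets: list[np.ndarray] = []
    for seg in config.planted_segments:
        mask = (chrom == seg.chrom) & (bp >= seg.start_bp) & (bp <= seg.end_bp)
        n_carriers = math.ceil(seg.carrier_fraction * n)
        carriers = np.sort(rng.choice(n, size=n_carriers, replace=False))
        calls[np.ix_(carriers, np.flatnonzero(mask))] = 0  # per-marker major hom
        truth.segments.append(seg)
        truth.carriers.append([samples[i] for i in carriers])
        seg_marker_masks.append(mask)
        carrier_idx_sets.append(carriers)

    # genotyping error: within planted segments a carrier call may be
    # rendered heterozygous, eroding the autozygous tract
    if config.het_error_rate > 0:
        for mask, carriers in zip(seg_marker_masks, carrier_idx_sets):
            cols = np.flatnonzero(mask)
            err = rng.random((carriers.size, cols.size)) < config.het_error_rate
            sub = calls[np.ix_(carriers, cols)]
            sub[err] = 1
            calls[np.ix_(carriers, cols)] = sub

    if config.missing_rate > 0:
        calls[rng.random((n, m)) < config.missing_rate] = MISSING

    dataset = GenotypeDataset(samples, markers, calls).canonicalize_orientation()

    pheno = None
    if config.phenotype is not None:
        pm = config.phenotype
        y = pm.mu + rng.normal(0.0, pm.sigma, size=n)
        for k, beta in pm.effects:
            if not (0 <= k < len(truth.segments)):
                raise ValueError(f"phenotype effect references planted segment {k}")
            y[carrier_idx_sets[k]] += beta
        pheno = pd.DataFrame({"sample_id": samples, "value": y})

    return dataset, truth, pheno


def _distinct_sorted_positions(rng, n_markers: int, extent_bp: int) -> np.ndarray:
    """Strictly increasing 1-based positions uniform over the extent."""
    draw = n_markers
    while True:
        pos = np.unique(rng.integers(1, extent_bp + 1, size=draw))
        if pos.size >= n_markers:
            return np.sort(rng.choice(pos, size=n_markers, replace=False))
        draw *= 2


def write_truth(truth: SimulationTruth, path) -> None:
    """Serialize planted intervals as BED-style rows (0-based half-open)
    with carrier fraction and comma-joined carrier ids; round-trips via
    :func:`read_truth`."""
    with open(path, "w") as fh:
        for seg, carriers in zip(truth.segments, truth.carriers):
            fh.write(
                f"{seg.chrom}\t{seg.start_bp - 1}\t{seg.end_bp}\t"
                f"{seg.carrier_fraction!r}\t{','.join(carriers)}\n"
            )


def read_truth(path) -> SimulationTruth:
    truth = SimulationTruth()
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            chrom, start0, end0, cf, carriers = line.rstrip("\n").split("\t")
            truth.segments.append(
                PlantedSegment(chrom, int(start0) + 1, int(end0), float(cf))
            )
            truth.carriers.append(carriers.split(",") if carriers else [])
    return truth
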