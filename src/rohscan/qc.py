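"""Genotype quality control: call-rate filters and a Hardy-Weinberg
exact test.

Three filters run in a fixed order — per-sample call rate, per-SNP call
rate, then the HWE exact test — mirroring the reference tool's single-pass
semantics.  The order matters: removing a low-call-rate sample can rescue a
marker's call rate, and HWE counts use only the samples retained at that
point.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datamodel import MISSING, GenotypeDataset

__all__ = [
    "QCConfig",
    "QCReport",
    "filter_samples_by_callrate",
    "filter_snps_by_callrate",
    "hwe_exact_pvalue",
    "filter_snps_by_hwe",
    "run_qc",
]


@dataclass(frozen=True)
class QCConfig:
    """Thresholds for the three genotype filters.

    Defaults are the conventional array-QC settings: 90% call rate on both
    axes and an exact-test threshold of 1e-6.
    """

    min_sample_callrate: float = 0.90
    min_snp_callrate: float = 0.90
    hwe_p_threshold: float = 1e-6

    def __post_init__(self):
        for name in ("min_sample_callrate", "min_snp_callrate", "hwe_p_threshold"):
            v = getattr(self, name)
            if not (0 < v <= 1):
                raise ValueError(f"{name} must be in (0, 1], got {v}")


@dataclass(frozen=True)
class QCReport:
    n_samples_removed: int
    n_snps_removed_callrate: int
    n_snps_removed_hwe: int
    n_samples_kept: int
    n_snps_kept: int


def filter_samples_by_callrate(
    dataset: GenotypeDataset, min_sample_callrate: float
) -> tuple[GenotypeDataset, list[str]]:
    """Drop samples whose fraction of non-missing calls is below threshold."""
    if dataset.n_samples == 0 or dataset.n_markers == 0:
        raise ValueError("empty dataset")
    callrate = (dataset.calls != MISSING).mean(axis=1)
    keep = callrate >= min_sample_callrate
    if not keep.any():
        raise ValueError("all samples removed by call-rate filter: empty dataset")
    removed = [s for s, k in zip(dataset.samples, keep) if not k]
    kept = [s for s, k in zip(dataset.samples, keep) if k]
    return dataset.subset_samples(kept), removed


def filter_snps_by_callrate(
    dataset: GenotypeDataset, min_snp_callrate: float
) -> tuple[GenotypeDataset, list[str]]:
    """Drop markers whose fraction of non-missing calls is below threshold."""
    if dataset.n_samples == 0 or dataset.n_markers == 0:
        raise ValueError("empty dataset")
    callrate = (dataset.calls != MISSING).mean(axis=0)
    keep = callrate >= min_snp_callrate
    if not keep.any():
        raise ValueError("all markers removed by call-rate filter: empty dataset")
    removed = [m.id for m, k in zip(dataset.markers, keep) if not k]
    return dataset.subset_markers(np.flatnonzero(keep)), removed


def hwe_exact_pvalue(n_AA: int, n_Ab: int, n_bb: int) -> float:
    """Two-sided exact test for Hardy-Weinberg proportions.

    Conditions on the observed allele counts and sums, over every
    heterozygote count compatible with them, the probabilities of tables no
    more likely than the observed one (ties included).  This is the
    standard SNP exact test; heterozygote counts step by 2 because the
    minor-allele count fixes their parity.

    Returns a p-value in (0, 1].
    """
    for v in (n_AA, n_Ab, n_bb):
        if v < 0 or v != int(v):
            raise ValueError("genotype counts must be non-negative integers")
    n = n_AA + n_Ab + n_bb
    if n == 0:
        raise ValueError("all genotype counts are zero")

    rare = 2 * min(n_AA, n_bb) + n_Ab  # rare-allele count
    if rare == 0:
        return 1.0

    # probabilities over het counts via the standard recurrence, then
    # normalised; start from the mode region by ascending from het=parity.
    het_min = rare % 2
    hets = list(range(het_min, rare + 1, 2))
    probs = np.empty(len(hets))
    probs[0] = 1.0
    for k in range(1, len(hets)):
        h = hets[k]
        # P(h) / P(h-2) = 4 * n_r(h-2) * n_c(h-2) / (h * (h-1))
        # where n_r, n_c are the hom counts at het = h-2
        n_rare_hom = (rare - (h - 2)) // 2
        n_common_hom = n - (h - 2) - n_rare_hom
        probs[k] = probs[k - 1] * 4.0 * n_rare_hom * n_common_hom / (h * (h - 1.0))
        if probs[k] > 1e280:  # rescale to avoid overflow at large n
            probs /= probs[k]
    probs /= probs.sum()

    obs = hets.index(n_Ab) if n_Ab in hets else None
    if obs is None:  # parity mismatch cannot happen with integer inputs
        raise ValueError("heterozygote count incompatible with allele counts")
    p_obs = probs[obs]
    # tie-tolerant sum of tables no more probable than observed
    p = probs[probs <= p_obs * (1 + 1e-12)].sum()
    if p <= 0.0:  # deep-tail underflow at very large n
        p = np.nextafter(0, 1)
    return float(min(p, 1.0))


def _genotype_counts(col: np.ndarray) -> tuple[int, int, int]:
    return int((col == 0).sum()), int((col == 1).sum()), int((col == 2).sum())


def filter_snps_by_hwe(
    dataset: GenotypeDataset, hwe_p_threshold: float
) -> tuple[GenotypeDataset, list[str]]:
    """Drop markers whose exact-test p-value falls below threshold.

    Missing calls are excluded from the genotype counts; markers with no
    observed calls are left untouched (call-rate filtering owns them).
    """
    keep = np.ones(dataset.n_markers, dtype=bool)
    removed: list[str] = []
    for j in range(dataset.n_markers):
        nAA, nAb, nbb = _genotype_counts(dataset.calls[:, j])
        if nAA + nAb + nbb == 0:
            continue
        if hwe_exact_pvalue(nAA, nAb, nbb) < hwe_p_threshold:
            keep[j] = False
            removed.append(dataset.markers[j].id)
    return dataset.subset_markers(np.flatnonzero(keep)), removed


def run_qc(
    dataset: GenotypeDataset, config: QCConfig | None = None
) -> tuple[GenotypeDataset, QCReport]:
    """Apply the three filters in order: sample call rate, SNP call rate,
    HWE exact test."""
    config = config or QCConfig()
    n0_samples, n0_snps = dataset.n_samples, dataset.n_markers
    ds, bad_samples = filter_samples_by_callrate(dataset, config.min_sample_callrate)
    ds, bad_callrate = filter_snps_by_callrate(ds, config.min_snp_callrate)
    ds, bad_hwe = filter_snps_by_hwe(ds, config.hwe_p_threshold)
    report = QCReport(
        n_samples_removed=len(bad_samples),
        n_snps_removed_callrate=len(bad_callrate),
        n_snps_removed_hwe=len(bad_hwe),
        n_samples_kept=ds.n_samples,
        n_snps_kept=ds.n_markers,
    )
    assert report.n_samples_kept + report.n_samples_removed == n0_samples
    assert (
        report.n_snps_kept
        + report.n_snps_removed_callrate
        + report.n_snps_removed_hwe
        == n0_snps
    )
    return ds, report
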