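"""Core genotype containers shared by every pipeline stage.

Genotypes are stored as small integer codes per (sample, marker):

* ``0`` — homozygous for allele A (the first allele observed at the marker),
* ``1`` — heterozygous,
* ``2`` — homozygous for allele B,
* ``MISSING`` (``-1``) — no call.

The A/B orientation is per-marker first-seen order and is arbitrary but
stable; all downstream ROH logic depends only on the hom/het/missing
distinction, never on which homozygote is which.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: genotype code for a missing call
MISSING: int = -1

#: allowed genotype codes
VALID_CODES = frozenset({0, 1, 2, MISSING})


def _natural_chrom_key(label: str):
    """Sort key for chromosome labels: numeric labels first in numeric
    order, everything else lexicographic after them."""
    try:
        return (0, int(label), "")
    except ValueError:
        return (1, 0, label)


@dataclass(frozen=True)
class Marker:
    """One biallelic SNP on the array.

    Attributes
    ----------
    chrom : str
        Chromosome label (autosomes only; kept as a string, e.g. ``"13"``).
    id : str
        Marker name.
    genetic_pos : float
        Genetic map position in centimorgan; may be 0 when unknown.
    bp : int
        Physical position, 1-based.
    """

    chrom: str
    id: str
    genetic_pos: float
    bp: int

    def __post_init__(self):
        if self.bp < 1:
            raise ValueError(f"marker {self.id}: bp must be >= 1, got {self.bp}")


@dataclass
class GenotypeDataset:
    """Samples x ordered markers with coded genotype calls.

    ``calls`` has shape ``(n_samples, n_markers)`` with values in
    ``{0, 1, 2, MISSING}``.  Markers are sorted by (chrom, bp) with
    strictly increasing bp within a chromosome.
    """

    samples: list[str]
    markers: list[Marker]
    calls: np.ndarray = field(repr=False)

    def __post_init__(self):
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.samples), len(self.markers)):
            raise ValueError(
                f"calls shape {self.calls.shape} != "
                f"({len(self.samples)}, {len(self.markers)})"
            )
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("duplicate sample ids")
        bad = ~np.isin(self.calls, [0, 1, 2, MISSING])
        if bad.any():
            raise ValueError("genotype codes outside {0,1,2,MISSING}")
        self._check_sorted()

    def _check_sorted(self):
        last: dict[str, int] = {}
        for m in self.markers:
            prev = last.get(m.chrom)
            if prev is not None and m.bp <= prev:
                raise ValueError(
                    f"markers not strictly increasing on chrom {m.chrom} "
                    f"at bp {m.bp}"
                )
            last[m.chrom] = m.bp

    # -- convenience views ------------------------------------------------

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    @property
    def chroms(self) -> list[str]:
        """Chromosome labels in marker order (deduplicated, order kept)."""
        seen: dict[str, None] = {}
        for m in self.markers:
            seen.setdefault(m.chrom, None)
        return list(seen)

    def marker_frame(self) -> pd.DataFrame:
        """Markers as a DataFrame (chrom, id, cM, bp) in panel order."""
        return pd.DataFrame(
            {
                "chrom": [m.chrom for m in self.markers],
                "id": [m.id for m in self.markers],
                "cM": [m.genetic_pos for m in self.markers],
                "bp": [m.bp for m in self.markers],
            }
        )

    def chrom_indices(self) -> dict[str, np.ndarray]:
        """Column index array per chromosome, in panel order."""
        out: dict[str, list[int]] = {}
        for j, m in enumerate(self.markers):
            out.setdefault(m.chrom, []).append(j)
        return {c: np.asarray(v, dtype=np.intp) for c, v in out.items()}

    def subset_samples(self, keep: list[str]) -> "GenotypeDataset":
        idx = [self.samples.index(s) for s in keep]
        return GenotypeDataset(list(keep), list(self.markers), self.calls[idx, :])

    def subset_markers(self, keep_cols: np.ndarray) -> "GenotypeDataset":
        keep_cols = np.asarray(keep_cols, dtype=np.intp)
        return GenotypeDataset(
            list(self.samples),
            [self.markers[j] for j in keep_cols],
            self.calls[:, keep_cols],
        )

    def mean_heterozygosity(self) -> float:
        """Average per-SNP heterozygosity over non-missing calls, pooled
        across all markers.  Used to calibrate the minimum-SNP formula."""
        obs = self.calls != MISSING
        if not obs.any():
            raise ValueError("no observed genotypes")
        return float((self.calls == 1).sum() / obs.sum())

    def canonicalize_orientation(self) -> "GenotypeDataset":
        """Swap hom codes (0 <-> 2) at markers whose first non-missing call
        is the code-2 homozygote.

        PED recoding assigns allele A by first appearance, so only datasets
        in this orientation round-trip through PED text with identical
        codes.  Orientation carries no information downstream (ROH logic
        sees hom/het/missing only), so this is a pure relabelling.
        """
        calls = self.calls.copy()
        for j in range(calls.shape[1]):
            col = calls[:, j]
            obs = col[col != MISSING]
            if obs.size and obs[0] == 2:
                hom0, hom2 = col == 0, col == 2
                col[hom0], col[hom2] = 2, 0
        return GenotypeDataset(list(self.samples), list(self.markers), calls)

    def __eq__(self, other) -> bool:
        if not isinstance(other, GenotypeDataset):
            return NotImplemented
        return (
            self.samples == other.samples
            and self.markers == other.markers
            and np.array_equal(self.calls, other.calls)
        )
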