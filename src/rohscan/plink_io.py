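"""Text PED/MAP reading and writing.

PED: whitespace-delimited, 6 mandatory leading columns (family, individual,
father, mother, sex, phenotype) followed by two allele columns per marker;
"0" marks a missing allele.  MAP: four columns (chrom, id, cM, bp).

Alleles are recoded to 0/1/2 per marker by first-seen order: the first
non-missing allele encountered (scanning samples in file order, first allele
of the pair first) becomes allele A.  Half-missing pairs ("A 0") are treated
as missing, as the dialect gives them no defined genotype.
"""

from __future__ import annotations

import os

import numpy as np

from .datamodel import MISSING, GenotypeDataset, Marker, _natural_chrom_key

__all__ = ["read_ped_map", "write_ped_map", "write_table"]


def _read_map(map_path) -> list[Marker]:
    markers: list[Marker] = []
    with open(map_path) as fh:
        for ln, line in enumerate(fh, 1):
            fields = line.split()
            if not fields:
                continue
            if len(fields) != 4:
                raise ValueError(
                    f"{map_path}: line {ln}: expected 4 columns, got {len(fields)}"
                )
            chrom, mid, cm, bp = fields
            markers.append(Marker(chrom, mid, float(cm), int(bp)))
    return markers


def read_ped_map(ped_path, map_path) -> GenotypeDataset:
    """Load a PED/MAP pair into a :class:`GenotypeDataset`.

    Markers are re-sorted by (chrom, bp) and the genotype columns permuted
    accordingly; duplicate physical positions on one chromosome are
    rejected.

    Raises
    ------
    ValueError
        On a ragged PED line (names the line number), a marker with more
        than two distinct non-missing alleles (names the marker), or a
        duplicate bp within a chromosome.
    """
    markers = _read_map(map_path)
    n_markers = len(markers)

    samples: list[str] = []
    rows: list[np.ndarray] = []
    # per-marker first-seen allele pair, e.g. {"A": 0, "G": 1}
    allele_codes: list[dict[str, int]] = [dict() for _ in range(n_markers)]

    with open(ped_path) as fh:
        for ln, line in enumerate(fh, 1):
            fields = line.split()
            if not fields:
                continue
            if len(fields) != 6 + 2 * n_markers:
                raise ValueError(
                    f"{ped_path}: line {ln}: expected {6 + 2 * n_markers} "
                    f"fields for {n_markers} markers, got {len(fields)}"
                )
            samples.append(fields[1])
            row = np.full(n_markers, MISSING, dtype=np.int8)
            alleles = fields[6:]
            for j in range(n_markers):
                a, b = alleles[2 * j], alleles[2 * j + 1]
                if a == "0" or b == "0":
                    continue
                codes = allele_codes[j]
                for al in (a, b):
                    if al not in codes:
                        if len(codes) == 2:
                            raise ValueError(
                                f"marker {markers[j].id}: more than 2 "
                                f"distinct alleles ({sorted(codes)} + {al!r})"
                            )
                        codes[al] = len(codes)
                row[j] = codes[a] + codes[b]  # 0/1/2 by construction
            rows.append(row)

    calls = (
        np.vstack(rows) if rows else np.empty((0, n_markers), dtype=np.int8)
    )

    # sort markers by (chrom, bp), rejecting duplicate positions
    order = sorted(
        range(n_markers),
        key=lambda j: (_natural_chrom_key(markers[j].chrom), markers[j].bp),
    )
    seen: set[tuple[str, int]] = set()
    for j in order:
        key = (markers[j].chrom, markers[j].bp)
        if key in seen:
            raise ValueError(
                f"duplicate position chrom {markers[j].chrom} bp "
                f"{markers[j].bp} (marker {markers[j].id})"
            )
        seen.add(key)
    markers = [markers[j] for j in order]
    calls = calls[:, order] if n_markers else calls

    return GenotypeDataset(samples, markers, calls)


_PED_ALLELES = {0: ("A", "A"), 1: ("A", "B"), 2: ("B", "B"), MISSING: ("0", "0")}


def write_ped_map(dataset: GenotypeDataset, ped_path, map_path) -> None:
    """Write a dataset back to PED/MAP, round-trippable by
    :func:`read_ped_map` (codes, sample order and marker order survive)."""
    with open(map_path, "w") as fh:
        for m in dataset.markers:
            cm = int(m.genetic_pos) if float(m.genetic_pos).is_integer() else m.genetic_pos
            fh.write(f"{m.chrom}\t{m.id}\t{cm}\t{m.bp}\n")
    with open(ped_path, "w") as fh:
        for i, sid in enumerate(dataset.samples):
            fields = [sid, sid, "0", "0", "0", "-9"]
            for code in dataset.calls[i]:
                fields.extend(_PED_ALLELES[int(code)])
            fh.write(" ".join(fields) + "\n")


def write_table(df, path, header_comment: str | None = None) -> None:
    """Write a tab-separated table with a single header line, optionally
    preceded by '# '-prefixed comment lines (version/config provenance)."""
    path = os.fspath(path)
    with open(path, "w") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False)
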