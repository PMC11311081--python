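"""Gene annotation of ROH islands by interval intersection with a BED
gene track."""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .datamodel import _natural_chrom_key
from .islands import IslandCall

__all__ = ["GeneFeature", "load_gene_track", "genes_in_islands"]


@dataclass(frozen=True)
class GeneFeature:
    """A named gene interval in 1-based closed coordinates."""

    chrom: str
    start_bp: int
    end_bp: int
    name: str

    def __post_init__(self):
        if self.end_bp <= self.start_bp:
            raise ValueError(f"gene {self.name}: end must exceed start")
        if not self.name:
            raise ValueError("gene name must be non-empty")


def load_gene_track(bed_path) -> list[GeneFeature]:
    """Read a BED3+ gene track.

    BED is 0-based half-open; features are converted to the pipeline's
    1-based closed convention (start+1, end) and sorted by (chrom, start).
    A missing name column falls back to ``chrom:start-end`` labels.
    """
    feats: list[GeneFeature] = []
    with open(bed_path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{bed_path}: line {ln}: expected >=3 BED columns")
            try:
                chrom, start0, end0 = fields[0], int(fields[1]), int(fields[2])
            except ValueError as e:
                raise ValueError(f"{bed_path}: line {ln}: {e}") from None
            if end0 <= start0:
                raise ValueError(f"{bed_path}: line {ln}: end <= start")
            name = fields[3] if len(fields) > 3 and fields[3] else f"{chrom}:{start0}-{end0}"
            feats.append(GeneFeature(chrom, start0 + 1, end0, name))
    feats.sort(key=lambda g: (_natural_chrom_key(g.chrom), g.start_bp))
    return feats


def genes_in_islands(
    islands: list[IslandCall],
    track: list[GeneFeature],
    mode: str = "overlap",
    flank_bp: int = 0,
) -> list[list[GeneFeature]]:
    """Genes assigned to each island, in island order.

    mode ``"overlap"`` lists a gene when its interval intersects the
    (optionally flank-padded) island; ``"contained"`` requires the gene to
    lie fully inside it.  ``flank_bp`` pads both island ends to capture
    genes in close proximity.
    """
    if mode not in ("overlap", "contained"):
        raise ValueError(f"mode must be 'overlap' or 'contained', got {mode!r}")
    if flank_bp < 0:
        raise ValueError("flank_bp must be >= 0")
    out: list[list[GeneFeature]] = []
    for isl in islands:
        lo = isl.start_bp - flank_bp
        hi = isl.end_bp + flank_bp
        hits = []
        for g in track:
            if g.chrom != isl.chrom:
                continue
            if mode == "overlap":
                if g.start_bp <= hi and g.end_bp >= lo:
                    hits.append(g)
            else:
                if g.start_bp >= lo and g.end_bp <= hi:
                    hits.append(g)
        out.append(hits)
    return out


def island_genes_frame(
    islands: list[IslandCall], gene_lists: list[list[GeneFeature]]
) -> pd.DataFrame:
    """One row per island: coordinates, gene count, comma-joined names."""
    return pd.DataFrame(
        {
            "chrom": [i.chrom for i in islands],
            "start_bp": [i.start_bp for i in islands],
            "end_bp": [i.end_bp for i in islands],
            "n_genes": [len(g) for g in gene_lists],
            "genes": [",".join(x.name for x in g) for g in gene_lists],
        }
    )
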