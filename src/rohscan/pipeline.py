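"""End-to-end pipeline: QC -> ROH detection -> summaries -> islands ->
optional gene annotation -> optional phenotype association.

Every output table is tab-separated with '#'-prefixed provenance lines
(package version, config hash, seed) above a single header row, so two
runs with the same config produce bit-identical artifacts.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .annotate import genes_in_islands, island_genes_frame, load_gene_track
from .assoc import AssocConfig, assoc_frame, assoc_scan, roh_state_matrix
from .islands import call_islands, island_report, support_profile
from .plink_io import read_ped_map, write_ped_map, write_table
from .qc import QCConfig, run_qc
from .roh_detect import ROHDetectionConfig, detect_roh, segments_frame
from .roh_stats import (
    chromosome_coverage,
    length_classes_frame,
    summarize_length_classes,
)

logger = logging.getLogger("rohscan")

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass(frozen=True)
class PipelineConfig:
    ped: str = ""
    map: str = ""
    out_dir: str = "rohscan_out"
    qc: QCConfig = field(default_factory=QCConfig)
    detect: ROHDetectionConfig = field(default_factory=ROHDetectionConfig)
    island_thresholds: tuple[float, ...] = (0.5, 0.7)
    assoc: AssocConfig = field(default_factory=AssocConfig)
    genes_bed: str | None = None
    annotate_mode: str = "overlap"
    flank_bp: int = 0
    phenotype_tsv: str | None = None
    seed: int = 0

    def __post_init__(self):
        for t in self.island_thresholds:
            if not (0 < t <= 1):
                raise ValueError(f"island threshold {t} outside (0, 1]")

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key, sub in (("qc", QCConfig), ("detect", ROHDetectionConfig), ("assoc", AssocConfig)):
            if key in d and isinstance(d[key], dict):
                d[key] = sub(**d[key])
        if "island_thresholds" in d:
            d["island_thresholds"] = tuple(d["island_thresholds"])
        return cls(**d)

    def config_hash(self) -> str:
        """Hash of the analysis parameters (thresholds, seed) — not the
        I/O paths, so identical analyses hash alike wherever they run."""
        d = dataclasses.asdict(self)
        for key in ("ped", "map", "out_dir", "genes_bed", "phenotype_tsv"):
            d.pop(key, None)
        blob = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _header(config: PipelineConfig) -> str:
    return (
        f"rohscan {__version__}\n"
        f"config_hash {config.config_hash()}\n"
        f"seed {config.seed}"
    )


def run_pipeline(config: PipelineConfig) -> dict[str, Path]:
    """Run every stage; returns a name -> path map of written artifacts.

    Stage failures raise with the stage name prefixed, so callers can
    report which step aborted.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}
    hdr = _header(config)

    def _write(name: str, df: pd.DataFrame) -> None:
        path = out / name
        write_table(df, path, hdr)
        artifacts[name] = path

    stage = "load"
    try:
        dataset = read_ped_map(config.ped, config.map)
        logger.info("load: %d samples x %d markers", dataset.n_samples, dataset.n_markers)

        stage = "qc"
        dataset, report = run_qc(dataset, config.qc)
        logger.info(
            "qc: kept %d samples, %d markers (removed %d samples, %d low-call SNPs, %d HWE SNPs)",
            report.n_samples_kept, report.n_snps_kept, report.n_samples_removed,
            report.n_snps_removed_callrate, report.n_snps_removed_hwe,
        )
        _write("qc_report.tsv", pd.DataFrame([report.__dict__]))
        write_ped_map(dataset, out / "filtered.ped", out / "filtered.map")
        artifacts["filtered.ped"] = out / "filtered.ped"
        artifacts["filtered.map"] = out / "filtered.map"

        stage = "detect"
        cfg = config.detect.resolve(dataset)
        segments = detect_roh(dataset, cfg)
        logger.info(
            "detect: %d segments (min_snps=%d, mean_het=%.4f)",
            len(segments), cfg.min_snps, cfg.mean_het,
        )
        _write("roh_segments.tsv", segments_frame(segments))

        stage = "summarize"
        lengths = [s.end_bp - s.start_bp for s in segments]
        _write("length_classes.tsv", length_classes_frame(summarize_length_classes(lengths)))
        cov = chromosome_coverage(segments, dataset.markers, n_individuals=dataset.n_samples)
        _write("chromosome_coverage.tsv", pd.DataFrame([c.__dict__ for c in cov]))

        stage = "islands"
        profile = support_profile(segments, dataset)
        _write("support_profile.tsv", profile.frame())
        islands_by_thr = {}
        for thr in config.island_thresholds:
            islands = call_islands(profile, thr)
            islands_by_thr[thr] = islands
            df, totals = island_report(islands)
            logger.info("islands@%.2f: %s", thr, totals)
            _write(f"islands_{int(round(thr * 100))}.tsv", df)

        if config.genes_bed:
            stage = "annotate"
            track = load_gene_track(config.genes_bed)
            thr0 = config.island_thresholds[0]
            gene_lists = genes_in_islands(
                islands_by_thr[thr0], track, config.annotate_mode, config.flank_bp
            )
            _write("island_genes.tsv", island_genes_frame(islands_by_thr[thr0], gene_lists))

        if config.phenotype_tsv:
            stage = "assoc"
            pheno = pd.read_csv(config.phenotype_tsv, sep="\t", comment="#")
            series = pd.Series(
                pheno["value"].to_numpy(), index=pheno["sample_id"].astype(str)
            )
            state = roh_state_matrix(segments, dataset)
            records = assoc_scan(state, series, dataset, config.assoc)
            logger.info(
                "assoc: %d markers tested, %d significant",
                len(records), sum(r.significant for r in records),
            )
            _write("assoc.tsv", assoc_frame(records))
    except Exception as e:
        raise RuntimeError(f"pipeline stage '{stage}' failed: {e}") from e

    return artifacts
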