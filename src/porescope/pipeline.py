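"""Stage orchestration: the analyze run and the paired test/control run.

``run_analyze`` wires the stages together for one FASTQ: strict format
validation, quality filtering with deduplication, MinHash sketching of
the raw reads, alignment (external aligner or supplied SAM), per-taxon
coverage statistics, and the two manifest outputs. Input validation
happens before any output is written, so a corrupt FASTQ never leaves a
partial summary behind. ``run_pipeline_pair`` runs analyze twice and
hands the two output directories to the report stage.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Optional

from . import __version__
from .alignment import AlignerConfig, align, select_primary
from .compare_report import render_reports
from .coverage_stats import (
    build_manifest,
    build_manifest_summary,
    compute_taxon_stats,
    write_manifest,
    write_manifest_summary,
)
from .formats import (
    PathLike,
    parse_fasta,
    parse_fastq,
    parse_sam,
    parse_sequencing_summary,
    write_fastq,
)
from .minhash import SketchError, estimate_coverage, estimate_genome_size, sketch_reads
from .read_qc import QcParams, qc_filter

logger = logging.getLogger("porescope")


@dataclass(frozen=True)
class AnalyzeConfig:
    """Everything one analyze run needs."""

    input_fastq: Path
    reference: Path
    output_dir: Path
    seq_summary: Optional[Path] = None
    sam: Optional[Path] = None  # precomputed alignments; skips the aligner
    minimum_coverage: int = 1
    sequencing_mode: str = "long_single"  # or "short_paired"
    sample_id: str = "sample"
    qc: QcParams = field(default_factory=QcParams)
    sketch_k: int = 27
    sketch_s: int = 1000
    sketch_m: int = 2

    def __post_init__(self) -> None:
        if self.minimum_coverage < 1:
            raise ValueError("minimum_coverage must be >= 1")
        if self.sequencing_mode not in ("long_single", "short_paired"):
            raise ValueError(f"unknown sequencing_mode {self.sequencing_mode!r}")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_analyze(config: AnalyzeConfig) -> Path:
    """Run the analyze stage; returns the output directory.

    Output inventory: ``sample_manifest.txt``, ``sample_manifest_summary.txt``,
    ``filtered.fastq`` (QC-passed reads), ``mapped.fastq`` (primary-mapped
    reads), ``alignments.sam`` (when the aligner ran), ``sketch.json`` and
    ``analyze.log``.
    """
    outdir = Path(config.output_dir)

    # --- validate all inputs before writing anything
    references = parse_fasta(config.reference)
    reads = list(parse_fastq(config.input_fastq, strict=True))
    summary = (
        parse_sequencing_summary(config.seq_summary)
        if config.seq_summary is not None
        else None
    )

    outdir.mkdir(parents=True, exist_ok=True)
    log_path = outdir / "analyze.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    try:
        logger.info("porescope %s analyze", __version__)
        logger.info("input_fastq=%s sha256=%s", config.input_fastq, _sha256(Path(config.input_fastq)))
        logger.info("reference=%s sha256=%s", config.reference, _sha256(Path(config.reference)))
        logger.info(
            "params: minimum_coverage=%d mode=%s qc=%s sketch(k=%d,s=%d,m=%d)",
            config.minimum_coverage,
            config.sequencing_mode,
            config.qc,
            config.sketch_k,
            config.sketch_s,
            config.sketch_m,
        )

        # --- QC filter
        kept, status, qc_stats = qc_filter(reads, config.qc)
        write_fastq(kept, outdir / "filtered.fastq")
        logger.info(
            "qc: %d in, %d out, %d failed, %d duplicates removed",
            qc_stats.reads_in,
            qc_stats.reads_out,
            qc_stats.failures,
            qc_stats.duplicates_removed,
        )

        # --- reference-free sketch estimates (raw reads)
        est_genome_size = est_coverage = 0.0
        try:
            sketch = sketch_reads(
                reads, k=config.sketch_k, s=config.sketch_s, m=config.sketch_m
            )
            est_genome_size = estimate_genome_size(sketch)
            est_coverage = estimate_coverage(sketch)
        except SketchError as exc:
            logger.warning("sketch skipped: %s", exc)
        (outdir / "sketch.json").write_text(
            '{"est_genome_size": %r, "est_coverage": %r, '
            '"k": %d, "s": %d, "m": %d}\n'
            % (
                est_genome_size,
                est_coverage,
                config.sketch_k,
                config.sketch_s,
                config.sketch_m,
            )
        )

        # --- alignments
        kept_ids = {r.read_id for r in kept}
        if config.sam is not None:
            # a supplied SAM may cover the whole run; restrict to the reads
            # of this condition that passed QC, so that QC-failed reads are
            # never counted as mapped and stats stay per-condition
            alignments = [
                a for a in parse_sam(config.sam) if a.read_id in kept_ids
            ]
            logger.info("alignments loaded from %s", config.sam)
        else:
            preset = (
                "long_read_ont"
                if config.sequencing_mode == "long_single"
                else "short_read_paired"
            )
            sam_path = outdir / "alignments.sam"
            align(
                outdir / "filtered.fastq",
                config.reference,
                sam_path,
                AlignerConfig(preset=preset),
            )
            alignments = parse_sam(sam_path)
            logger.info("aligner wrote %s", sam_path)
        primaries = select_primary(alignments)
        mapped_ids = {a.read_id for a in primaries if a.is_mapped}
        write_fastq(
            (r for r in kept if r.read_id in mapped_ids), outdir / "mapped.fastq"
        )

        # --- per-taxon statistics and manifests
        taxon_stats = compute_taxon_stats(
            references, alignments, threshold=config.minimum_coverage
        )
        manifest = build_manifest(
            reads, status, alignments, summary, sample_id=config.sample_id
        )
        summary_table = build_manifest_summary(
            taxon_stats, qc_stats, est_genome_size, est_coverage
        )
        write_manifest(manifest, outdir / "sample_manifest.txt")
        write_manifest_summary(summary_table, outdir / "sample_manifest_summary.txt")
        logger.info(
            "wrote %d manifest rows, %d taxon rows",
            len(manifest),
            len(summary_table),
        )
    finally:
        logger.removeHandler(handler)
        handler.close()
    return outdir


def run_pipeline_pair(
    test_config: AnalyzeConfig,
    control_config: AnalyzeConfig,
    report_dir: PathLike,
    as_mode: bool = True,
    bin_minutes: float = 15.0,
) -> Path:
    """Analyze test and control, then build the comparison report."""
    try:
        test_dir = run_analyze(test_config)
    except Exception as exc:
        raise RuntimeError(f"analyze (test) failed: {exc}") from exc
    try:
        control_dir = run_analyze(control_config)
    except Exception as exc:
        raise RuntimeError(f"analyze (control) failed: {exc}") from exc
    render_reports(
        test_dir,
        control_dir,
        report_dir,
        as_mode=as_mode,
        bin_minutes=bin_minutes,
    )
    return Path(report_dir)
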