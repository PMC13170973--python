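"""Per-taxon depth/breadth statistics and the two manifest outputs.

This module assembles the analyze stage's two key tables:

* the **sample manifest** — one row per read per pore event, joining FASTQ
  fields, QC verdicts, primary alignment assignment, and (when a
  sequencing summary is supplied) channel/time/decision details;
* the **sample manifest summary** — one row per reference sequence
  ("taxon") with mean coverage depth, covered bases and percent breadth
  at a depth threshold, total mapped bases, and mean read length, plus a
  final "*" row for unmapped reads and sample-wide fields (sketch-based
  genome size/coverage estimates and pre/post-filter base totals).

Depth is per-base: an alignment adds one to every reference position its
M/=/X CIGAR operations cover (computed with a difference array; deletions
span but do not cover). SAM coordinates are 1-based closed externally and
converted to 0-based half-open exactly once, here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .alignment import DataError, aligned_ref_span, parse_cigar, primary_assignment
from .formats import (
    AlignmentRecord,
    FastqRead,
    PathLike,
    ReferenceSeq,
    SummaryRow,
    UNMAPPED,
)
from .read_qc import QcStats, mean_qscore

MANIFEST_COLUMNS = (
    "sample_id",
    "read_id",
    "read_len",
    "read_qscore",
    "channel",
    "start_time",
    "end_time",
    "decision",
    "fastp_status",
    "is_mapped",
    "is_uniq",
    "contig_id",
)


@dataclass(frozen=True)
class TaxonStats:
    """Aggregate mapping statistics for one reference sequence."""

    taxon_id: str
    taxon_length: int
    taxon_mean_coverage: float
    taxon_covered_bases: int
    taxon_pct_covered_bases: float
    total_taxon_ref_mapped_bases: int
    taxon_mean_read_length: float
    threshold: int = 1


@dataclass(frozen=True)
class ManifestRow:
    """One per-read record of the sample manifest (one per pore event)."""

    sample_id: str
    read_id: str
    read_len: int
    read_qscore: float
    channel: Optional[int]
    start_time: Optional[float]
    end_time: Optional[float]
    decision: str
    fastp_status: bool
    is_mapped: bool
    is_uniq: bool
    contig_id: str


def round_sig(value: float, digits: int = 2) -> float:
    """Round to ``digits`` significant digits (reporting only)."""
    if value == 0:
        return 0.0
    magnitude = math.floor(math.log10(abs(value)))
    return round(value, digits - 1 - magnitude)


# ---------------------------------------------------------------------------
# depth
# ---------------------------------------------------------------------------

def cigar_ref_blocks(pos: int, cigar: str) -> List[tuple]:
    """0-based half-open reference blocks covered by M/=/X ops.

    ``pos`` is the SAM 1-based leftmost coordinate; D/N advance the cursor
    without emitting a block.
    """
    cursor = pos - 1
    blocks: List[tuple] = []
    for n, op in parse_cigar(cigar):
        if op in "M=X":
            blocks.append((cursor, cursor + n))
            cursor += n
        elif op in "DN":
            cursor += n
    return blocks


def depth_profile(
    alignments: Iterable[AlignmentRecord], taxon_length: int
) -> np.ndarray:
    """Per-position depth over one taxon from its primary alignments.

    Implemented as a difference array: +1 at each covered block start,
    -1 at its end, then a cumulative sum. Total depth mass equals the sum
    of aligned_ref_span over the alignments.
    """
    if taxon_length <= 0:
        raise ValueError("taxon_length must be positive")
    diff = np.zeros(taxon_length + 1, dtype=np.int64)
    for aln in alignments:
        for start, end in cigar_ref_blocks(aln.pos, aln.cigar):
            if start < 0 or end > taxon_length:
                raise DataError(
                    f"alignment of read {aln.read_id!r} overruns reference "
                    f"({start}:{end} vs length {taxon_length})"
                )
            diff[start] += 1
            diff[end] -= 1
    return np.cumsum(diff[:-1])


def taxon_summary(
    taxon_id: str,
    taxon_length: int,
    depths: np.ndarray,
    read_lengths: Sequence[int],
    threshold: int = 1,
) -> TaxonStats:
    """Collapse a depth profile into one summary row.

    ``read_lengths`` are the FULL lengths of reads whose primary alignment
    is to this taxon (adaptive-sampling truncation therefore shows up as a
    short mean read length). Covered bases count positions with
    depth >= threshold, inclusive.
    """
    if taxon_length <= 0:
        raise ValueError(f"taxon {taxon_id!r} has length 0")
    if threshold < 1:
        raise ValueError("threshold must be >= 1")
    total_mapped = int(depths.sum())
    covered = int(np.count_nonzero(depths >= threshold))
    return TaxonStats(
        taxon_id=taxon_id,
        taxon_length=taxon_length,
        taxon_mean_coverage=total_mapped / taxon_length,
        taxon_covered_bases=covered,
        taxon_pct_covered_bases=100.0 * covered / taxon_length,
        total_taxon_ref_mapped_bases=total_mapped,
        taxon_mean_read_length=(
            float(np.mean(read_lengths)) if len(read_lengths) else 0.0
        ),
        threshold=threshold,
    )


def unmapped_stats(threshold: int = 1) -> TaxonStats:
    """The all-zero "*" row for reads that mapped to no reference."""
    return TaxonStats(
        taxon_id=UNMAPPED,
        taxon_length=0,
        taxon_mean_coverage=0.0,
        taxon_covered_bases=0,
        taxon_pct_covered_bases=0.0,
        total_taxon_ref_mapped_bases=0,
        taxon_mean_read_length=0.0,
        threshold=threshold,
    )


def compute_taxon_stats(
    references: Sequence[ReferenceSeq],
    alignments: Sequence[AlignmentRecord],
    threshold: int = 1,
) -> List[TaxonStats]:
    """One TaxonStats per reference (sorted by id) plus the "*" row, last."""
    assignment = primary_assignment(alignments)
    by_taxon: Dict[str, List[AlignmentRecord]] = {
        ref.taxon_id: [] for ref in references
    }
    for aln in assignment.values():
        if aln.taxon_id not in by_taxon:
            raise DataError(
                f"alignment target {aln.taxon_id!r} absent from reference set"
            )
        by_taxon[aln.taxon_id].append(aln)
    out: List[TaxonStats] = []
    for ref in sorted(references, key=lambda r: r.taxon_id):
        alns = by_taxon[ref.taxon_id]
        depths = depth_profile(alns, ref.taxon_length)
        out.append(
            taxon_summary(
                ref.taxon_id,
                ref.taxon_length,
                depths,
                [a.read_length for a in alns],
                threshold=threshold,
            )
        )
    out.append(unmapped_stats(threshold))
    return out


# ---------------------------------------------------------------------------
# manifests
# ---------------------------------------------------------------------------

def build_manifest(
    reads: Sequence[FastqRead],
    qc_status: Mapping[str, bool],
    alignments: Sequence[AlignmentRecord],
    summary: Optional[Sequence[SummaryRow]] = None,
    sample_id: str = "sample",
) -> List[ManifestRow]:
    """Join reads, QC verdicts, alignments and summary rows per read.

    One output row per (read, summary occurrence); reads absent from the
    summary (or when no summary is given) get a single row with empty
    pore-level fields and a FASTQ-derived Q score. A read with several
    summary rows was re-evaluated by the pore, so all its rows carry
    is_uniq=False.
    """
    assignment = primary_assignment(alignments)
    by_read: Dict[str, List[SummaryRow]] = {}
    if summary is not None:
        for row in summary:
            by_read.setdefault(row.read_id, []).append(row)
    out: List[ManifestRow] = []
    for read in reads:
        passed = bool(qc_status.get(read.read_id, False))
        aln = assignment.get(read.read_id) if passed else None
        contig = aln.taxon_id if aln is not None else ""
        rows = by_read.get(read.read_id, [])
        if rows:
            uniq = len(rows) == 1
            for srow in rows:
                out.append(
                    ManifestRow(
                        sample_id=sample_id,
                        read_id=read.read_id,
                        read_len=read.length,
                        read_qscore=srow.mean_qscore_template,
                        channel=srow.channel,
                        start_time=srow.start_time,
                        end_time=srow.end_time,
                        decision=srow.end_reason,
                        fastp_status=passed,
                        is_mapped=aln is not None,
                        is_uniq=uniq,
                        contig_id=contig,
                    )
                )
        else:
            out.append(
                ManifestRow(
                    sample_id=sample_id,
                    read_id=read.read_id,
                    read_len=read.length,
                    read_qscore=mean_qscore(read),
                    channel=None,
                    start_time=None,
                    end_time=None,
                    decision="",
                    fastp_status=passed,
                    is_mapped=aln is not None,
                    is_uniq=True,
                    contig_id=contig,
                )
            )
    return out


def manifest_frame(rows: Sequence[ManifestRow]) -> pd.DataFrame:
    df = pd.DataFrame(
        [
            {
                "sample_id": r.sample_id,
                "read_id": r.read_id,
                "read_len": r.read_len,
                "read_qscore": r.read_qscore,
                "channel": r.channel,
                "start_time": r.start_time,
                "end_time": r.end_time,
                "decision": r.decision,
                "fastp_status": r.fastp_status,
                "is_mapped": r.is_mapped,
                "is_uniq": r.is_uniq,
                "contig_id": r.contig_id,
            }
            for r in rows
        ],
        columns=list(MANIFEST_COLUMNS),
    )
    return df


def pct_covered_column(threshold: int) -> str:
    return f"taxon_%_covered_bases_{threshold}X"


def covered_column(threshold: int) -> str:
    return f"taxon_covered_bases_{threshold}X"


def build_manifest_summary(
    taxon_stats: Sequence[TaxonStats],
    qc: QcStats,
    est_genome_size: float = 0.0,
    est_coverage: float = 0.0,
) -> pd.DataFrame:
    """Assemble the per-taxon summary table with sample-wide fields attached.

    Rows are ordered by taxon_id with the "*" unmapped row last. The
    covered-bases column names carry the active depth threshold (e.g.
    ``taxon_%_covered_bases_5X``). Sample-wide fields are replicated on
    every row, matching the summary-file layout.
    """
    stats = sorted(
        taxon_stats, key=lambda t: (t.taxon_id == UNMAPPED, t.taxon_id)
    )
    threshold = stats[0].threshold if stats else 1
    records = []
    for t in stats:
        records.append(
            {
                "taxon_id": t.taxon_id,
                "taxon_length": t.taxon_length,
                "taxon_mean_coverage": t.taxon_mean_coverage,
                covered_column(threshold): t.taxon_covered_bases,
                pct_covered_column(threshold): t.taxon_pct_covered_bases,
                "total_taxon_ref_mapped_bases": t.total_taxon_ref_mapped_bases,
                "taxon_mean_read_length": t.taxon_mean_read_length,
                "est_genome_size": est_genome_size,
                "est_coverage": est_coverage,
                "total_bases": qc.total_bases,
                "total_fastp_bases": qc.total_fastp_bases,
                "mean_read_length": qc.mean_read_length,
            }
        )
    return pd.DataFrame(records)


def write_manifest(rows: Sequence[ManifestRow], path: PathLike) -> None:
    manifest_frame(rows).to_csv(path, sep="\t", index=False)


def write_manifest_summary(summary: pd.DataFrame, path: PathLike) -> None:
    summary.to_csv(path, sep="\t", index=False)


def read_manifest(path: PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", keep_default_na=True)


def read_manifest_summary(path: PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
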