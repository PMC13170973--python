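"""Strict readers and writers for the pipeline's text formats.

Covers 4-line FASTQ (plain or gzip), multi-record FASTA references, SAM
alignments (via pysam) and the ONT sequencing-summary TSV emitted by the
basecaller. Every downstream stage consumes only the parsed record types
defined here; nothing else in the package touches raw files.

FASTQ validation follows the basecaller-output convention: each record is
exactly four lines, '@' must open line 1 and '+' line 3, and the sequence
and quality strings must be the same length. Wrapped (multi-line) FASTQ is
rejected by design. Read identity is the first whitespace-delimited token
of the header, matching aligner and sequencing-summary conventions.
"""

from __future__ import annotations

import gzip
import io
from dataclasses import dataclass
from pathlib import Path
from typing import IO, Iterable, Iterator, List, Optional, Sequence, Union

import pandas as pd
import pysam
from Bio import SeqIO

PathLike = Union[str, Path]

#: marker used for reads without a mapped reference (SAM convention)
UNMAPPED = "*"

#: columns the sequencing summary must provide (any order; extras ignored)
REQUIRED_SUMMARY_COLUMNS = (
    "read_id",
    "channel",
    "start_time",
    "duration",
    "sequence_length_template",
    "mean_qscore_template",
    "end_reason",
)

_NUMERIC_SUMMARY_COLUMNS = (
    "channel",
    "start_time",
    "duration",
    "sequence_length_template",
    "mean_qscore_template",
)


class FormatError(ValueError):
    """A record violates the format contract (malformed FASTQ/SAM/FASTA)."""


class ConfigError(ValueError):
    """An input file lacks a required column or is otherwise unusable."""


# ---------------------------------------------------------------------------
# record types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FastqRead:
    """One basecalled read: id, sequence over {A,C,G,T,N}, phred+33 quality."""

    read_id: str
    sequence: str
    quality: str

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class ReferenceSeq:
    """One reference sequence ("taxon"); id is the first FASTA header token."""

    taxon_id: str
    sequence: str

    @property
    def taxon_length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class SummaryRow:
    """One sequencing-summary record (one pore event for one read)."""

    read_id: str
    channel: int
    start_time: float
    duration: float
    sequence_length_template: int
    mean_qscore_template: float
    end_reason: str

    @property
    def end_time(self) -> float:
        return self.start_time + self.duration


@dataclass(frozen=True)
class AlignmentRecord:
    """One SAM alignment, normalised to the fields the pipeline needs.

    ``pos`` is the 1-based leftmost reference coordinate as printed in SAM;
    conversion to 0-based half-open happens in one place (coverage_stats).
    """

    read_id: str
    taxon_id: str  # UNMAPPED ("*") when the read did not map
    flag: int
    pos: int
    cigar: str
    mapq: int
    read_length: int

    @property
    def is_mapped(self) -> bool:
        return not self.flag & 0x4

    @property
    def is_secondary(self) -> bool:
        return bool(self.flag & 0x100)

    @property
    def is_supplementary(self) -> bool:
        return bool(self.flag & 0x800)

    @property
    def is_primary(self) -> bool:
        return not (self.is_secondary or self.is_supplementary)


# ---------------------------------------------------------------------------
# low-level IO helpers
# ---------------------------------------------------------------------------

def open_text(path: PathLike) -> IO[str]:
    """Open plain or gzipped text, sniffing gzip by magic bytes, not suffix."""
    path = Path(path)
    with open(path, "rb") as fh:
        magic = fh.read(2)
    if magic == b"\x1f\x8b":
        return io.TextIOWrapper(gzip.open(path, "rb"))
    return open(path, "rt")


# ---------------------------------------------------------------------------
# FASTQ
# ---------------------------------------------------------------------------

def _first_token(header: str) -> str:
    return header.split(None, 1)[0] if header.strip() else ""


def parse_fastq(path: PathLike, strict: bool = True) -> Iterator[FastqRead]:
    """Yield :class:`FastqRead` records from a 4-line FASTQ file.

    In strict mode (the default, and what the analyze stage uses) the first
    malformed record aborts the whole parse with a :class:`FormatError`
    naming the offending record index. With ``strict=False`` malformed
    records are silently dropped, which is only appropriate for exploratory
    use.
    """
    with open_text(path) as fh:
        record_index = 0
        while True:
            header = fh.readline()
            if not header:
                return
            if header.strip() == "":
                continue  # tolerate trailing blank lines
            record_index += 1
            seq = fh.readline().rstrip("\n")
            plus = fh.readline()
            qual = fh.readline().rstrip("\n")
            if not plus:
                raise FormatError(
                    f"record {record_index}: truncated record (fewer than 4 lines)"
                )
            errors = []
            if not header.startswith("@"):
                errors.append("line 1 does not start with '@'")
            if not plus.startswith("+"):
                errors.append("line 3 does not start with '+'")
            if len(seq) != len(qual):
                errors.append(
                    f"sequence length {len(seq)} != quality length {len(qual)}"
                )
            read_id = _first_token(header[1:])
            if not errors and not read_id:
                errors.append("empty read id")
            if errors:
                if strict:
                    raise FormatError(
                        f"record {record_index}: " + "; ".join(errors)
                    )
                continue
            yield FastqRead(read_id=read_id, sequence=seq, quality=qual)


def write_fastq(reads: Iterable[FastqRead], path: PathLike) -> int:
    """Write reads as 4-line FASTQ; returns the number of records written."""
    n = 0
    with open(path, "wt") as fh:
        for r in reads:
            fh.write(f"@{r.read_id}\n{r.sequence}\n+\n{r.quality}\n")
            n += 1
    return n


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def parse_fasta(path: PathLike) -> List[ReferenceSeq]:
    """Read a (multi-)FASTA reference set; taxon ids must be unique."""
    refs: List[ReferenceSeq] = []
    seen = set()
    with open_text(path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            taxon_id = rec.id
            seq = str(rec.seq).upper()
            if not seq:
                raise FormatError(f"reference {taxon_id!r} has empty sequence")
            if taxon_id in seen:
                raise FormatError(f"duplicate taxon_id {taxon_id!r} in reference")
            seen.add(taxon_id)
            refs.append(ReferenceSeq(taxon_id=taxon_id, sequence=seq))
    if not refs:
        raise FormatError(f"no FASTA records found in {path}")
    return refs


def write_fasta(refs: Iterable[ReferenceSeq], path: PathLike) -> None:
    with open(path, "wt") as fh:
        for ref in refs:
            fh.write(f">{ref.taxon_id}\n")
            seq = ref.sequence
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")


# ---------------------------------------------------------------------------
# sequencing summary
# ---------------------------------------------------------------------------

def parse_sequencing_summary(path: PathLike) -> List[SummaryRow]:
    """Parse the basecaller sequencing-summary TSV into :class:`SummaryRow`s.

    Required columns may appear in any order; unknown columns are ignored.
    A missing required column raises :class:`ConfigError` naming it; an
    unparsable numeric cell raises :class:`FormatError` with its line number.
    """
    with open_text(path) as fh:
        df = pd.read_csv(fh, sep="\t", dtype=str)
    missing = [c for c in REQUIRED_SUMMARY_COLUMNS if c not in df.columns]
    if missing:
        raise ConfigError(
            "sequencing summary is missing required column(s): "
            + ", ".join(missing)
        )
    converted = {}
    for col in _NUMERIC_SUMMARY_COLUMNS:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() & df[col].notna()
        if bad.any():
            line = int(bad.idxmax()) + 2  # +1 header, +1 one-based
            raise FormatError(
                f"line {line}: cannot parse {col}={df[col][bad.idxmax()]!r}"
            )
        if vals.isna().any():
            line = int(vals.isna().idxmax()) + 2
            raise FormatError(f"line {line}: empty value in column {col}")
        converted[col] = vals
    rows: List[SummaryRow] = []
    for i in range(len(df)):
        rows.append(
            SummaryRow(
                read_id=str(df["read_id"].iloc[i]),
                channel=int(converted["channel"].iloc[i]),
                start_time=float(converted["start_time"].iloc[i]),
                duration=float(converted["duration"].iloc[i]),
                sequence_length_template=int(
                    converted["sequence_length_template"].iloc[i]
                ),
                mean_qscore_template=float(
                    converted["mean_qscore_template"].iloc[i]
                ),
                end_reason=str(df["end_reason"].iloc[i]).strip(),
            )
        )
    return rows


def write_sequencing_summary(rows: Iterable[SummaryRow], path: PathLike) -> None:
    """Write rows in the basecaller's TSV layout (required columns only)."""
    with open(path, "wt") as fh:
        fh.write("\t".join(REQUIRED_SUMMARY_COLUMNS) + "\n")
        for r in rows:
            fh.write(
                f"{r.read_id}\t{r.channel}\t{r.start_time:.6f}\t"
                f"{r.duration:.6f}\t{r.sequence_length_template}\t"
                f"{r.mean_qscore_template:.6f}\t{r.end_reason}\n"
            )


# ---------------------------------------------------------------------------
# SAM
# ---------------------------------------------------------------------------

def parse_sam(path: PathLike) -> List[AlignmentRecord]:
    """Parse a SAM file (with @SQ headers for all mapped targets) via pysam."""
    records: List[AlignmentRecord] = []
    try:
        with pysam.AlignmentFile(str(path), "r") as sam:
            for aln in sam.fetch(until_eof=True):
                if aln.is_unmapped:
                    taxon_id = UNMAPPED
                    pos = 0
                    cigar = "*"
                else:
                    taxon_id = aln.reference_name
                    pos = aln.reference_start + 1  # back to SAM 1-based
                    cigar = aln.cigarstring or "*"
                length = aln.query_length or aln.infer_read_length() or 0
                records.append(
                    AlignmentRecord(
                        read_id=aln.query_name,
                        taxon_id=taxon_id,
                        flag=aln.flag,
                        pos=pos,
                        cigar=cigar,
                        mapq=aln.mapping_quality,
                        read_length=int(length),
                    )
                )
    except ValueError as exc:
        raise FormatError(f"malformed SAM {path}: {exc}") from exc
    return records


def sam_reference_lengths(path: PathLike) -> dict:
    """Return the @SQ name->length map, for cross-checks against the FASTA."""
    with pysam.AlignmentFile(str(path), "r") as sam:
        return dict(zip(sam.references, sam.lengths))
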