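"""Read-to-reference alignment: external aligner adapter + SAM normalisation.

Alignments come from one of two routes with the same downstream contract:
invoking minimap2 as a subprocess with the pipeline's presets (``map-ont``
for single-end long reads, ``sr`` for paired short reads, k-mer size fixed
at 15), or ingesting a user-supplied SAM via :func:`formats.parse_sam`.
Either way, coverage statistics are computed from PRIMARY alignments only:
secondary (0x100) and supplementary (0x800) records are dropped so that
per-read totals stay conserved, idxstats-style. No MAPQ floor is applied.
"""

from __future__ import annotations

import re
import shutil
import subprocess
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence

from .formats import AlignmentRecord, FormatError, PathLike

#: maps the module's preset names onto minimap2 -x presets
PRESET_FLAGS = {
    "long_read_ont": "map-ont",
    "short_read_paired": "sr",
}

_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")


class AlignerNotFoundError(RuntimeError):
    """The external aligner executable is not on PATH."""


class AlignerError(RuntimeError):
    """The external aligner exited non-zero; stderr is attached."""


class DataError(ValueError):
    """Alignment data violates an internal consistency contract."""


@dataclass(frozen=True)
class AlignerConfig:
    """How to invoke the external aligner."""

    preset: str = "long_read_ont"
    kmer: int = 15
    executable: str = "minimap2"

    def __post_init__(self) -> None:
        if self.preset not in PRESET_FLAGS:
            raise ValueError(
                f"unknown preset {self.preset!r}; expected one of "
                f"{sorted(PRESET_FLAGS)}"
            )
        if self.kmer < 1:
            raise ValueError("kmer must be >= 1")


def align(
    reads: PathLike,
    reference: PathLike,
    out_sam: PathLike,
    config: AlignerConfig = AlignerConfig(),
    mate_reads: Optional[PathLike] = None,
) -> Path:
    """Run the external aligner, writing a SAM with @SQ lines, and return its path.

    ``mate_reads`` supplies the second FASTQ in paired short-read mode.
    Raises :class:`AlignerNotFoundError` with a pointer at SAM-input mode
    when the executable is absent, and :class:`AlignerError` carrying the
    tool's stderr on non-zero exit.
    """
    exe = shutil.which(config.executable)
    if exe is None:
        raise AlignerNotFoundError(
            f"{config.executable!r} not found on PATH; either install it or "
            "supply precomputed alignments as SAM (--sam / load_alignments)"
        )
    cmd = [
        exe,
        "-ax",
        PRESET_FLAGS[config.preset],
        "-k",
        str(config.kmer),
        str(reference),
        str(reads),
    ]
    if mate_reads is not None:
        cmd.append(str(mate_reads))
    out_sam = Path(out_sam)
    with open(out_sam, "wb") as out:
        proc = subprocess.run(cmd, stdout=out, stderr=subprocess.PIPE)
    if proc.returncode != 0:
        raise AlignerError(
            f"{config.executable} exited {proc.returncode}: "
            + proc.stderr.decode(errors="replace").strip()
        )
    return out_sam


def select_primary(
    alignments: Iterable[AlignmentRecord],
) -> List[AlignmentRecord]:
    """Drop secondary/supplementary records; keep primaries and unmapped.

    At most one mapped record may remain per read id; a second mapped
    primary for the same read is a data error (malformed aligner output).
    """
    out: List[AlignmentRecord] = []
    seen_mapped: set = set()
    for aln in alignments:
        if not aln.is_primary:
            continue
        if aln.is_mapped:
            if aln.read_id in seen_mapped:
                raise DataError(
                    f"read {aln.read_id!r} has more than one primary mapped "
                    "alignment"
                )
            seen_mapped.add(aln.read_id)
        out.append(aln)
    return out


def parse_cigar(cigar: str) -> List[tuple]:
    """Split a CIGAR string into (length, op) tuples, validating syntax."""
    if cigar in ("", "*"):
        return []
    ops = _CIGAR_RE.findall(cigar)
    if "".join(f"{n}{op}" for n, op in ops) != cigar:
        raise FormatError(f"malformed CIGAR {cigar!r}")
    return [(int(n), op) for n, op in ops]


def aligned_ref_span(cigar: str) -> int:
    """Reference positions covered by M/=/X operations.

    Deletions (D) and skips (N) advance along the reference but contribute
    no coverage; insertions and clips consume no reference at all. This is
    the quantity that feeds per-base depth and mapped-base totals.
    """
    return sum(n for n, op in parse_cigar(cigar) if op in "M=X")


def reference_span(cigar: str) -> int:
    """Total reference length consumed (M/=/X/D/N), i.e. the footprint."""
    return sum(n for n, op in parse_cigar(cigar) if op in "M=XDN")


def primary_assignment(
    alignments: Iterable[AlignmentRecord],
) -> Dict[str, AlignmentRecord]:
    """Map read_id -> its primary mapped alignment (unmapped reads absent)."""
    return {
        a.read_id: a for a in select_primary(alignments) if a.is_mapped
    }
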