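"""Read quality filtering with exact-duplicate removal, plus sample stats.

Reproduces the behaviour of a default fastp run with deduplication switched
on, frozen to the published defaults of that tool: bases with phred < 15
are "unqualified" and a read fails when more than 40% of its bases are
unqualified, when it carries more than 5 N bases, or when it is shorter
than 15 bases. Deduplication keeps the first occurrence of each exact
sequence string. Adapter/quality trimming is deliberately omitted (rapid
kits, long reads); this is an approximation of the external tool, not a
byte-for-byte port.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Tuple

import numpy as np

from .formats import FastqRead

PHRED_OFFSET = 33


@dataclass(frozen=True)
class QcParams:
    """Thresholds for the read filter (defaults mirror fastp's defaults)."""

    qualified_phred: int = 15
    max_unqualified_fraction: float = 0.40
    max_n_bases: int = 5
    min_length: int = 15
    dedup: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.max_unqualified_fraction <= 1.0:
            raise ValueError("max_unqualified_fraction must be in [0, 1]")
        if min(self.qualified_phred, self.max_n_bases, self.min_length) < 0:
            raise ValueError("thresholds must be >= 0")


@dataclass
class QcStats:
    """Sample-wide base/length statistics around the filter."""

    total_bases: int = 0          # pre-filter
    total_fastp_bases: int = 0    # post-filter
    reads_in: int = 0
    reads_out: int = 0
    failures: int = 0
    duplicates_removed: int = 0

    @property
    def mean_read_length(self) -> float:
        """Mean post-filter read length (0 when nothing passed)."""
        return self.total_fastp_bases / self.reads_out if self.reads_out else 0.0


def phred_array(quality: str) -> np.ndarray:
    """Decode a phred+33 quality string to an integer score array."""
    return np.frombuffer(quality.encode("ascii"), dtype=np.uint8).astype(
        np.int64
    ) - PHRED_OFFSET


def mean_qscore(read_or_quality) -> float:
    """Error-probability-averaged phred score of a read.

    Returns -10*log10(mean_i 10^(-q_i/10)): the quality of the mean
    per-base error probability, which is how basecallers summarise
    per-read accuracy (and is dominated by the worst bases, unlike a
    plain mean of the scores).
    """
    quality = getattr(read_or_quality, "quality", read_or_quality)
    if len(quality) == 0:
        raise ValueError("empty quality string")
    q = phred_array(quality)
    return float(-10.0 * math.log10(np.mean(10.0 ** (-q / 10.0))))


def _passes_thresholds(read: FastqRead, params: QcParams) -> bool:
    if read.length < params.min_length:
        return False
    if read.sequence.count("N") > params.max_n_bases:
        return False
    if read.length:
        q = phred_array(read.quality)
        unqualified = float(np.mean(q < params.qualified_phred))
        if unqualified > params.max_unqualified_fraction:
            return False
    return True


def qc_filter(
    reads: Iterable[FastqRead], params: QcParams = QcParams()
) -> Tuple[List[FastqRead], Dict[str, bool], QcStats]:
    """Apply the filter; returns (kept reads, per-read verdict, stats).

    A read is kept iff it passes all thresholds AND (with dedup) its exact
    sequence has not been seen among earlier threshold-passing reads.
    Conservation: reads_in == reads_out + failures + duplicates_removed.
    """
    kept: List[FastqRead] = []
    status: Dict[str, bool] = {}
    stats = QcStats()
    seen: set = set()
    for read in reads:
        stats.reads_in += 1
        stats.total_bases += read.length
        ok = _passes_thresholds(read, params)
        if ok and params.dedup:
            if read.sequence in seen:
                stats.duplicates_removed += 1
                status[read.read_id] = False
                continue
            seen.add(read.sequence)
        if ok:
            kept.append(read)
            stats.reads_out += 1
            stats.total_fastp_bases += read.length
        else:
            stats.failures += 1
        status[read.read_id] = ok
    return kept, status, stats
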