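"""Summary-driven read subsetting: the filter stage of the pipeline.

Reads are selected by criteria evaluated against the sequencing-summary
table, never against the FASTQ itself: channel range, read length, Q
score, start-time window, per-read duration, and raw end_reason tokens.
All bounds are inclusive; every criterion is optional. A read that
appears in several summary rows (re-evaluated strands) is kept if ANY of
its rows matches — subsetting is all-or-nothing per read id.

The canonical use is splitting one flow cell into test and control
conditions by channel range (e.g. adaptive-sampling depletion on channels
1-256, standard sequencing on 257-512).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, Iterator, Optional, Sequence, Set, Tuple

from .formats import FastqRead, SummaryRow


class CriteriaError(ValueError):
    """Raised when a bound pair has min > max."""


@dataclass(frozen=True)
class FilterCriteria:
    """Optional inclusive bounds on summary fields; None = no constraint."""

    min_ch: Optional[int] = None
    max_ch: Optional[int] = None
    min_len: Optional[int] = None
    max_len: Optional[int] = None
    min_q: Optional[float] = None
    max_q: Optional[float] = None
    start_time_min: Optional[float] = None
    start_time_max: Optional[float] = None
    min_duration: Optional[float] = None
    max_duration: Optional[float] = None
    decisions: Optional[frozenset] = None  # raw end_reason tokens

    def __post_init__(self) -> None:
        for lo, hi, name in (
            (self.min_ch, self.max_ch, "channel"),
            (self.min_len, self.max_len, "length"),
            (self.min_q, self.max_q, "q score"),
            (self.start_time_min, self.start_time_max, "start time"),
            (self.min_duration, self.max_duration, "duration"),
        ):
            if lo is not None and hi is not None and lo > hi:
                raise CriteriaError(f"{name} bounds: min {lo} > max {hi}")
        if self.decisions is not None:
            object.__setattr__(
                self,
                "decisions",
                frozenset(d.strip().lower() for d in self.decisions),
            )

    def matches(self, row: SummaryRow) -> bool:
        """True iff every present criterion holds for this summary row."""
        checks: Tuple[Tuple[Optional[float], Optional[float], float], ...] = (
            (self.min_ch, self.max_ch, row.channel),
            (self.min_len, self.max_len, row.sequence_length_template),
            (self.min_q, self.max_q, row.mean_qscore_template),
            (self.start_time_min, self.start_time_max, row.start_time),
            (self.min_duration, self.max_duration, row.duration),
        )
        for lo, hi, value in checks:
            if lo is not None and value < lo:
                return False
            if hi is not None and value > hi:
                return False
        if self.decisions is not None:
            if row.end_reason.strip().lower() not in self.decisions:
                return False
        return True


def match_reads(
    summary: Iterable[SummaryRow], criteria: FilterCriteria
) -> Set[str]:
    """Read ids with at least one summary row satisfying all criteria."""
    return {row.read_id for row in summary if criteria.matches(row)}


def subset_fastq(
    reads: Iterable[FastqRead], keep: Set[str]
) -> Iterator[FastqRead]:
    """Yield, in input order, exactly the reads whose id is in ``keep``.

    Ids in ``keep`` that never occur in the input are not an error; callers
    wanting the count can compare ``keep`` against the ids they saw.
    """
    for read in reads:
        if read.read_id in keep:
            yield read
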