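"""Classify pore-level read-end reasons into adaptive-sampling decisions.

The sequencing summary does not record the selective-sequencing API's
per-read decisions directly; the per-read ``end_reason`` is a practical
retrospective proxy. Tokens map onto three decision classes:

* ``signal_positive``                  -> ``stop_receiving`` (accepted; the
  pore sequenced the strand to its natural end)
* ``data_service_unblock_mux_change``  -> ``unblocked`` (rejected; voltage
  reversed to eject the strand)
* ``signal_negative``, ``unblock_mux_change`` -> ``no_decision`` (no
  explicit accept/reject was issued)

Any other token is "unknown": counted, but excluded from percentage
denominators, since the three-class scheme is explicitly approximate.
Matching is case-insensitive with whitespace trimmed (both capitalised
and lower-case spellings occur in basecaller output).

Time-binned distributions come in two flavours: *independent* bins
(left-closed right-open, contiguous, a row binned by its start time) and
*cumulative* bins (bin i aggregates bins 0..i).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

DECISION_CLASSES = ("stop_receiving", "unblocked", "no_decision")

END_REASON_MAP = {
    "signal_positive": "stop_receiving",
    "data_service_unblock_mux_change": "unblocked",
    "signal_negative": "no_decision",
    "unblock_mux_change": "no_decision",
}


def classify_end_reason(end_reason: str) -> Optional[str]:
    """Decision class for a raw end_reason token, or None if unknown."""
    return END_REASON_MAP.get(end_reason.strip().lower())


@dataclass(frozen=True)
class DecisionBin:
    """One time interval with per-class counts (percentages derived)."""

    bin_start: float
    bin_end: float
    counts: Dict[str, int]
    unknown: int = 0

    @property
    def read_count(self) -> int:
        """Number of classified rows in the bin."""
        return sum(self.counts.values())

    @property
    def pct(self) -> Dict[str, float]:
        """Per-class percentages over classified rows; sums to 100."""
        total = self.read_count
        if total == 0:
            return {c: 0.0 for c in DECISION_CLASSES}
        return {c: 100.0 * self.counts[c] / total for c in DECISION_CLASSES}


def _event(row) -> Tuple[float, str]:
    """Pull (start_time, end_reason token) off a summary/manifest-like row."""
    if isinstance(row, tuple):
        return float(row[0]), str(row[1])
    reason = getattr(row, "end_reason", None)
    if reason is None:
        reason = getattr(row, "decision")
    return float(row.start_time), str(reason)


def bin_decisions(rows: Iterable, bin_width: float) -> List[DecisionBin]:
    """Independent time bins of decision events.

    ``rows`` may be SummaryRow/ManifestRow objects or (start_time, token)
    tuples; every row is an event (re-evaluated strands count once per
    occurrence). A row falls in bin floor(start_time / bin_width); bins
    span [0, max start_time]. Returns [] when nothing classifies.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    events = [_event(r) for r in rows]
    classified = [
        (t, classify_end_reason(tok), tok) for t, tok in events
    ]
    if not any(cls is not None for _, cls, _ in classified):
        return []
    max_t = max(t for t, _, _ in classified)
    n_bins = int(math.floor(max_t / bin_width)) + 1
    counts = [
        {c: 0 for c in DECISION_CLASSES} for _ in range(n_bins)
    ]
    unknown = [0] * n_bins
    for t, cls, _tok in classified:
        idx = min(int(math.floor(t / bin_width)), n_bins - 1)
        if cls is None:
            unknown[idx] += 1
        else:
            counts[idx][cls] += 1
    return [
        DecisionBin(
            bin_start=i * bin_width,
            bin_end=(i + 1) * bin_width,
            counts=counts[i],
            unknown=unknown[i],
        )
        for i in range(n_bins)
    ]


def cumulate_bins(independent: Sequence[DecisionBin]) -> List[DecisionBin]:
    """Cumulative view: output bin i aggregates input bins 0..i."""
    out: List[DecisionBin] = []
    running = {c: 0 for c in DECISION_CLASSES}
    running_unknown = 0
    start = independent[0].bin_start if independent else 0.0
    for b in independent:
        for c in DECISION_CLASSES:
            running[c] += b.counts[c]
        running_unknown += b.unknown
        out.append(
            DecisionBin(
                bin_start=start,
                bin_end=b.bin_end,
                counts=dict(running),
                unknown=running_unknown,
            )
        )
    return out


def overall_tally(rows: Iterable) -> DecisionBin:
    """Whole-run classification distribution as a single bin."""
    events = [_event(r) for r in rows]
    counts = {c: 0 for c in DECISION_CLASSES}
    unknown = 0
    max_t = 0.0
    for t, tok in events:
        cls = classify_end_reason(tok)
        max_t = max(max_t, t)
        if cls is None:
            unknown += 1
        else:
            counts[cls] += 1
    return DecisionBin(bin_start=0.0, bin_end=max_t, counts=counts, unknown=unknown)
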