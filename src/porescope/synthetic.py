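"""Deterministic generator of complete mock adaptive-sampling runs.

Emulates the study design every stage of the pipeline is built around: a
mock community of reference genomes at specified relative abundances is
sequenced on a flow cell whose channels are split between an
adaptive-sampling (AS) condition depleting one target taxon and a control
condition sequencing everything. Reads are substrings of their source
genome with seeded substitution errors; depletion-target reads that land
on AS channels are, with a configurable probability, truncated to roughly
the unblock decision window (~400 bases at a 1 s window) and annotated
``data_service_unblock_mux_change``, while accepted reads end with
``signal_positive``. A configurable fraction of events carries the
no-decision tokens, and a fraction of reads is re-evaluated (extra
summary rows for the same read id). The sequencing summary is consistent
with the FASTQ (lengths and error-averaged Q scores match) and a truth
SAM records the generating coordinates.

Genomes are i.i.d. uniform random sequences, so mapping truth is
unambiguous; an optional homology fraction copies a block of the target
genome into the others to emulate conserved-region misassignment
qualitatively. All randomness flows from the scenario seed through one
named generator: a fixed seed gives byte-identical output files.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pysam

from .formats import (
    FastqRead,
    ReferenceSeq,
    SummaryRow,
    write_fasta,
    write_fastq,
    write_sequencing_summary,
)
from .read_qc import mean_qscore

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}

#: pore translocation speed used to derive event durations (bases/second)
SEQUENCING_SPEED = 400.0


def revcomp(seq: str) -> str:
    return "".join(_COMPLEMENT[b] for b in reversed(seq))


@dataclass(frozen=True)
class TaxonSpec:
    taxon_id: str
    genome_length: int
    relative_abundance: float


@dataclass(frozen=True)
class RunScenario:
    """Parameters of one simulated flow-cell run.

    Defaults emulate the channel-split depletion design: 512 channels,
    AS depletion of the dominant taxon on channels 1-256, control on
    257-512, log-normal read lengths (median ~1.5 kb), ~400-base unblock
    truncation, and a 4 h run.
    """

    taxa: Tuple[TaxonSpec, ...]
    read_count: int = 4000
    read_length_mean_log: float = 7.3   # ln bases; median ~1480 b
    read_length_sigma: float = 0.35
    error_rate: float = 0.02
    channels: Tuple[int, int] = (1, 512)
    as_channels: Tuple[int, int] = (1, 256)
    depletion_target: str = ""
    unblock_truncation_length: int = 400
    unblock_probability: float = 0.75
    no_decision_fraction: float = 0.0
    reevaluation_fraction: float = 0.02
    low_quality_fraction: float = 0.01
    duplicate_fraction: float = 0.0
    qscore_loc: float = 19.0
    run_duration: float = 14400.0
    homology_fraction: float = 0.0
    seed: int = 1

    def __post_init__(self) -> None:
        total = sum(t.relative_abundance for t in self.taxa)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"relative abundances sum to {total}, not 1")
        if not (
            self.channels[0] <= self.as_channels[0]
            and self.as_channels[1] <= self.channels[1]
        ):
            raise ValueError("as_channels must be a subrange of channels")
        if self.depletion_target and self.depletion_target not in {
            t.taxon_id for t in self.taxa
        }:
            raise ValueError(
                f"depletion_target {self.depletion_target!r} not among taxa"
            )

    @property
    def expected_unblock_pct(self) -> float:
        """Planted unblocked percentage among classified AS-channel events.

        Each read contributes one pore event; re-evaluated reads add one
        extra no-decision event on the same channel, which inflates the
        classified-event denominator by (1 + reevaluation_fraction).
        """
        if not self.depletion_target:
            return 0.0
        abundance = next(
            t.relative_abundance
            for t in self.taxa
            if t.taxon_id == self.depletion_target
        )
        per_read = (
            (1.0 - self.no_decision_fraction)
            * abundance
            * self.unblock_probability
        )
        return 100.0 * per_read / (1.0 + self.reevaluation_fraction)


def depletion_scenario(seed: int = 1, **overrides) -> RunScenario:
    """The canonical two-taxon depletion scenario used across the tests.

    The depletion target dominates the community (80% abundance) and is
    unblocked with probability 0.75 on AS channels, planting a 60%
    unblocked rate among AS-channel events.
    """
    params = dict(
        taxa=(
            TaxonSpec("taxon_a", 60_000, 0.80),
            TaxonSpec("taxon_b", 40_000, 0.20),
        ),
        depletion_target="taxon_a",
        seed=seed,
    )
    params.update(overrides)
    return RunScenario(**params)


def _random_genome(rng: np.random.Generator, length: int) -> str:
    return _BASES[rng.integers(0, 4, size=length)].tobytes().decode("ascii")


def _make_quality(rng: np.random.Generator, n: int, loc: float) -> str:
    q = np.clip(np.rint(rng.normal(loc, 6.0, size=n)), 2, 35).astype(np.uint8)
    return (q + 33).tobytes().decode("ascii")


def _mutate(rng: np.random.Generator, seq: str, error_rate: float) -> str:
    if error_rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    hits = np.nonzero(rng.random(len(arr)) < error_rate)[0]
    if len(hits) == 0:
        return seq
    shifts = rng.integers(1, 4, size=len(hits))
    code = {65: 0, 67: 1, 71: 2, 84: 3}
    inv = _BASES
    for i, s in zip(hits, shifts):
        arr[i] = inv[(code.get(int(arr[i]), 0) + int(s)) % 4]
    return arr.tobytes().decode("ascii")


@dataclass
class _ReadTruth:
    read_id: str
    taxon_id: str
    start: int          # 0-based on the genome
    length: int
    reverse: bool
    channel: int
    end_reason: str


def generate_run(scenario: RunScenario, outdir) -> Dict[str, Path]:
    """Write reference FASTA, reads FASTQ, summary TSV, truth SAM + JSON.

    Returns a dict of output paths keyed by
    ``reference/reads/summary/sam/truth``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(scenario.seed)

    # genomes
    refs: List[ReferenceSeq] = []
    genomes: Dict[str, str] = {}
    for spec in scenario.taxa:
        genomes[spec.taxon_id] = _random_genome(rng, spec.genome_length)
    if scenario.homology_fraction > 0 and scenario.depletion_target:
        src = genomes[scenario.depletion_target]
        block = src[: int(len(src) * scenario.homology_fraction)]
        for spec in scenario.taxa:
            if spec.taxon_id != scenario.depletion_target:
                g = genomes[spec.taxon_id]
                genomes[spec.taxon_id] = block + g[len(block):]
    for spec in scenario.taxa:
        refs.append(ReferenceSeq(spec.taxon_id, genomes[spec.taxon_id]))

    abundances = np.array([t.relative_abundance for t in scenario.taxa])
    taxon_ids = [t.taxon_id for t in scenario.taxa]
    as_lo, as_hi = scenario.as_channels
    ch_lo, ch_hi = scenario.channels

    n_unique = max(1, round(scenario.read_count * (1 - scenario.duplicate_fraction)))
    reads: List[FastqRead] = []
    summary_rows: List[SummaryRow] = []
    truths: List[_ReadTruth] = []

    for i in range(n_unique):
        read_id = f"read_{i:06d}"
        taxon = taxon_ids[int(rng.choice(len(taxon_ids), p=abundances))]
        genome = genomes[taxon]
        channel = int(rng.integers(ch_lo, ch_hi + 1))
        on_as = as_lo <= channel <= as_hi
        full_len = int(
            np.clip(
                rng.lognormal(scenario.read_length_mean_log, scenario.read_length_sigma),
                200,
                len(genome),
            )
        )
        u = rng.random()
        if u < scenario.no_decision_fraction:
            end_reason = str(rng.choice(["signal_negative", "unblock_mux_change"]))
            length = full_len
        elif (
            on_as
            and taxon == scenario.depletion_target
            and rng.random() < scenario.unblock_probability
        ):
            end_reason = "data_service_unblock_mux_change"
            length = int(
                np.clip(
                    rng.normal(
                        scenario.unblock_truncation_length,
                        scenario.unblock_truncation_length * 0.1,
                    ),
                    50,
                    full_len,
                )
            )
        else:
            end_reason = "signal_positive"
            length = full_len
        start = int(rng.integers(0, len(genome) - length + 1))
        reverse = bool(rng.random() < 0.5)
        fragment = genome[start : start + length]
        if reverse:
            fragment = revcomp(fragment)
        seq = _mutate(rng, fragment, scenario.error_rate)
        q_loc = (
            6.0 if rng.random() < scenario.low_quality_fraction else scenario.qscore_loc
        )
        qual = _make_quality(rng, length, q_loc)
        reads.append(FastqRead(read_id, seq, qual))
        truths.append(
            _ReadTruth(read_id, taxon, start, length, reverse, channel, end_reason)
        )
        start_time = float(rng.uniform(0, scenario.run_duration))
        duration = length / SEQUENCING_SPEED
        summary_rows.append(
            SummaryRow(
                read_id=read_id,
                channel=channel,
                start_time=start_time,
                duration=duration,
                sequence_length_template=length,
                mean_qscore_template=mean_qscore(qual),
                end_reason=end_reason,
            )
        )
        if rng.random() < scenario.reevaluation_fraction:
            # an earlier, inconclusive pore event for the same strand
            pre_t = max(0.0, start_time - float(rng.uniform(1.0, 30.0)))
            summary_rows.append(
                SummaryRow(
                    read_id=read_id,
                    channel=channel,
                    start_time=pre_t,
                    duration=0.5,
                    sequence_length_template=int(rng.integers(50, 200)),
                    mean_qscore_template=mean_qscore(qual),
                    end_reason="signal_negative",
                )
            )

    # exact duplicates of existing reads (for dedup exercising)
    n_dup = scenario.read_count - n_unique
    for j in range(n_dup):
        src = int(rng.integers(0, n_unique))
        orig, t = reads[src], truths[src]
        read_id = f"read_{n_unique + j:06d}"
        reads.append(FastqRead(read_id, orig.sequence, orig.quality))
        truths.append(
            _ReadTruth(
                read_id, t.taxon_id, t.start, t.length, t.reverse, t.channel, t.end_reason
            )
        )
        summary_rows.append(
            SummaryRow(
                read_id=read_id,
                channel=t.channel,
                start_time=float(rng.uniform(0, scenario.run_duration)),
                duration=t.length / SEQUENCING_SPEED,
                sequence_length_template=t.length,
                mean_qscore_template=mean_qscore(orig.quality),
                end_reason=t.end_reason,
            )
        )

    summary_rows.sort(key=lambda r: (r.start_time, r.read_id))

    as_events = [r for r in summary_rows if as_lo <= r.channel <= as_hi]
    planted_unblocked = sum(
        1 for r in as_events if r.end_reason == "data_service_unblock_mux_change"
    )

    paths = {
        "reference": outdir / "reference.fasta",
        "reads": outdir / "reads.fastq",
        "summary": outdir / "sequencing_summary.txt",
        "sam": outdir / "truth.sam",
        "truth": outdir / "truth.json",
    }
    write_fasta(refs, paths["reference"])
    write_fastq(reads, paths["reads"])
    write_sequencing_summary(summary_rows, paths["summary"])
    _write_truth_sam(refs, reads, truths, paths["sam"])

    truth = {
        "scenario": _scenario_dict(scenario),
        "expected_unblock_pct": scenario.expected_unblock_pct,
        "planted_unblocked_events": planted_unblocked,
        "as_channel_events": len(as_events),
        "control_channel_events": len(summary_rows) - len(as_events),
        "planted_unblock_pct": (
            100.0 * planted_unblocked / len(as_events) if as_events else 0.0
        ),
        "reads_per_taxon": {
            t: sum(1 for x in truths if x.taxon_id == t) for t in taxon_ids
        },
        "read_count": len(reads),
    }
    paths["truth"].write_text(json.dumps(truth, indent=2, sort_keys=True))
    return paths


def _scenario_dict(scenario: RunScenario) -> dict:
    d = asdict(scenario)
    d["taxa"] = [asdict(t) for t in scenario.taxa]
    return d


def _write_truth_sam(
    refs: Sequence[ReferenceSeq],
    reads: Sequence[FastqRead],
    truths: Sequence[_ReadTruth],
    path: Path,
) -> None:
    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [
            {"SN": r.taxon_id, "LN": r.taxon_length} for r in refs
        ],
    }
    by_id = {r.read_id: r for r in reads}
    ref_index = {r.taxon_id: i for i, r in enumerate(refs)}
    with pysam.AlignmentFile(str(path), "w", header=header) as sam:
        for t in truths:
            read = by_id[t.read_id]
            a = pysam.AlignedSegment(sam.header)
            a.query_name = t.read_id
            a.flag = 16 if t.reverse else 0
            a.reference_id = ref_index[t.taxon_id]
            a.reference_start = t.start
            a.mapping_quality = 60
            a.cigarstring = f"{t.length}M"
            # SAM stores the reference-oriented sequence
            seq = revcomp(read.sequence) if t.reverse else read.sequence
            qual = read.quality[::-1] if t.reverse else read.quality
            a.query_sequence = seq
            a.query_qualities = pysam.qualitystring_to_array(qual)
            sam.write(a)
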