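# Methods

## Pipeline model

porescope treats an adaptive-sampling (AS) run as three joined data
sources keyed by read id: the basecalled FASTQ, the basecaller's
sequencing-summary table (one row per pore event; a read re-evaluated by
the pore appears in several rows), and read-to-reference alignments.
The three stages are pure transformations over these:

1. **filter** — a read is selected iff *any* of its summary rows
   satisfies every present criterion (all bounds inclusive). Subsetting
   is all-or-nothing per read id, so multi-event reads are never split
   across conditions. Channel criteria therefore partition a flow cell
   exactly: the [1,256]/[257,512] split is disjoint and exhaustive,
   filtering is idempotent, and tightening any bound can only shrink
   the selection. These laws are property-tested.
2. **analyze** — QC filter, sketching, alignment, statistics (below).
3. **plot** — test-vs-control comparison of two analyze outputs.

## Read QC

The filter freezes the published defaults of fastp, the tool this step
emulates: a base is *qualified* at phred ≥ 15; a read fails when more
than 40% of its bases are unqualified, when it has more than 5 `N`
bases, or when it is shorter than 15 b. Deduplication removes exact
full-sequence duplicates, keeping the first occurrence. Adapter and
quality trimming are deliberately omitted (rapid-kit long reads); this
is an approximation of the external tool's behaviour, not a port, and
the conservation law reads_in = reads_out + failures + duplicates holds
exactly. Per-read Q scores are error-probability-averaged:
Q = −10·log₁₀(mean(10^(−qᵢ/10))), which is how basecallers summarise
read accuracy and is dominated by the worst bases.

## Coverage statistics

Primary alignments only (SAM flags 0x100/0x800 excluded, no MAPQ
floor), so per-read totals stay conserved, idxstats-style. Depth is
per-base via a difference array: M/=/X CIGAR operations add depth,
D/N advance along the reference without covering it, insertions and
clips contribute nothing. Consequently Σ depth = Σ aligned_ref_span
exactly, and mean coverage · reference length = total mapped bases.
Breadth at threshold X counts positions with depth ≥ X (inclusive);
X defaults to 1 and renames the output columns
(`taxon_%_covered_bases_5X` for X = 5). Per-taxon mean read length uses
*full* read lengths of reads primarily assigned to that taxon, so
AS-truncated reads visibly depress the mean. SAM coordinates are
1-based closed externally and converted to 0-based half-open in exactly
one place (`coverage_stats.cigar_ref_blocks`). Reporting rounds mean
coverage and percent breadth to two significant digits and read lengths
to integers; internal values keep full precision. When a SAM is
supplied instead of running the aligner, its records are first
restricted to QC-passed reads of the condition, preserving the
invariant that a QC-failed read is never counted as mapped.

## MinHash estimators

The sketch keeps the s = 1000 smallest splitmix64 hashes (fixed seed)
over distinct canonical 27-mers, with multiplicities. For FASTQ input,
k-mers seen fewer than m = 2 times are dropped first, suppressing
singleton error k-mers. Genome size is the k-minimum-values cardinality
estimate (s−1)·2⁶⁴/h₍ₛ₎ (exact distinct count while unsaturated);
coverage is the mean multiplicity of retained k-mers, which estimates
per-k-mer depth — base depth scaled by (L−k+1)/L for read length L.
Validation regime: error-free reads at 10–20× over 100 kb random
genomes recover genome size within ±10% and coverage within ±20%
(20-replicate median); the test suite and acceptance script both
measure this. Two caveats are inherent to the estimator and documented
rather than hidden: (i) at high depth with realistic error rates,
recurrent error k-mers pass the m = 2 filter and inflate the
genome-size estimate; (ii) no parity with any external sketching tool
is claimed — the estimator is defined here and validated by simulation.

## Decision classification

`end_reason` tokens map to three classes: `signal_positive` →
`stop_receiving`, `data_service_unblock_mux_change` → `unblocked`,
`signal_negative` and `unblock_mux_change` → `no_decision`; matching is
case-insensitive (both spellings occur in real summaries). Any other
token is counted as *unknown* and excluded from percentage
denominators — the three-class scheme is an approximation of the
selective-sequencing API's true decisions, which the summary file does
not record. Binning uses event start time (a documented choice; end
time is not used), left-closed right-open bins of 15 min by default,
and every summary occurrence is one decision event. The cumulative view
aggregates bins 0..i; its final bin equals the whole-run tally by
construction and by test.

## Synthetic runs

The generator emulates the channel-split depletion design: 512
channels, AS on 1–256; log-normal read lengths (median ≈ 1.5 kb,
σ = 0.35); per-base substitution errors at 2%; per-base qualities
Normal(19, 6) clipped to [2, 35] so that typical reads pass the QC
filter while a 1% planted low-quality fraction (location 6) fails it;
uniform start times over a 4 h run with durations at 400 b/s.
Depletion-target reads on AS channels are unblocked with probability
0.75 and truncated to Normal(400, 40) bases; 2% of reads gain an extra
earlier `signal_negative` summary row (re-evaluation), which is why the
planted unblocked percentage among classified AS events is
100·abundance·0.75/(1 + 0.02) ≈ 58.8% in the canonical scenario
(target at 80% abundance) rather than a bare 60%. The generator exposes
this analytic value and writes the realised planted rate to
`truth.json`. Genomes are i.i.d. uniform random sequences, making
mapping truth unambiguous; an optional homology fraction copies a block
of the target genome into the others to explore misassignment
qualitatively. What the simulator does *not* model — and what passing
tests therefore do not show about real data: nanopore signal-level
error structure (indels dominate real ONT error, only substitutions are
simulated), quality autocorrelation, pore-time reallocation after
unblocking (real AS speeds up off-target coverage; here off-target
yield is unchanged), channel death, and translocation-speed variation.

## Problem sizes

Tests and the acceptance script run at desk scale by design: the
canonical end-to-end scenario uses 2000–6000 reads over a 100 kb
two-taxon community (at 6000 reads the binomial noise on the unblocked
percentage is below one point), and estimator recovery uses 20
replicates of 15× over 100 kb. All randomness flows from a single seed
through `numpy.random.default_rng`; identical seeds give byte-identical
outputs, including the report CSVs.

## Numerical and design choices

* Gzip inputs are detected by magic bytes, not file extension.
* Wrapped (multi-line) FASTQ is rejected: basecaller output is 4-line,
  and the validity rules presume it.
* Duplicate primary mapped alignments for one read are a hard data
  error, not silently resolved.
* `min_ch=0` and `min_ch=1` are equivalent (channels start at 1; bounds
  are inclusive and not clamped).
* Decision filtering in the filter stage matches raw `end_reason`
  tokens, not derived classes — classification lives in one module.
* Charts embed SVG in self-contained HTML with a JS linear/log toggle
  for the coverage chart (two precomputed renderings); the CSV twin of
  each chart is the stable test surface. Violins downsample to 100 000
  points with a fixed seed.
* Exit codes: 0 success, 2 usage, 3 input validation, 4 external-tool
  failure.

## Known limitations

Short-read (paired) mode maps both mates independently and is not
benchmarked; BAM/CRAM and signal-level formats are out of scope; the
optional AS-decision log file some sequencer versions emit is not
parsed — classification always goes through `end_reason`.
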