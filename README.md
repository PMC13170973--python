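# porescope

Analytics for Oxford Nanopore **adaptive sampling (AS)** runs. During AS,
the sequencer decides in real time — per pore, per read — whether to keep
sequencing a strand or to eject ("unblock") it by reversing the pore
voltage, enriching or depleting chosen taxa without extra lab work.
Assessing whether a depletion actually worked is surprisingly fiddly:
the evidence is spread across the basecalled FASTQ, the sequencing-summary
table, and read-to-reference alignments. porescope is a three-stage
command-line pipeline for exactly that post-run evaluation, aimed at
microbiologists and sequencing-core analysts comparing a test (AS)
condition against a control on the same flow cell.

## What it computes

**`filter_ONT`** subsets reads by criteria evaluated against the
sequencing-summary table (channel range, length, Q score, start time,
duration, raw `end_reason` tokens). The canonical use is splitting one
flow cell into conditions by channel range (AS on channels 1–256,
control on 257–512).

**`analyze`** validates the FASTQ (4-line records, `@`/`+` markers,
|sequence| = |quality|; invalid files abort), applies a quality filter
with exact-duplicate removal, maps reads with minimap2
(`-ax map-ont -k 15`, or `-ax sr` for short reads; a precomputed SAM can
be supplied instead), and writes two tables:

* the **sample manifest** — one row per read per pore event
  (length, Q score, channel, times, end reason, QC verdict, mapping);
* the **sample manifest summary** — one row per reference sequence
  ("taxon") with, for reference length *L* and total primary-mapped
  bases *B*: mean coverage depth *B/L*, covered bases and percent
  breadth at depth ≥ *X* (default 1×), and mean read length; plus
  reference-free community estimates from a bottom-*s* MinHash sketch of
  canonical 27-mers (*s* = 1000): genome size via the k-minimum-values
  estimator (s−1)·2⁶⁴/h₍ₛ₎ and coverage via mean retained-k-mer
  multiplicity.

**`plot`** compares two analyze outputs: a taxon × parameter summary
table, read-length and Q-score violins, per-taxon bar charts (mean read
length, mean coverage with a linear/log toggle, percent breadth), and —
with `--AS` — time-binned **decision charts** classifying each
`end_reason` into `stop_receiving` (accept) / `unblocked` (reject) /
`no_decision`, in independent and cumulative 15-minute bins. Every chart
is an HTML file with a CSV twin holding the plotted values.

**`simulate`** generates a complete deterministic mock run (reference
FASTA, reads, sequencing summary, truth SAM) for a channel-split
depletion experiment, so the whole pipeline is testable offline.

## Worked example

A simulated two-taxon community (taxon_a 60 kb at 80% abundance,
taxon_b 40 kb at 20%) with AS depletion of taxon_a on channels 1–256:

```sh
porescope simulate --output_dir demo --seed 7 --read_count 2000
porescope filter_ONT --seq_summary demo/sequencing_summary.txt \
    --input_fastq demo/reads.fastq --output demo/test --min_ch 1 --max_ch 256
porescope filter_ONT --seq_summary demo/sequencing_summary.txt \
    --input_fastq demo/reads.fastq --output demo/control --min_ch 257 --max_ch 512
porescope analyze --input_fastq demo/test.fastq --reference demo/reference.fasta \
    --seq_summary demo/sequencing_summary.txt --output demo/test_out --sample_id test
porescope analyze --input_fastq demo/control.fastq --reference demo/reference.fasta \
    --seq_summary demo/sequencing_summary.txt --output demo/control_out --sample_id control
porescope plot --test_dir demo/test_out --control_dir demo/control_out \
    --output_dir demo/report --AS
```

`demo/report/summary_table.csv` begins:

```
taxon_id,parameter,test_value,control_value
taxon_a,taxon_%_covered_bases_1X,100.0,100.0
taxon_a,taxon_covered_bases_1X,59983.0,59994.0
taxon_a,taxon_mean_coverage,9.1,20.86
taxon_a,taxon_mean_read_length,693.0,1546.0
taxon_a,total_taxon_ref_mapped_bases,545958.0,1251776.0
```

The depletion signature is unmistakable: the target's mean coverage
drops from 20.86× (control) to 9.1× (test) and its mean read length from
1546 b to 693 b — unblocked strands are cut short at roughly the ~400 b
decision window. The final cumulative decision bin for the test
condition reads 58.1% `unblocked` / 39.2% `stop_receiving` /
2.7% `no_decision` over 1026 events, while the control shows 0%
`unblocked` throughout, exactly as a run with AS on half the channels
should.

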