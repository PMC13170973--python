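"""Depth profiles, taxon summaries, manifests: oracles and conservation."""

from __future__ import annotations

import numpy as np
import pytest

from porescope.alignment import DataError, aligned_ref_span
from porescope.coverage_stats import (
    build_manifest,
    build_manifest_summary,
    cigar_ref_blocks,
    compute_taxon_stats,
    depth_profile,
    round_sig,
    taxon_summary,
    unmapped_stats,
)
from porescope.formats import AlignmentRecord, FastqRead, ReferenceSeq, SummaryRow
from porescope.read_qc import QcStats


def rec(read_id, pos, cigar, taxon="t", flag=0, read_length=None):
    return AlignmentRecord(
        read_id, taxon, flag, pos, cigar, 60,
        read_length if read_length is not None else aligned_ref_span(cigar),
    )


def brute_force_depth(alignments, length):
    depth = np.zeros(length, dtype=int)
    for a in alignments:
        for start, end in cigar_ref_blocks(a.pos, a.cigar):
            for i in range(start, end):
                depth[i] += 1
    return depth


class TestDepthProfile:
    def test_single_alignment(self):
        depth = depth_profile([rec("r", 1, "10M")], 20)
        assert depth[:10].tolist() == [1] * 10
        assert depth[10:].tolist() == [0] * 10

    def test_two_overlapping_alignments(self):
        depth = depth_profile([rec("a", 1, "10M"), rec("b", 6, "10M")], 20)
        assert depth.max() == 2
        assert (depth == brute_force_depth([rec("a", 1, "10M"), rec("b", 6, "10M")], 20)).all()

    def test_deletions_spanned_but_not_covered(self):
        depth = depth_profile([rec("r", 1, "5M3D5M")], 13)
        assert depth.tolist() == [1] * 5 + [0] * 3 + [1] * 5

    def test_random_alignments_equal_brute_force(self):
        rng = np.random.default_rng(7)
        length = 500
        alignments = []
        for i in range(200):
            parts = []
            for _ in range(int(rng.integers(1, 4))):
                parts.append((int(rng.integers(1, 30)), str(rng.choice(list("MDI")))))
            cigar = "".join(f"{n}{o}" for n, o in parts)
            footprint = sum(n for n, o in parts if o in "MD")
            if footprint == 0 or footprint >= length:
                continue
            pos = int(rng.integers(1, length - footprint + 1))
            alignments.append(rec(f"r{i}", pos, cigar))
        depth = depth_profile(alignments, length)
        assert (depth == brute_force_depth(alignments, length)).all()
        # total depth mass == sum of aligned reference spans
        assert depth.sum() == sum(aligned_ref_span(a.cigar) for a in alignments)

    def test_overrun_names_the_read(self):
        with pytest.raises(DataError, match="r_bad"):
            depth_profile([rec("r_bad", 95, "10M")], 100)


class TestTaxonSummary:
    def test_table_row_arithmetic(self):
        depth = np.array([3, 3, 0, 1, 1, 1, 0, 0, 0, 0])
        stats = taxon_summary("t", 10, depth, [100, 200], threshold=1)
        assert stats.total_taxon_ref_mapped_bases == 9
        assert stats.taxon_mean_coverage == pytest.approx(0.9)
        assert stats.taxon_covered_bases == 5
        assert stats.taxon_pct_covered_bases == pytest.approx(50.0)
        assert stats.taxon_mean_read_length == pytest.approx(150.0)

    def test_zero_alignments_zero_stats(self):
        stats = taxon_summary("t", 10, np.zeros(10, dtype=int), [])
        assert stats.taxon_mean_coverage == 0
        assert stats.taxon_pct_covered_bases == 0
        assert stats.taxon_mean_read_length == 0

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(0)
        depth = rng.integers(0, 6, size=300)
        covered = [
            taxon_summary("t", 300, depth, [], threshold=x).taxon_covered_bases
            for x in range(1, 6)
        ]
        assert covered == sorted(covered, reverse=True)

    def test_round_sig_matches_reporting_convention(self):
        assert round_sig(60.51) == 61
        assert round_sig(0.9383) == 0.94
        assert round_sig(4.438) == 4.4
        assert round_sig(0.0019329) == 0.0019
        assert round_sig(0.0) == 0.0


class TestComputeTaxonStats:
    def test_conservation_across_taxa(self):
        rng = np.random.default_rng(3)
        refs = [ReferenceSeq("a", "A" * 400), ReferenceSeq("b", "C" * 300)]
        alignments = []
        for i in range(150):
            taxon = str(rng.choice(["a", "b"]))
            limit = 400 if taxon == "a" else 300
            n = int(rng.integers(10, 60))
            pos = int(rng.integers(1, limit - n + 1))
            alignments.append(rec(f"r{i}", pos, f"{n}M", taxon=taxon))
        stats = compute_taxon_stats(refs, alignments)
        total = sum(t.total_taxon_ref_mapped_bases for t in stats)
        assert total == sum(aligned_ref_span(a.cigar) for a in alignments)
        # mean coverage * length recovers the mapped-base total per taxon
        for t in stats:
            if t.taxon_id != "*":
                assert t.taxon_mean_coverage * t.taxon_length == pytest.approx(
                    t.total_taxon_ref_mapped_bases
                )

    def test_unmapped_row_is_all_zero_and_last(self):
        refs = [ReferenceSeq("a", "A" * 10)]
        stats = compute_taxon_stats(refs, [])
        assert stats[-1].taxon_id == "*"
        assert stats[-1].total_taxon_ref_mapped_bases == 0


class TestBuildManifest:
    READS = [
        FastqRead("m1", "ACGTACGT", "IIIIIIII"),
        FastqRead("m2", "ACGTACGT", "IIIIIIII"),
        FastqRead("m3", "ACGT", "IIII"),
    ]
    STATUS = {"m1": True, "m2": False, "m3": True}
    ALN = [rec("m1", 1, "8M", taxon="Pseudomonas_aeruginosa", read_length=8)]

    def _summary(self):
        return [
            SummaryRow("m1", 255, 86.13, 5.39, 8, 14.94, "signal_positive"),
            SummaryRow("m2", 211, 108.37, 3.18, 8, 9.13, "signal_positive"),
            SummaryRow("m3", 19, 185.07, 5.77, 4, 15.16, "signal_negative"),
            SummaryRow("m3", 19, 100.0, 0.5, 4, 15.16, "signal_positive"),
        ]

    def test_joined_fields_per_read(self):
        rows = build_manifest(self.READS, self.STATUS, self.ALN, self._summary(), "Test")
        by_id = {}
        for r in rows:
            by_id.setdefault(r.read_id, []).append(r)
        m1 = by_id["m1"][0]
        assert m1.fastp_status and m1.is_mapped
        assert m1.contig_id == "Pseudomonas_aeruginosa"
        assert m1.end_time == pytest.approx(86.13 + 5.39)
        m2 = by_id["m2"][0]
        assert not m2.fastp_status and not m2.is_mapped and m2.contig_id == ""

    def test_multi_event_read_gets_row_per_event_not_uniq(self):
        rows = build_manifest(self.READS, self.STATUS, self.ALN, self._summary())
        m3 = [r for r in rows if r.read_id == "m3"]
        assert len(m3) == 2
        assert all(not r.is_uniq for r in m3)

    def test_without_summary_uses_fastq_qscore(self):
        rows = build_manifest(self.READS, self.STATUS, self.ALN, None)
        assert len(rows) == len(self.READS)
        assert all(r.channel is None and r.decision == "" for r in rows)
        assert rows[0].read_qscore == pytest.approx(40.0)  # all 'I' bases

    def test_every_input_read_appears(self):
        rows = build_manifest(self.READS, self.STATUS, self.ALN, self._summary())
        assert {r.read_id for r in rows} == {r.read_id for r in self.READS}


class TestManifestSummary:
    def test_structure_and_footer_fields(self):
        refs = [ReferenceSeq(chr(97 + i), "A" * 100) for i in range(3)]
        stats = compute_taxon_stats(refs, [rec("r", 1, "50M", taxon="b")])
        qc = QcStats(total_bases=1000, total_fastp_bases=900, reads_in=10, reads_out=9)
        frame = build_manifest_summary(stats, qc, est_genome_size=5e5, est_coverage=12.0)
        assert list(frame["taxon_id"]) == ["a", "b", "c", "*"]
        assert frame["taxon_%_covered_bases_1X"].iloc[1] == pytest.approx(50.0)
        assert (frame["est_genome_size"] == 5e5).all()
        assert (frame["total_bases"] == 1000).all()

    def test_custom_threshold_renames_columns(self):
        stats = [unmapped_stats(threshold=5)]
        frame = build_manifest_summary(stats, QcStats())
        assert "taxon_%_covered_bases_5X" in frame.columns
        assert "taxon_covered_bases_5X" in frame.columns

    def test_empty_reference_set_gives_only_unmapped_row(self):
        frame = build_manifest_summary([unmapped_stats()], QcStats())
        assert list(frame["taxon_id"]) == ["*"]
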