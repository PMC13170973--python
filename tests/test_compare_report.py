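"""Report stage: summary table construction, chart inventory, determinism."""

from __future__ import annotations

import hashlib
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

from porescope.compare_report import (
    ComparisonError,
    build_summary_table,
    comparison_parameters,
    render_reports,
    render_summary_table,
)
from porescope.coverage_stats import (
    build_manifest_summary,
    compute_taxon_stats,
)
from porescope.filter_ont import FilterCriteria, match_reads, subset_fastq
from porescope.formats import (
    parse_fastq,
    parse_sequencing_summary,
    write_fastq,
)
from porescope.pipeline import AnalyzeConfig, run_analyze


@pytest.fixture(scope="module")
def analyzed_pair(tmp_path_factory, small_run):
    """Test/control analyze outputs for the shared small run (truth SAM)."""
    base = tmp_path_factory.mktemp("pair")
    summary = parse_sequencing_summary(small_run["summary"])
    reads = list(parse_fastq(small_run["reads"]))
    dirs = {}
    for name, lo, hi in (("test", 1, 256), ("control", 257, 512)):
        keep = match_reads(summary, FilterCriteria(min_ch=lo, max_ch=hi))
        fq = base / f"{name}.fastq"
        write_fastq(subset_fastq(reads, keep), fq)
        dirs[name] = run_analyze(
            AnalyzeConfig(
                input_fastq=fq,
                reference=small_run["reference"],
                output_dir=base / f"{name}_out",
                seq_summary=small_run["summary"],
                sam=small_run["sam"],
                sample_id=name,
            )
        )
    return dirs


def summary_frame(taxon_values: dict, threshold: int = 1) -> pd.DataFrame:
    from porescope.coverage_stats import TaxonStats, unmapped_stats
    from porescope.read_qc import QcStats

    stats = [
        TaxonStats(
            taxon_id=t,
            taxon_length=v["len"],
            taxon_mean_coverage=v["mapped"] / v["len"],
            taxon_covered_bases=v["cov"],
            taxon_pct_covered_bases=100 * v["cov"] / v["len"],
            total_taxon_ref_mapped_bases=v["mapped"],
            taxon_mean_read_length=v["mrl"],
            threshold=threshold,
        )
        for t, v in taxon_values.items()
    ] + [unmapped_stats(threshold)]
    return build_manifest_summary(stats, QcStats())


class TestSummaryTable:
    VALUES = {
        "Listeria_monocytogenes": dict(len=1000, mapped=33130, cov=1000, mrl=514.0),
        "Bacillus_subtilis": dict(len=2000, mapped=2000, cov=1200, mrl=1830.0),
    }

    def test_row_inventory_and_order(self):
        frame = summary_frame(self.VALUES)
        table = build_summary_table(frame, frame)
        assert len(table) == 3 * 5  # two taxa + unmapped row, five parameters
        assert list(table["taxon_id"].unique()) == [
            "Bacillus_subtilis",
            "Listeria_monocytogenes",
            "*",
        ]
        per_taxon = table[table["taxon_id"] == "Bacillus_subtilis"]["parameter"]
        assert list(per_taxon) == comparison_parameters(1)

    def test_identical_inputs_give_equal_columns(self):
        frame = summary_frame(self.VALUES)
        table = build_summary_table(frame, frame)
        assert (table["test_value"] == table["control_value"]).all()

    def test_values_match_manifest_summaries(self):
        test = summary_frame(self.VALUES)
        control = summary_frame(
            {
                "Listeria_monocytogenes": dict(len=1000, mapped=89470, cov=1000, mrl=1842.0),
                "Bacillus_subtilis": dict(len=2000, mapped=1460, cov=1009, mrl=1779.0),
            }
        )
        table = build_summary_table(test, control).set_index(["taxon_id", "parameter"])
        row = table.loc[("Listeria_monocytogenes", "taxon_mean_coverage")]
        assert row["test_value"] == pytest.approx(33.13)
        assert row["control_value"] == pytest.approx(89.47)

    def test_rounding_applied_at_render_only(self):
        test = summary_frame(self.VALUES)
        table = build_summary_table(test, test)
        rendered = render_summary_table(table)
        cov = rendered[rendered["parameter"] == "taxon_mean_coverage"]
        assert (cov["test_value"] == cov["test_value"].round(2)).all()
        other = rendered[rendered["parameter"] != "taxon_mean_coverage"]
        assert (other["test_value"] % 1 == 0).all()
        # source table untouched
        assert not (table["test_value"] % 1 == 0).all()

    def test_mismatched_taxon_sets_listed(self):
        a = summary_frame(self.VALUES)
        b = summary_frame({"Listeria_monocytogenes": self.VALUES["Listeria_monocytogenes"]})
        with pytest.raises(ComparisonError, match="Bacillus_subtilis"):
            build_summary_table(a, b)


class TestRenderReports:
    def test_as_mode_output_inventory(self, analyzed_pair, tmp_path):
        artifacts = render_reports(
            analyzed_pair["test"], analyzed_pair["control"], tmp_path / "report",
            as_mode=True,
        )
        html = sorted(p.name for p in (tmp_path / "report").glob("*.html"))
        csv = sorted(p.name for p in (tmp_path / "report").glob("*.csv"))
        assert len(html) == 7  # 5 default charts + 2 decision charts
        assert "summary_table.csv" in csv
        assert len(csv) >= 8  # one backing CSV per chart + summary table

    def test_default_mode_has_no_decision_charts(self, analyzed_pair, tmp_path):
        render_reports(
            analyzed_pair["test"], analyzed_pair["control"], tmp_path / "plain",
            as_mode=False,
        )
        html = {p.name for p in (tmp_path / "plain").glob("*.html")}
        assert len(html) == 5
        assert not any("decision" in name for name in html)

    def test_depleted_taxon_shows_lower_test_coverage_only(self, analyzed_pair, tmp_path):
        render_reports(
            analyzed_pair["test"], analyzed_pair["control"], tmp_path / "dep"
        )
        bars = pd.read_csv(tmp_path / "dep" / "mean_coverage_bar.csv").set_index("taxon_id")
        a_drop = (
            bars.loc["taxon_a", "control_value"] - bars.loc["taxon_a", "test_value"]
        ) / bars.loc["taxon_a", "control_value"]
        b_drop = (
            bars.loc["taxon_b", "control_value"] - bars.loc["taxon_b", "test_value"]
        ) / bars.loc["taxon_b", "control_value"]
        assert a_drop > 0.3          # depletion target clearly suppressed
        assert abs(b_drop) < a_drop  # off-target taxon essentially unaffected

    def test_chart_csvs_bit_identical_across_runs(self, analyzed_pair, tmp_path):
        digests = []
        for sub in ("a", "b"):
            out = tmp_path / sub
            render_reports(
                analyzed_pair["test"], analyzed_pair["control"], out, as_mode=True
            )
            digests.append(
                {
                    p.name: hashlib.sha256(p.read_bytes()).hexdigest()
                    for p in sorted(out.glob("*.csv"))
                }
            )
        assert digests[0] == digests[1]

    def test_control_decisions_all_stop_receiving(self, analyzed_pair, tmp_path):
        render_reports(
            analyzed_pair["test"], analyzed_pair["control"], tmp_path / "as",
            as_mode=True,
        )
        frame = pd.read_csv(tmp_path / "as" / "decision_independent.csv")
        ctrl = frame[frame["condition"] == "control"]
        assert (ctrl["pct_unblocked"] == 0).all()
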