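"""Test-vs-control reporting: summary table and comparison charts.

Consumes the two manifest files the analyze stage writes for each
condition and produces (a) a long-format summary table with one row per
taxon x parameter comparing the test and control values, and (b) the
report charts: read-length and Q-score violins, per-taxon bars for mean
read length, mean coverage (with a linear/log y-axis toggle) and percent
bases covered at the active depth threshold, plus — in AS mode — the
independent and cumulative time-binned decision charts.

Charts are self-contained HTML files with an embedded SVG rendering;
every chart also writes a plain CSV of exactly the values plotted, which
is the stable, browser-free test surface. Rounding (mean coverage to two
decimals, other parameters to the nearest integer) is applied at render
time only; the underlying tables keep full precision.
"""

from __future__ import annotations

import io
import re
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .coverage_stats import pct_covered_column, read_manifest, read_manifest_summary
from .decision_analysis import (
    DECISION_CLASSES,
    DecisionBin,
    bin_decisions,
    cumulate_bins,
)
from .formats import UNMAPPED, PathLike

#: maximum points drawn per violin; larger inputs are downsampled (seeded)
VIOLIN_MAX_POINTS = 100_000

_DECISION_COLOURS = {
    "unblocked": "#3b6fb6",
    "no_decision": "#8e6bb0",
    "stop_receiving": "#4caf6e",
}


class ComparisonError(ValueError):
    """The two summaries do not describe the same reference set."""


# ---------------------------------------------------------------------------
# summary table
# ---------------------------------------------------------------------------

def _threshold_of(summary: pd.DataFrame) -> int:
    for col in summary.columns:
        m = re.fullmatch(r"taxon_%_covered_bases_(\d+)X", col)
        if m:
            return int(m.group(1))
    raise ComparisonError("summary lacks a taxon_%_covered_bases_<X>X column")


def comparison_parameters(threshold: int) -> List[str]:
    """The five compared parameters, in their rendered (alphabetical) order."""
    return sorted(
        [
            f"taxon_%_covered_bases_{threshold}X",
            f"taxon_covered_bases_{threshold}X",
            "taxon_mean_coverage",
            "taxon_mean_read_length",
            "total_taxon_ref_mapped_bases",
        ]
    )


def build_summary_table(
    test: pd.DataFrame, control: pd.DataFrame
) -> pd.DataFrame:
    """Long-format comparison: taxon_id, parameter, test_value, control_value.

    Five rows per taxon (including the "*" unmapped row, kept last),
    ordered by taxon then parameter. Both inputs must cover the same
    taxon set and the same depth threshold.
    """
    t_x, c_x = _threshold_of(test), _threshold_of(control)
    if t_x != c_x:
        raise ComparisonError(
            f"depth thresholds differ: test {t_x}X vs control {c_x}X"
        )
    t_taxa = set(test["taxon_id"])
    c_taxa = set(control["taxon_id"])
    if t_taxa != c_taxa:
        raise ComparisonError(
            "taxon sets differ; only in test: "
            f"{sorted(t_taxa - c_taxa)}; only in control: {sorted(c_taxa - t_taxa)}"
        )
    params = comparison_parameters(t_x)
    t_idx = test.set_index("taxon_id")
    c_idx = control.set_index("taxon_id")
    taxa = sorted(t_taxa, key=lambda t: (t == UNMAPPED, t))
    rows = []
    for taxon in taxa:
        for p in params:
            rows.append(
                {
                    "taxon_id": taxon,
                    "parameter": p,
                    "test_value": float(t_idx.loc[taxon, p]),
                    "control_value": float(c_idx.loc[taxon, p]),
                }
            )
    return pd.DataFrame(rows)


def render_summary_table(table: pd.DataFrame) -> pd.DataFrame:
    """Apply reporting rounding: mean coverage 2 dp, everything else integer."""
    out = table.copy()
    is_cov = out["parameter"] == "taxon_mean_coverage"
    for col in ("test_value", "control_value"):
        out.loc[is_cov, col] = out.loc[is_cov, col].round(2)
        out.loc[~is_cov, col] = out.loc[~is_cov, col].round(0)
    return out


# ---------------------------------------------------------------------------
# HTML scaffolding
# ---------------------------------------------------------------------------

def _fig_to_svg(fig) -> str:
    buf = io.StringIO()
    fig.savefig(buf, format="svg", bbox_inches="tight")
    plt.close(fig)
    return buf.getvalue()


def _write_html(path: Path, title: str, body: str) -> None:
    path.write_text(
        "<!DOCTYPE html><html><head><meta charset='utf-8'>"
        f"<title>{title}</title></head><body><h1>{title}</h1>{body}</body></html>"
    )


def _toggle_html(linear_svg: str, log_svg: str) -> str:
    """Two precomputed axis renderings with a JS show/hide toggle."""
    return (
        "<button onclick=\""
        "var a=document.getElementById('linear'),b=document.getElementById('log');"
        "var t=a.style.display;a.style.display=b.style.display;b.style.display=t;"
        "\">toggle linear/log</button>"
        f"<div id='linear'>{linear_svg}</div>"
        f"<div id='log' style='display:none'>{log_svg}</div>"
    )


# ---------------------------------------------------------------------------
# individual charts
# ---------------------------------------------------------------------------

def _grouped_bar(
    taxa: Sequence[str],
    test_vals: Sequence[float],
    control_vals: Sequence[float],
    ylabel: str,
    log: bool = False,
):
    fig, ax = plt.subplots(figsize=(max(6, len(taxa) * 1.1), 4))
    x = np.arange(len(taxa))
    ax.bar(x - 0.2, test_vals, width=0.4, label="test", color="#d95f02")
    ax.bar(x + 0.2, control_vals, width=0.4, label="control", color="#1b9e77")
    ax.set_xticks(x)
    ax.set_xticklabels(taxa, rotation=45, ha="right")
    ax.set_ylabel(ylabel)
    if log:
        ax.set_yscale("log")
    ax.legend()
    fig.tight_layout()
    return fig


def _bar_chart_files(
    outdir: Path,
    stem: str,
    title: str,
    taxa: Sequence[str],
    test_vals: Sequence[float],
    control_vals: Sequence[float],
    log_toggle: bool = False,
) -> Tuple[Path, Path]:
    csv_path = outdir / f"{stem}.csv"
    pd.DataFrame(
        {"taxon_id": taxa, "test_value": test_vals, "control_value": control_vals}
    ).to_csv(csv_path, index=False)
    svg = _fig_to_svg(_grouped_bar(taxa, test_vals, control_vals, title))
    if log_toggle:
        log_svg = _fig_to_svg(
            _grouped_bar(taxa, test_vals, control_vals, title, log=True)
        )
        body = _toggle_html(svg, log_svg)
    else:
        body = svg
    html_path = outdir / f"{stem}.html"
    _write_html(html_path, title, body)
    return csv_path, html_path


def _violin_files(
    outdir: Path,
    stem: str,
    title: str,
    test_vals: np.ndarray,
    control_vals: np.ndarray,
    seed: int = 0,
) -> Tuple[Path, Path]:
    rng = np.random.default_rng(seed)

    def cap(v: np.ndarray) -> np.ndarray:
        if len(v) > VIOLIN_MAX_POINTS:
            return rng.choice(v, VIOLIN_MAX_POINTS, replace=False)
        return v

    test_vals, control_vals = cap(np.asarray(test_vals)), cap(
        np.asarray(control_vals)
    )
    csv_path = outdir / f"{stem}.csv"
    pd.concat(
        [
            pd.DataFrame({"condition": "test", "value": test_vals}),
            pd.DataFrame({"condition": "control", "value": control_vals}),
        ]
    ).to_csv(csv_path, index=False)
    fig, ax = plt.subplots(figsize=(6, 4))
    data = [v for v in (test_vals, control_vals) if len(v)]
    labels = [
        n for n, v in (("test", test_vals), ("control", control_vals)) if len(v)
    ]
    if data:
        ax.violinplot(data, showmedians=True)
        ax.set_xticks(np.arange(1, len(labels) + 1))
        ax.set_xticklabels(labels)
    ax.set_ylabel(title)
    fig.tight_layout()
    html_path = outdir / f"{stem}.html"
    _write_html(html_path, title, _fig_to_svg(fig))
    return csv_path, html_path


def decision_bin_frame(bins: Sequence[DecisionBin]) -> pd.DataFrame:
    """CSV-ready view of a decision-bin sequence."""
    return pd.DataFrame(
        [
            {
                "bin_start": b.bin_start,
                "bin_end": b.bin_end,
                "read_count": b.read_count,
                **{f"pct_{c}": b.pct[c] for c in DECISION_CLASSES},
                "unknown": b.unknown,
            }
            for b in bins
        ]
    )


def _decision_panel(ax, frame: pd.DataFrame, label: str) -> None:
    x = np.arange(len(frame))
    bottom = np.zeros(len(frame))
    for cls in ("unblocked", "no_decision", "stop_receiving"):
        vals = frame[f"pct_{cls}"].to_numpy()
        ax.bar(x, vals, bottom=bottom, label=cls, color=_DECISION_COLOURS[cls])
        bottom += vals
    ax.set_title(label)
    ax.set_ylabel("% of sequencing decisions")
    ax.set_xlabel("time bin start (min)")
    ax.set_xticks(x)
    ax.set_xticklabels(
        [f"{s / 60:.0f}" for s in frame["bin_start"]], rotation=90, fontsize=7
    )
    ax2 = ax.twinx()
    ax2.plot(x, frame["read_count"], color="black", marker="o", markersize=3)
    ax2.set_ylabel("read count")
    ax.legend(loc="lower left", fontsize=7)


def _decision_chart_files(
    outdir: Path,
    stem: str,
    title: str,
    test_bins: Sequence[DecisionBin],
    control_bins: Sequence[DecisionBin],
) -> Tuple[Path, Path]:
    """One chart with test and control panels, as in the standard AS report."""
    test_frame = decision_bin_frame(test_bins)
    control_frame = decision_bin_frame(control_bins)
    test_frame.insert(0, "condition", "test")
    control_frame.insert(0, "condition", "control")
    frame = pd.concat([test_frame, control_frame], ignore_index=True)
    csv_path = outdir / f"{stem}.csv"
    frame.to_csv(csv_path, index=False)
    width = max(6, max(len(test_bins), len(control_bins)) * 0.5)
    fig, axes = plt.subplots(2, 1, figsize=(width, 8))
    _decision_panel(axes[0], test_frame, "test")
    _decision_panel(axes[1], control_frame, "control")
    fig.tight_layout()
    html_path = outdir / f"{stem}.html"
    _write_html(html_path, title, _fig_to_svg(fig))
    return csv_path, html_path


# ---------------------------------------------------------------------------
# top-level report
# ---------------------------------------------------------------------------

def render_reports(
    test_dir: PathLike,
    control_dir: PathLike,
    output_dir: PathLike,
    as_mode: bool = False,
    bin_minutes: float = 15.0,
    seed: int = 0,
) -> Dict[str, Path]:
    """Produce the full report from two analyze output directories.

    Writes five charts (seven with ``as_mode``) as HTML+CSV pairs plus
    ``summary_table.csv``; returns the map of artifact names to paths.
    Raises :class:`ComparisonError` when AS mode is requested but the
    manifests carry no decision data.
    """
    test_dir, control_dir = Path(test_dir), Path(control_dir)
    outdir = Path(output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    test_summary = read_manifest_summary(test_dir / "sample_manifest_summary.txt")
    control_summary = read_manifest_summary(
        control_dir / "sample_manifest_summary.txt"
    )
    test_manifest = read_manifest(test_dir / "sample_manifest.txt")
    control_manifest = read_manifest(control_dir / "sample_manifest.txt")

    threshold = _threshold_of(test_summary)
    table = build_summary_table(test_summary, control_summary)
    artifacts: Dict[str, Path] = {}
    summary_csv = outdir / "summary_table.csv"
    render_summary_table(table).to_csv(summary_csv, index=False)
    artifacts["summary_table"] = summary_csv

    taxa_rows = test_summary[test_summary["taxon_id"] != UNMAPPED]
    c_idx = control_summary.set_index("taxon_id")
    taxa = list(taxa_rows["taxon_id"])

    def pair(col: str) -> Tuple[List[float], List[float]]:
        t = [float(v) for v in taxa_rows[col]]
        c = [float(c_idx.loc[x, col]) for x in taxa]
        return t, c

    for stem, col, title, log_toggle in (
        ("mean_read_length_bar", "taxon_mean_read_length", "mean read length (b)", False),
        ("mean_coverage_bar", "taxon_mean_coverage", "mean coverage depth (fold)", True),
        (
            "pct_covered_bar",
            pct_covered_column(threshold),
            f"% bases covered at {threshold}X",
            False,
        ),
    ):
        t, c = pair(col)
        csv_path, html_path = _bar_chart_files(
            outdir, stem, title, taxa, t, c, log_toggle=log_toggle
        )
        artifacts[stem] = html_path
        artifacts[f"{stem}_csv"] = csv_path

    for stem, col, title in (
        ("read_length_violin", "read_len", "read length (b)"),
        ("qscore_violin", "read_qscore", "read Q score"),
    ):
        csv_path, html_path = _violin_files(
            outdir,
            stem,
            title,
            test_manifest[col].dropna().to_numpy(dtype=float),
            control_manifest[col].dropna().to_numpy(dtype=float),
            seed=seed,
        )
        artifacts[stem] = html_path
        artifacts[f"{stem}_csv"] = csv_path

    if as_mode:
        bin_width = bin_minutes * 60.0
        binned: Dict[str, Tuple[List[DecisionBin], List[DecisionBin]]] = {}
        for label, manifest in (("test", test_manifest), ("control", control_manifest)):
            events = [
                (float(t), str(d))
                for t, d in zip(manifest["start_time"], manifest["decision"])
                if pd.notna(t) and pd.notna(d) and str(d).strip()
            ]
            if not events:
                raise ComparisonError(
                    f"--AS requested but the {label} manifest has no decision data"
                )
            independent = bin_decisions(events, bin_width)
            binned[label] = (independent, cumulate_bins(independent))
        for i, kind in enumerate(("independent", "cumulative")):
            stem = f"decision_{kind}"
            csv_path, html_path = _decision_chart_files(
                outdir,
                stem,
                f"{kind} sequencing decisions",
                binned["test"][i],
                binned["control"][i],
            )
            artifacts[stem] = html_path
            artifacts[f"{stem}_csv"] = csv_path
    return artifacts
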