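"""Shared fixtures: small deterministic mock runs and format helpers."""

from __future__ import annotations

from pathlib import Path

import pytest

from porescope.synthetic import depletion_scenario, generate_run


@pytest.fixture(scope="session")
def small_run(tmp_path_factory) -> dict:
    """A small depletion run (600 reads) shared by read-only tests."""
    outdir = tmp_path_factory.mktemp("small_run")
    scenario = depletion_scenario(seed=11, read_count=600)
    paths = generate_run(scenario, outdir)
    paths["scenario"] = scenario
    return paths


@pytest.fixture(scope="session")
def clean_run(tmp_path_factory) -> dict:
    """An error-free run (exact substrings) for truth-based mapping checks."""
    outdir = tmp_path_factory.mktemp("clean_run")
    scenario = depletion_scenario(
        seed=7,
        read_count=300,
        error_rate=0.0,
        low_quality_fraction=0.0,
        reevaluation_fraction=0.0,
    )
    paths = generate_run(scenario, outdir)
    paths["scenario"] = scenario
    return paths


def write_lines(path: Path, *lines: str) -> Path:
    path.write_text("".join(line + "\n" for line in lines))
    return path


@pytest.fixture
def fastq_file(tmp_path):
    """Factory writing a FASTQ from (id, seq, qual) triples."""

    def _write(records, name="reads.fastq"):
        path = tmp_path / name
        with open(path, "w") as fh:
            for read_id, seq, qual in records:
                fh.write(f"@{read_id}\n{seq}\n+\n{qual}\n")
        return path

    return _write


@pytest.fixture
def summary_file(tmp_path):
    """Factory writing a sequencing-summary TSV from row dicts."""

    columns = (
        "read_id",
        "channel",
        "start_time",
        "duration",
        "sequence_length_template",
        "mean_qscore_template",
        "end_reason",
    )

    def _write(rows, name="sequencing_summary.txt", drop=()):
        cols = [c for c in columns if c not in drop]
        path = tmp_path / name
        with open(path, "w") as fh:
            fh.write("\t".join(cols) + "\n")
            for row in rows:
                fh.write("\t".join(str(row[c]) for c in cols) + "\n")
        return path

    return _write
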