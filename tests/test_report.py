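"""Table rendering, run manifest, and CLI integration."""

import json
from pathlib import Path

import pytest
from click.testing import CliRunner

from genoconcord import SimulationConfig, simulate_scenario, write_scenario
from genoconcord.cli import main
from genoconcord.engine import FamilySummary, ProcessSummary
from genoconcord.errors import ValidationError
from genoconcord.report import (
    RunManifest,
    format_percent,
    format_ratio,
    parse_table,
    render_family_table,
    render_process_table,
    round_half_up,
)


def test_half_up_rounding_differs_from_binary_float_rounding():
    # 5287/20 = 264.35 exactly in decimal; binary round() would give 264.3
    assert str(round_half_up(5287, 20, 1)) == "264.4"
    assert format_ratio(14678, 32) == "458.7"
    assert format_ratio(0, 0) == ""


def test_family_table_rows_blanks_and_totals():
    rows = [
        FamilySummary("T2DG23", n_seq=0, d_seq=0, n_nonseq=32, d_nonseq=14678),
        FamilySummary("T2DG17", n_seq=20, d_seq=5287, n_nonseq=22, d_nonseq=5639),
    ]
    text = render_family_table(rows, sort_key="all")
    parsed = parse_table(text)
    first = parsed[0]
    assert first["Fam_ID"] == "T2DG23"
    assert first["N_seq"] == "" and first["D/N_seq"] == ""  # empty stratum
    assert first["D/N_all"] == "458.7"
    second = parsed[1]
    assert second["D/N_seq"] == "264.4" and second["D/N_nonseq"] == "256.3"
    total = parsed[-1]
    assert total["Fam_ID"] == "TOTAL"
    assert total["N_all"] == "74" and total["D_all"] == "25604"


def test_family_table_empty_input():
    text = render_family_table([])
    parsed = parse_table(text)
    assert len(parsed) == 1 and parsed[0]["Fam_ID"] == "TOTAL"
    assert parsed[0]["N_all"] == "0" and parsed[0]["D_all"] == "0"


def test_process_table_formatting_and_pooled_additivity():
    rows = [
        ProcessSummary("Imputation", 463, 205962, 51816),
        ProcessSummary("Sequencing", 463, 107780325, 0),
        ProcessSummary("Inference-families-with-sequence", 349, 82103861, 100),
        ProcessSummary("Inference-families-without-sequence", 146, 34359172, 50),
        ProcessSummary("Inference", 495, 116463033, 150),
    ]
    text = render_process_table(rows)
    parsed = {r["Type"]: r for r in parse_table(text)}
    assert parsed["Sequencing"]["% Discrepant"] == "0.00"
    assert parsed["Sequencing"]["Genotypes (N)"] == "107,780,325"
    pooled = parsed["Inference"]
    assert int(pooled["Subjects"]) == 349 + 146
    assert pooled["Genotypes (N)"] == f"{82103861 + 34359172:,}"
    # render/parse round trip preserves the summary numbers
    for s in rows:
        assert int(parsed[s.process]["Subjects"]) == s.subjects
        assert parsed[s.process]["% Discrepant"] == format_percent(
            s.discrepant, s.genotypes
        )


def test_manifest_telescoping_is_enforced():
    manifest = RunManifest(
        candidate_rsids=100, after_duplicates=90, after_chromosome=85,
        after_ambiguous=80, retained=70, high_call_rate=40,
    )
    manifest.validate()
    bad = RunManifest(candidate_rsids=10, after_duplicates=20)
    with pytest.raises(ValidationError):
        bad.validate()


# ---------------------------------------------------------------------------
# CLI integration


@pytest.fixture(scope="module")
def cli_scenario(tmp_path_factory):
    out = tmp_path_factory.mktemp("cli") / "scenario"
    config = SimulationConfig(
        n_families=5, family_size_range=(6, 12), n_generations=3,
        n_variants=150, n_noseq_families=2, seed=31,
    )
    write_scenario(simulate_scenario(config), out)
    return out


def _compare_args(scenario, out):
    return [
        "compare",
        "--gwas-ped", str(scenario / "gwas.ped"),
        "--gwas-map", str(scenario / "gwas.map"),
        "--geno", str(scenario / "geno.tsv"),
        "--seq-vcf", str(scenario / "sequence.vcf"),
        "--pedigree", str(scenario / "pedigree.tsv"),
        "--out", str(out),
    ]


def test_cli_compare_end_to_end_with_telescoping_manifest(cli_scenario, tmp_path):
    runner = CliRunner()
    out = tmp_path / "report"
    result = runner.invoke(main, _compare_args(cli_scenario, out))
    assert result.exit_code == 0, result.output
    manifest = dict(
        line.split("\t")
        for line in (out / "manifest.txt").read_text().splitlines()
    )
    stages = [
        int(manifest[f"stage.{k}"])
        for k in ("candidate_rsids", "after_duplicates", "after_chromosome",
                  "after_ambiguous", "retained", "high_call_rate")
    ]
    assert stages == sorted(stages, reverse=True)
    summary = json.loads((out / "summary.json").read_text())
    assert set(summary["sets"]) == {"full", "high_call_rate"}
    # report subcommand re-renders identical tables
    rpt = tmp_path / "rerender"
    result = runner.invoke(
        main, ["report", "--summary", str(out / "summary.json"),
               "--out", str(rpt)]
    )
    assert result.exit_code == 0, result.output
    assert (rpt / "process_full.tsv").read_text() == \
        (out / "process_full.tsv").read_text()


def test_cli_compare_is_deterministic(cli_scenario, tmp_path):
    runner = CliRunner()
    outs = []
    for d in ("r1", "r2"):
        out = tmp_path / d
        result = runner.invoke(main, _compare_args(cli_scenario, out))
        assert result.exit_code == 0, result.output
        outs.append(out)
    for name in ("family_full.tsv", "process_full.tsv", "summary.json",
                 "manifest.txt"):
        assert (outs[0] / name).read_bytes() == (outs[1] / name).read_bytes()


def test_cli_compare_unknown_sample_exits_nonzero(cli_scenario, tmp_path):
    truncated = tmp_path / "ped.tsv"
    lines = (cli_scenario / "pedigree.tsv").read_text().splitlines()
    truncated.write_text("\n".join(lines[:-1]) + "\n")
    dropped_sample = lines[-1].split("\t")[1]
    runner = CliRunner()
    args = _compare_args(cli_scenario, tmp_path / "x")
    args[args.index("--pedigree") + 1] = str(truncated)
    result = runner.invoke(main, args)
    assert result.exit_code == 1
    assert dropped_sample in result.output


def test_cli_audit_clean_scenario_has_no_violations(cli_scenario, tmp_path):
    runner = CliRunner()
    result = runner.invoke(
        main,
        ["audit",
         "--geno", str(cli_scenario / "geno.tsv"),
         "--dosage", str(cli_scenario / "dosage.txt"),
         "--dosage-snps", str(cli_scenario / "dosage.snps"),
         "--out", str(tmp_path / "audit.tsv")],
    )
    assert result.exit_code == 0, result.output
    assert "violations\t0" in result.output


def test_cli_simulate_then_harmonize(tmp_path):
    runner = CliRunner()
    config = tmp_path / "cfg.yaml"
    SimulationConfig(
        n_families=4, family_size_range=(5, 8), n_generations=2,
        n_variants=60, n_noseq_families=1, seed=3,
    ).to_yaml(config)
    out = tmp_path / "sc"
    result = runner.invoke(
        main, ["simulate", "--config", str(config), "--seed", "3",
               "--out", str(out)]
    )
    assert result.exit_code == 0, result.output
    result = runner.invoke(
        main, ["harmonize",
               "--gwas-ped", str(out / "gwas.ped"),
               "--gwas-map", str(out / "gwas.map"),
               "--geno", str(out / "geno.tsv"),
               "--out", str(tmp_path / "pairs.tsv")],
    )
    assert result.exit_code == 0, result.output
    pairs = (tmp_path / "pairs.tsv").read_text().splitlines()
    counters = dict(
        line.split("\t") for line in result.output.strip().splitlines()
    )
    assert len(pairs) - 1 == int(counters["retained"])
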