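"""Audit orchestration: config handling, summaries, outputs, CLI."""

import json

import numpy as np
import pandas as pd
import pytest
import yaml
from click.testing import CliRunner

from embaudit import (
    AnalogyQuery,
    AnalogyResult,
    SyntheticSpec,
    emit_fixture,
    generate,
    run_full_audit,
    summarize_bias,
)
from embaudit.cli import main
from embaudit.geometry import RankedNeighbors
from embaudit.report import AuditError, analogy_results_frame, load_config


def study_spec(seed: int = 7) -> SyntheticSpec:
    return SyntheticSpec(
        planted_terms=(
            ("depressed", -0.10, -0.08),
            ("manic", -0.07, -0.02),
            ("fit", 0.30, 0.25),
        ),
        analogy_quads=(("well", "productive", "psychotic", "workshy", 0.05),),
        n_background=120,
        noise_sd=0.0,
        seed=seed,
    )


@pytest.fixture
def fixture_dir(tmp_path):
    return emit_fixture(study_spec(), tmp_path / "fix")


def _result(rank, b="employable"):
    q = AnalogyQuery("healthy", b, "depression")
    ranked = RankedNeighbors([(f"tok{i}", 1.0 - 0.01 * i) for i in range(10)])
    positions = [rank] if rank else []
    return AnalogyResult(query=q, ranked=ranked, biased_positions=positions,
                         first_biased_rank=rank)


class TestSummarizeBias:
    def test_hand_enumerated_counts(self):
        results = [_result(1), _result(4), _result(None)]
        s = summarize_bias(results)
        assert (s["top1"], s["top5"], s["top10"], s["none"]) == (1, 2, 2, 1)

    def test_single_rank1_among_eleven(self):
        results = [_result(1)] + [_result(None) for _ in range(10)]
        s = summarize_bias(results)
        assert s["top1"] == 1 and s["none"] == 10 and s["n_queries"] == 11

    def test_all_unbiased(self):
        s = summarize_bias([_result(None), _result(None)])
        assert s["top1"] == s["top5"] == s["top10"] == 0 and s["none"] == 2

    def test_error_records_counted_separately(self):
        bad = AnalogyResult(query=AnalogyQuery("a", "b", "c"), error="OOV")
        s = summarize_bias([_result(1), bad])
        assert s["errors"] == 1 and s["top1"] == 1

    def test_per_attribute_breakdown(self):
        s = summarize_bias([_result(1, b="employable"),
                            _result(3, b="reliable"),
                            _result(None, b="reliable")])
        assert s["per_attribute"]["employable"]["best_rank"] == 1
        assert s["per_attribute"]["reliable"] == {
            "queries": 2, "biased": 1, "best_rank": 3}

    def test_empty_results_rejected(self):
        with pytest.raises(ValueError):
            summarize_bias([])


class TestRunFullAudit:
    def test_axes_only_config_has_empty_analogy_section(self, fixture_dir, tmp_path):
        cfg = {
            "embedding": {"path": str(fixture_dir / "vectors_glove.txt"),
                          "format": "glove_text"},
            "axes": {"terms": {"psychiatric": ["depressed", "manic"]}},
        }
        report = run_full_audit(cfg, tmp_path / "out")
        assert report.analogy_results == []
        assert len(report.projection) == 2
        assert not (tmp_path / "out" / "analogy_results.tsv").exists()

    def test_planted_bias_rank_reported(self, fixture_dir, tmp_path):
        cfg = {
            "embedding": {"path": str(fixture_dir / "vectors_word2vec.bin"),
                          "format": "word2vec_binary"},
            "analogy": {"battery": [["well", "productive", "psychotic"]],
                        "lexicon": ["workshy"]},
        }
        report = run_full_audit(cfg, tmp_path / "out")
        assert report.analogy_results[0].first_biased_rank == 1
        assert report.analogy_summary["top1"] == 1
        summary = json.loads((tmp_path / "out" / "summary.json").read_text())
        assert summary["analogy"]["summary"]["top1"] == 1

    def test_missing_embedding_file_is_fatal(self, tmp_path):
        cfg = {"embedding": {"path": str(tmp_path / "nope.txt"),
                             "format": "glove_text"},
               "axes": {}}
        with pytest.raises(AuditError, match="not found"):
            run_full_audit(cfg)

    def test_oov_terms_are_warnings_not_failures(self, fixture_dir, tmp_path):
        cfg = {
            "embedding": {"path": str(fixture_dir / "vectors_glove.txt"),
                          "format": "glove_text"},
            "axes": {"terms": {"psychiatric": ["depressed", "missingterm"]}},
        }
        report = run_full_audit(cfg, tmp_path / "out")
        assert any("missingterm" in w for w in report.warnings)
        assert len(report.projection) == 1

    def test_report_counts_recomputable_from_emitted_tsv(self, fixture_dir, tmp_path):
        cfg = {
            "embedding": {"path": str(fixture_dir / "vectors_word2vec.txt"),
                          "format": "word2vec_text"},
            "analogy": {"battery": [["well", "productive", "psychotic"],
                                    ["well", "productive", "depressed"]],
                        "lexicon": ["workshy"]},
        }
        report = run_full_audit(cfg, tmp_path / "out")
        tsv = pd.read_csv(tmp_path / "out" / "analogy_results.tsv", sep="\t")
        top1_from_tsv = int(((tsv["rank"] == 1) & tsv["biased"]).sum())
        assert top1_from_tsv == report.analogy_summary["top1"]

    def test_config_must_name_an_audit_block(self, tmp_path):
        path = tmp_path / "cfg.yaml"
        path.write_text(yaml.safe_dump({"embedding": {"path": "x"}}))
        with pytest.raises(AuditError, match="neither"):
            load_config(path)

    def test_sha256_recorded_for_file_based_runs(self, fixture_dir, tmp_path):
        cfg = {
            "embedding": {"path": str(fixture_dir / "vectors_glove.txt"),
                          "format": "glove_text"},
            "axes": {"terms": {"psychiatric": ["depressed"]}},
        }
        report = run_full_audit(cfg, tmp_path / "out")
        assert len(report.meta["embedding_sha256"]) == 64

    def test_results_frame_has_error_rows(self):
        bad = AnalogyResult(query=AnalogyQuery("a", "b", "c"), error="boom")
        frame = analogy_results_frame([bad])
        assert frame.iloc[0]["error"] == "boom"


class TestCli:
    def test_simulate_then_audit_axes_recovers_ground_truth(self, tmp_path):
        runner = CliRunner()
        spec_file = tmp_path / "spec.yaml"
        spec = study_spec()
        spec_file.write_text(yaml.safe_dump({
            "dim": spec.dim, "n_background": spec.n_background,
            "noise_sd": spec.noise_sd, "seed": spec.seed,
            "planted_terms": [list(t) for t in spec.planted_terms],
            "analogy_quads": [list(q) for q in spec.analogy_quads],
        }))
        fix = tmp_path / "fix"
        res = runner.invoke(main, ["simulate", "--spec", str(spec_file),
                                   "--out", str(fix)])
        assert res.exit_code == 0, res.output
        terms_file = tmp_path / "terms.yaml"
        terms_file.write_text(yaml.safe_dump(
            {"psychiatric": ["depressed", "manic"],
             "very_healthy_control": ["fit"]}))
        out = tmp_path / "axout"
        res = runner.invoke(main, [
            "audit-axes", "--embeddings", str(fix / "vectors_glove.txt"),
            "--format", "glove-txt", "--terms", str(terms_file),
            "--x-poles", "healthy,ill",
            "--y-poles", "employable,unemployable", "--out", str(out)])
        assert res.exit_code == 0, res.output
        table = pd.read_csv(out / "projections.tsv", sep="\t").set_index("term")
        truth = json.loads((fix / "ground_truth.json").read_text())["loadings"]
        for term, (x, y) in truth.items():
            assert table.loc[term, "x_score"] == pytest.approx(x, abs=1e-3)
            assert table.loc[term, "y_score"] == pytest.approx(y, abs=1e-3)

    def test_audit_analogy_cli_reports_planted_rank(self, fixture_dir, tmp_path):
        runner = CliRunner()
        battery = tmp_path / "battery.yaml"
        battery.write_text(yaml.safe_dump([["well", "productive", "psychotic"]]))
        lexicon = tmp_path / "lexicon.yaml"
        lexicon.write_text(yaml.safe_dump(["workshy"]))
        out = tmp_path / "anout"
        res = runner.invoke(main, [
            "audit-analogy", "--embeddings",
            str(fixture_dir / "vectors_word2vec.bin"),
            "--format", "word2vec-bin", "--battery", str(battery),
            "--lexicon", str(lexicon), "--out", str(out)])
        assert res.exit_code == 0, res.output
        summary = json.loads((out / "summary.json").read_text())
        key = "well : productive :: psychotic : ?"
        assert summary["analogy"]["first_biased_rank"][key] == 1

    def test_audit_all_runs_both_blocks(self, fixture_dir, tmp_path):
        runner = CliRunner()
        cfg = tmp_path / "cfg.yaml"
        cfg.write_text(yaml.safe_dump({
            "embedding": {"path": str(fixture_dir / "vectors_glove.txt"),
                          "format": "glove_text"},
            "analogy": {"battery": [["well", "productive", "psychotic"]],
                        "lexicon": ["workshy"]},
            "axes": {"terms": {"psychiatric": ["depressed"]}},
        }))
        out = tmp_path / "allout"
        res = runner.invoke(main, ["audit-all", "--config", str(cfg),
                                   "--out", str(out)])
        assert res.exit_code == 0, res.output
        for name in ("analogy_results.tsv", "projections.tsv",
                     "summary.json", "report.txt", "scatter.png"):
            assert (out / name).is_file()

    def test_missing_embedding_gives_nonzero_exit(self, tmp_path):
        runner = CliRunner()
        res = runner.invoke(main, [
            "audit-axes", "--embeddings", str(tmp_path / "ghost.txt"),
            "--format", "glove-txt", "--out", str(tmp_path / "o")])
        assert res.exit_code != 0
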