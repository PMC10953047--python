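"""Model/results layer, end-to-end pipeline and CLI."""

import json

import numpy as np
import pandas as pd
import pytest
from click.testing import CliRunner

from lupustrat import (
    CohortConfig,
    CohortStratificationModel,
    RunConfig,
    generate_cohort,
    run_pipeline,
)
from lupustrat.cli import main
from lupustrat.pipeline import reproduce_printed_tables


@pytest.fixture(scope="module")
def fitted(small_cohort_module):
    config, ct, clinical, truth = small_cohort_module
    model = CohortStratificationModel(ct, clinical)
    return model.fit(), truth


@pytest.fixture(scope="module")
def small_cohort_module():
    config = CohortConfig(seed=11)
    ct, clinical, truth = generate_cohort(config)
    return config, ct, clinical, truth


class TestModel:
    def test_two_strata_three_clusters_each(self, fitted):
        results, _ = fitted
        assert set(results.assignments) == {"EA", "NEA"}
        for assignment in results.assignments.values():
            sizes = [len(assignment.members(c)) for c in range(1, 4)]
            assert all(s > 0 for s in sizes)
            assert len(assignment.archetypes) == 3

    def test_response_labels_cover_all_patients(self, fitted):
        results, _ = fitted
        counts = results.response.value_counts()
        assert counts.get("responder", 0) + counts.get("nonresponder", 0) > 0
        assert set(results.response.unique()) <= {
            "responder", "nonresponder", "undetermined", "ineligible"
        }

    def test_recovers_planted_partition(self, fitted):
        from sklearn.metrics import adjusted_rand_score

        results, truth = fitted
        for stratum, assignment in results.assignments.items():
            ari = adjusted_rand_score(
                truth.labels_for(assignment.samples), assignment.labels
            )
            assert ari >= 0.8

    def test_contingency_and_tests_present(self, fitted):
        results, _ = fitted
        assert "NEA" in results.contingency and "EA" in results.contingency
        assert "cluster_response_NEA" in results.tests
        assert "ancestry_response" in results.tests
        fractions = results.responder_fraction("NEA")
        assert ((fractions >= 0) & (fractions <= 1)).all()

    def test_cluster_characteristics_report(self, fitted):
        results, _ = fitted
        report = results.cluster_characteristics("NEA")
        assert list(report.columns[:4]) == ["variable", "NEA-1", "NEA-2", "NEA-3"]
        assert "bilag_responder" in set(report["variable"])
        assert any(v.startswith("score:") for v in report["variable"])
        ps = report["p_value"].dropna()
        assert ((ps >= 0) & (ps <= 1)).all()

    def test_summary_mentions_archetypes_and_statistics(self, fitted):
        results, _ = fitted
        text = results.summary()
        assert "chi-square" in text and "Stratum NEA" in text
        assert any(a in text for a in ("all-high", "IFN-high/neutrophil-low"))

    def test_missing_clinical_rows_rejected(self, small_cohort_module):
        _, ct, clinical, _ = small_cohort_module
        with pytest.raises(ValueError, match="clinical row"):
            CohortStratificationModel(ct, clinical.iloc[:10])

    def test_from_files_round_trip(self, small_cohort_module, tmp_path):
        from lupustrat.qpcr import write_ct_table

        _, ct, clinical, _ = small_cohort_module
        write_ct_table(ct, tmp_path / "ct.tsv")
        clinical.to_csv(tmp_path / "clinical.csv", index=False)
        model = CohortStratificationModel.from_files(
            tmp_path / "ct.tsv", tmp_path / "clinical.csv"
        )
        results = model.fit()
        assert set(results.assignments) == {"EA", "NEA"}


class TestPipeline:
    def test_run_writes_artifacts_and_summary(self, tmp_path):
        config = RunConfig(out_dir=tmp_path / "run", seed=7,
                           cohort=CohortConfig(seed=7))
        summary = run_pipeline(config)
        for stratum in ("EA", "NEA"):
            assert len(summary["strata"][stratum]["clusters"]) == 3
        assert (tmp_path / "run" / "summary.json").exists()
        assert (tmp_path / "run" / "merges_NEA.tsv").exists()
        assert summary["checksums"]

    def test_rerun_is_byte_identical(self, tmp_path):
        texts = []
        for name in ("a", "b"):
            config = RunConfig(out_dir=tmp_path / name, seed=3,
                               cohort=CohortConfig(seed=3))
            run_pipeline(config)
            texts.append((tmp_path / name / "summary.json").read_text())
        assert texts[0] == texts[1]

    def test_missing_inputs_rejected_when_not_simulating(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            RunConfig(out_dir=tmp_path, simulate=False)

    def test_printed_tables_reproduce(self):
        table = reproduce_printed_tables()
        assert bool(table["agrees"].all())
        chi = table[table["quantity"] == "chi_square"].set_index("table")["computed"]
        assert chi["NEA_clusters"] == pytest.approx(14.45, abs=0.01)


class TestCli:
    def test_simulate_then_report(self, tmp_path):
        runner = CliRunner()
        out = tmp_path / "cohort"
        result = runner.invoke(
            main, ["simulate", "--out-dir", str(out), "--seed", "2"]
        )
        assert result.exit_code == 0, result.output
        result = runner.invoke(
            main,
            ["report", str(out / "ct_matrix.tsv"), str(out / "clinical.csv"),
             "--out-dir", str(tmp_path / "report")],
        )
        assert result.exit_code == 0, result.output
        assert "chi-square" in result.output

    def test_process_subcommand(self, tmp_path):
        runner = CliRunner()
        out = tmp_path / "cohort"
        runner.invoke(main, ["simulate", "--out-dir", str(out), "--seed", "4",
                             "--n-ea", "20", "--n-nea", "20"])
        result = runner.invoke(
            main,
            ["process", str(out / "ct_matrix.tsv"),
             "--out", str(tmp_path / "expr.tsv")],
        )
        assert result.exit_code == 0, result.output
        frame = pd.read_csv(tmp_path / "expr.tsv", sep="\t", index_col=0)
        assert frame.shape == (94, 40)
        assert np.isfinite(frame.to_numpy()).all()

    def test_cluster_subcommand(self, tmp_path):
        runner = CliRunner()
        out = tmp_path / "cohort"
        runner.invoke(main, ["simulate", "--out-dir", str(out), "--seed", "5",
                             "--n-ea", "18", "--n-nea", "18"])
        runner.invoke(main, ["process", str(out / "ct_matrix.tsv"),
                             "--out", str(tmp_path / "expr.tsv")])
        result = runner.invoke(
            main, ["cluster", str(tmp_path / "expr.tsv"),
                   "--out-dir", str(tmp_path / "clust"), "--k", "2"],
        )
        assert result.exit_code == 0, result.output
        frame = pd.read_csv(tmp_path / "clust" / "assignments.csv")
        assert set(frame["cluster_id"]) == {1, 2}
        merges = pd.read_csv(tmp_path / "clust" / "merges.tsv", sep="\t")
        assert list(merges.columns) == ["left", "right", "height"]

    def test_reproduce_subcommand(self):
        result = CliRunner().invoke(main, ["reproduce"])
        assert result.exit_code == 0, result.output
        assert "14.45" in result.output
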