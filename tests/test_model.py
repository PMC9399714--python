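"""Model/Results interface, pipeline driver, and CLI."""

import json

import numpy as np
import pytest

from rdpglink import (
    BLOCKS,
    RdpgLinkPredictor,
    SplitSpec,
    SyntheticScenario,
    make_benchmark,
    run_pipeline,
)


@pytest.fixture(scope="module")
def fitted():
    truth = make_benchmark(
        SyntheticScenario(M=120, N=110, d_true=2, noise_sd=0.0, seed=42)
    )
    model = RdpgLinkPredictor.from_benchmark(
        truth, d=2, split_spec=SplitSpec(seed=42)
    )
    return truth, model.fit()


class TestResults:
    def test_block_probabilities_in_unit_interval(self, fitted):
        _, res = fitted
        for block in BLOCKS:
            vals = res.block_probabilities(block).values
            assert vals.min() >= 0 and vals.max() <= 1

    def test_block_provenance(self, fitted):
        _, res = fitted
        assert res.block_probabilities("obs_obs").provenance == ("svd", "svd")
        assert res.block_probabilities("new_new").provenance == ("metadata", "metadata")
        assert res.block_probabilities("new_obs").provenance == ("metadata", "svd")

    def test_obs_obs_excludes_training_edges(self, fitted):
        _, res = fitted
        scored = res.score_block("obs_obs")
        train_edges = set(res.split.training_graph.edges())
        assert not train_edges & set(scored.pair_ids)

    def test_scored_labels_match_source_graph(self, fitted):
        truth, res = fitted
        scored = res.score_block("new_new")
        ridx = {r: i for i, r in enumerate(truth.graph.row_ids)}
        cidx = {c: j for j, c in enumerate(truth.graph.col_ids)}
        A = truth.graph.toarray()
        expect = [A[ridx[r], cidx[c]] for r, c in scored.pair_ids]
        assert scored.labels.tolist() == expect

    def test_new_nodes_absent_from_training(self, fitted):
        _, res = fitted
        assert not set(res.split.row_new) & set(res.embedding.row_ids)
        assert not set(res.split.col_new) & set(res.embedding.col_ids)

    def test_informative_metadata_beats_chance(self, fitted):
        _, res = fitted
        assert res.block_auc("new_new") > 0.55

    def test_summary_mentions_key_facts(self, fitted):
        _, res = fitted
        text = res.summary()
        assert "latent dimension d = 2" in text
        assert "new_new" in text and "AUC" in text

    def test_mapping_metrics_structure(self, fitted):
        _, res = fitted
        mm = res.mapping_metrics()
        assert set(mm) == {"row", "col"}
        assert mm["row"]["test"]["mae"] > 0


class TestRunPipeline:
    CONFIG = {
        "scenario": {"M": 80, "N": 80, "d_true": 2, "noise_sd": 0.0},
        "split": {"new_row_fraction": 0.15, "new_col_fraction": 0.15},
        "d": 2,
        "family": "linear",
        "evaluation": {"n_sample": 300, "n_boot": 100},
    }

    def test_runs_and_reports(self, tmp_path):
        report, results = run_pipeline(dict(self.CONFIG), seed=7, out_dir=tmp_path / "run")
        assert 0 <= report.auc <= 1
        assert (tmp_path / "run" / "report.json").exists()
        assert (tmp_path / "run" / "manifest.json").exists()
        manifest = json.loads((tmp_path / "run" / "manifest.json").read_text())
        assert manifest["complete"] is True
        metrics = json.loads((tmp_path / "run" / "block_metrics.json").read_text())
        assert set(metrics) == set(BLOCKS)

    def test_byte_identical_reports_same_seed(self, tmp_path):
        r1, _ = run_pipeline(dict(self.CONFIG), seed=11, out_dir=tmp_path / "a")
        r2, _ = run_pipeline(dict(self.CONFIG), seed=11, out_dir=tmp_path / "b")
        assert (tmp_path / "a" / "report.json").read_bytes() == (
            tmp_path / "b" / "report.json"
        ).read_bytes()
        assert r1.auc == r2.auc

    def test_failure_leaves_manifest(self, tmp_path):
        bad = dict(self.CONFIG)
        bad["d"] = 999  # out of range at fit time
        with pytest.raises(RuntimeError, match="stage"):
            run_pipeline(bad, seed=0, out_dir=tmp_path / "bad")
        manifest = json.loads((tmp_path / "bad" / "manifest.json").read_text())
        assert manifest["complete"] is False
        assert "error" in manifest


class TestMonotonicity:
    def test_metadata_information_ordering(self):
        """Cold-start AUC ranks: informative metadata >= noisy >= permuted,
        averaged over seeds."""
        levels = {"clean": [], "noisy": [], "permuted": []}
        for seed in range(5):
            truth = make_benchmark(
                SyntheticScenario(M=150, N=150, d_true=2, noise_sd=0.0, seed=seed)
            )
            noisy = make_benchmark(
                SyntheticScenario(M=150, N=150, d_true=2, noise_sd=0.5, seed=seed)
            )
            res = RdpgLinkPredictor.from_benchmark(
                truth, d=2, split_spec=SplitSpec(seed=seed)
            ).fit()
            res_noisy = RdpgLinkPredictor(
                truth.graph, noisy.row_metadata, noisy.col_metadata, d=2,
                split_spec=SplitSpec(seed=seed),
            ).fit()
            rng = np.random.default_rng(seed + 500)
            from rdpglink import NodeMetadataTable

            perm_row = NodeMetadataTable(
                truth.row_metadata.node_ids,
                truth.row_metadata.data.iloc[rng.permutation(150)].reset_index(drop=True),
                truth.row_metadata.schema,
            )
            perm_col = NodeMetadataTable(
                truth.col_metadata.node_ids,
                truth.col_metadata.data.iloc[rng.permutation(150)].reset_index(drop=True),
                truth.col_metadata.schema,
            )
            res_perm = RdpgLinkPredictor(
                truth.graph, perm_row, perm_col, d=2, split_spec=SplitSpec(seed=seed)
            ).fit()
            new_blocks = ("new_obs", "obs_new", "new_new")
            levels["clean"].append(np.mean([res.block_auc(b) for b in new_blocks]))
            levels["noisy"].append(np.mean([res_noisy.block_auc(b) for b in new_blocks]))
            levels["permuted"].append(np.mean([res_perm.block_auc(b) for b in new_blocks]))
        assert np.mean(levels["clean"]) >= np.mean(levels["noisy"])
        assert np.mean(levels["noisy"]) >= np.mean(levels["permuted"])


class TestCli:
    def test_simulate_embed_run(self, tmp_path):
        from click.testing import CliRunner

        from rdpglink.cli import main

        runner = CliRunner()
        out = runner.invoke(
            main, ["simulate", "--seed", "3", "--out-dir", str(tmp_path / "sim")]
        )
        assert out.exit_code == 0, out.output
        assert (tmp_path / "sim" / "graph.mtx").exists()

        out = runner.invoke(
            main,
            ["embed", str(tmp_path / "sim" / "graph.mtx"), "-d", "2",
             "--out", str(tmp_path / "emb")],
        )
        assert out.exit_code == 0, out.output
        assert (tmp_path / "emb.rows.csv").exists()

        cfg = tmp_path / "cfg.yaml"
        cfg.write_text(
            "scenario: {M: 60, N: 60, d_true: 2}\n"
            "d: 2\nfamily: linear\n"
            "evaluation: {n_sample: 200, n_boot: 50}\n"
        )
        out = runner.invoke(
            main, ["run", "--config", str(cfg), "--seed", "5",
                   "--out-dir", str(tmp_path / "run")]
        )
        assert out.exit_code == 0, out.output
        assert "RDPG link prediction results" in out.output
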