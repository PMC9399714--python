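"""Metadata-to-latent regressions: linear baseline and neural networks."""

import numpy as np
import pandas as pd
import pytest

from rdpglink import (
    MappingModel,
    NodeMetadataTable,
    TrainingConfig,
    encode_features,
    evaluate_mapping,
    fit_mapping,
    predict_latent,
)
from rdpglink.graph import DesignMatrix, EncoderSpec


def continuous_design(values, names=None):
    """Build a DesignMatrix directly from a raw numeric array (identity
    encoding: center 0, scale 1) so fits are exact on the given values."""
    X = np.asarray(values, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    names = names or [f"f{k}" for k in range(X.shape[1])]
    spec = EncoderSpec(list(names), {}, {n: (0.0, 1.0) for n in names})
    return DesignMatrix(list(range(X.shape[0])), X, spec)


class TestLinear:
    def test_identity_map_recovered(self, rng):
        X = continuous_design(rng.normal(size=(30, 4)))
        model = fit_mapping(X, X.matrix, "linear")
        assert evaluate_mapping(model, X, X.matrix)["mae"] == pytest.approx(0, abs=1e-10)

    def test_worked_one_dimensional_example(self):
        X = continuous_design([0.0, 1.0, 2.0])
        model = fit_mapping(X, np.array([0.0, 1.0, 4.0]), "linear")
        W, b = model.weights[0]
        assert W[0, 0] == pytest.approx(2.0)
        assert b[0] == pytest.approx(-1 / 3)
        assert model.training_history["train"][0] == pytest.approx(4 / 9)

    def test_matches_pseudoinverse_oracle(self, rng):
        for _ in range(20):
            n, p, d = int(rng.integers(5, 100)), int(rng.integers(1, 10)), 3
            X = continuous_design(rng.normal(size=(n, p)))
            Z = rng.normal(size=(n, d))
            model = fit_mapping(X, Z, "linear")
            design = np.hstack([np.ones((n, 1)), X.matrix])
            B_oracle = np.linalg.pinv(design) @ Z
            fitted = np.vstack([model.weights[0][1], model.weights[0][0]])
            assert np.allclose(fitted, B_oracle, atol=1e-8)

    def test_collinear_one_hot_design_is_solvable(self):
        # full one-hot columns sum to the intercept: minimum-norm LS copes
        t = NodeMetadataTable(
            [1, 2, 3, 4],
            pd.DataFrame({"v": ["A", "B", "A", "B"]}),
            {"v": "categorical"},
        )
        X = encode_features(t)
        Z = np.array([[1.0], [2.0], [1.0], [2.0]])
        model = fit_mapping(X, Z, "linear")
        assert np.allclose(model.forward(X.matrix), Z, atol=1e-8)

    def test_misaligned_rows_rejected(self):
        X = continuous_design([[1.0], [2.0]])
        with pytest.raises(ValueError, match="rows"):
            fit_mapping(X, np.zeros((3, 1)), "linear")

    def test_nan_rejected(self):
        X = continuous_design([[1.0], [np.nan]])
        with pytest.raises(ValueError, match="NaN"):
            fit_mapping(X, np.zeros((2, 1)), "linear")


class TestPredict:
    def test_stated_cold_start_formula(self):
        # x* = beta0 + m . beta with beta0=0.5, beta=(1,-1), m=(0.2,0.1)
        spec = EncoderSpec(["f0", "f1"], {}, {"f0": (0.0, 1.0), "f1": (0.0, 1.0)})
        model = MappingModel(
            "linear",
            [(np.array([[1.0], [-1.0]]), np.array([0.5]))],
            spec,
            output_dim=1,
        )
        t = NodeMetadataTable(
            ["n"], pd.DataFrame({"f0": [0.2], "f1": [0.1]}),
            {"f0": "continuous", "f1": "continuous"},
        )
        assert predict_latent(model, t)[0, 0] == pytest.approx(0.6)

    def test_identical_rows_identical_predictions(self, rng):
        X = continuous_design(rng.normal(size=(20, 3)))
        model = fit_mapping(X, rng.normal(size=(20, 2)), "mlp1", TrainingConfig(epochs=2, seed=0))
        row = continuous_design(np.vstack([X.matrix[0], X.matrix[0]]))
        out = predict_latent(model, row)
        assert np.array_equal(out[0], out[1])

    def test_training_row_reproduced_by_linear_fit(self, rng):
        X = continuous_design(rng.normal(size=(10, 3)))
        model = fit_mapping(X, X.matrix, "linear")
        pred = predict_latent(model, continuous_design(X.matrix[[4]]))
        assert np.allclose(pred, X.matrix[4], atol=1e-8)


class TestEvaluate:
    @pytest.mark.parametrize(
        "pred, target, mae, mse",
        [
            ([[1.0]], [[1.0]], 0.0, 0.0),
            ([[1.0]], [[0.0]], 1.0, 1.0),
            ([[0.5, 0.0]], [[0.0, 0.0]], 0.25, 0.125),
        ],
    )
    def test_cellwise_means(self, pred, target, mae, mse):
        # constant model returning `pred` regardless of input
        p = np.asarray(pred, dtype=float)
        spec = EncoderSpec(["f0"], {}, {"f0": (0.0, 1.0)})
        model = MappingModel(
            "linear", [(np.zeros((1, p.shape[1])), p[0])], spec, p.shape[1]
        )
        X = DesignMatrix([0], np.zeros((1, 1)), spec)
        out = evaluate_mapping(model, X, np.asarray(target, dtype=float))
        assert out["mae"] == pytest.approx(mae)
        assert out["mse"] == pytest.approx(mse)


class TestNetworks:
    def test_constant_targets_learned(self, rng):
        X = continuous_design(rng.normal(size=(50, 3)))
        Z = np.full((50, 2), 0.7)
        for family in ("mlp1", "nn2"):
            model = fit_mapping(X, Z, family, TrainingConfig(seed=1))
            history = model.training_history["train"]
            # converges towards the attainable constant: error shrinks
            # steadily and ends at a small fraction of the target value
            assert history[-1] < history[0] < 0.7
            assert evaluate_mapping(model, X, Z)["mae"] < 0.15 * 0.7

    def test_seeded_reproducibility(self, rng):
        X = continuous_design(rng.normal(size=(40, 3)))
        Z = rng.normal(size=(40, 2))
        cfg = TrainingConfig(epochs=5, seed=9)
        h1 = fit_mapping(X, Z, "mlp1", cfg).training_history
        h2 = fit_mapping(X, Z, "mlp1", cfg).training_history
        assert h1 == h2

    def test_time_decay_schedule_exact(self):
        cfg = TrainingConfig(schedule="time_decay")
        rates = [cfg.rate_at(t) for t in range(cfg.epochs)]
        assert rates == pytest.approx([0.01 - 0.0001 * t for t in range(30)])

    def test_history_records_test_loss(self, rng):
        X = continuous_design(rng.normal(size=(40, 3)))
        Z = rng.normal(size=(40, 2))
        Xt = continuous_design(rng.normal(size=(10, 3)))
        Zt = rng.normal(size=(10, 2))
        cfg = TrainingConfig(epochs=3, seed=2)
        model = fit_mapping(X, Z, "mlp1", cfg, test=(Xt, Zt))
        assert len(model.training_history["train"]) == 3
        assert len(model.training_history["test"]) == 3

    def test_invalid_schedule_config(self):
        with pytest.raises(ValueError, match="non-positive"):
            TrainingConfig(schedule="time_decay", learning_rate=0.001, epochs=30)

    def test_architecture_widths(self, rng):
        X = continuous_design(rng.normal(size=(25, 4)))
        Z = rng.normal(size=(25, 3))
        m1 = fit_mapping(X, Z, "mlp1", TrainingConfig(epochs=1, seed=0))
        assert [w.shape for w, _ in m1.weights] == [(4, 200), (200, 3)]
        m2 = fit_mapping(X, Z, "nn2", TrainingConfig(epochs=1, seed=0))
        assert [w.shape for w, _ in m2.weights] == [(4, 250), (250, 250), (250, 3)]

    def test_save_load_bit_identical_predictions(self, tmp_path, rng):
        X = continuous_design(rng.normal(size=(30, 3)))
        Z = rng.normal(size=(30, 2))
        model = fit_mapping(X, Z, "mlp1", TrainingConfig(epochs=2, seed=4))
        model.save(tmp_path / "m.json")
        back = MappingModel.load(tmp_path / "m.json")
        assert np.array_equal(back.forward(X.matrix), model.forward(X.matrix))


class TestNonlinearity:
    def test_networks_beat_linear_on_quadratic_map(self, rng):
        """Latent coordinates recoverable from metadata only through a
        square root: the misspecified linear fit plateaus, the networks
        pass below it."""
        from rdpglink import SyntheticScenario, generate_metadata, sample_latent_positions

        sc = SyntheticScenario(M=600, N=600, d_true=3, metadata_map="quadratic",
                               noise_sd=0.0, seed=21)
        X_true, _ = sample_latent_positions(600, 600, 3, seed=22)
        md = generate_metadata(X_true, sc, side="row")
        train, test = md.node_ids[:300], md.node_ids[300:]
        Xtr = encode_features(md.subset(train))
        Xte = encode_features(md.subset(test), Xtr.encoder_spec)
        Ztr, Zte = X_true[:300], X_true[300:]
        maes = {}
        for family in ("linear", "mlp1", "nn2"):
            m = fit_mapping(Xtr, Ztr, family, TrainingConfig(seed=5))
            maes[family] = evaluate_mapping(m, Xte, Zte)["mae"]
        assert maes["mlp1"] <= maes["linear"]
        assert maes["nn2"] <= maes["linear"]

    def test_linear_competitive_on_linear_map(self, rng):
        """On a purely linear metadata map the linear fit is within 10% of
        the best network (here: essentially exact)."""
        from rdpglink import SyntheticScenario, generate_metadata, sample_latent_positions

        sc = SyntheticScenario(M=400, N=400, d_true=3, metadata_map="linear",
                               noise_sd=0.0, seed=31)
        X_true, _ = sample_latent_positions(400, 400, 3, seed=32)
        md = generate_metadata(X_true, sc, side="row")
        train, test = md.node_ids[:200], md.node_ids[200:]
        Xtr = encode_features(md.subset(train))
        Xte = encode_features(md.subset(test), Xtr.encoder_spec)
        lin = evaluate_mapping(
            fit_mapping(Xtr, X_true[:200], "linear"), Xte, X_true[200:]
        )["mae"]
        best_net = min(
            evaluate_mapping(
                fit_mapping(Xtr, X_true[:200], fam, TrainingConfig(seed=6)),
                Xte, X_true[200:],
            )["mae"]
            for fam in ("mlp1", "nn2")
        )
        assert lin <= 1.1 * best_net
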