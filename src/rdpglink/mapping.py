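"""Regressions from encoded node metadata to latent positions.

Three model families map a node's encoded metadata vector to its
``d``-dimensional latent position: an ordinary least-squares linear
baseline (minimum-norm solution, so full one-hot designs are handled), a
one-hidden-layer perceptron of 200 ReLU units, and a two-hidden-layer
network of 250 ReLU units each.  The networks are trained by mini-batch
Adam on mean-absolute-error cost for 30 epochs with batch size 20, under
either a constant learning rate of 0.01 or a time-based decay that lowers
it by 0.0001 after each epoch.  The fitted mapping is what lets a
brand-new node, observed only through its metadata, be projected into the
latent space: ``x*_{n+1} = β₀ + m_{n+1}·β`` in the linear case, the
network forward pass otherwise.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .graph import DesignMatrix, EncoderSpec, NodeMetadataTable, encode_features

__all__ = [
    "TrainingConfig",
    "MappingModel",
    "fit_mapping",
    "predict_latent",
    "evaluate_mapping",
]

FAMILIES = ("linear", "mlp1", "nn2")
_HIDDEN = {"mlp1": (200,), "nn2": (250, 250)}


@dataclass
class TrainingConfig:
    """Network training protocol (ignored by the linear family)."""

    epochs: int = 30
    batch_size: int = 20
    optimizer: str = "adam"
    learning_rate: float = 0.01
    schedule: str = "constant"  # or "time_decay"
    decay: float = 0.0001  # per-epoch decrement under time_decay
    loss: str = "mae"
    seed: int = 0

    def __post_init__(self):
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.optimizer != "adam":
            raise ValueError(f"unsupported optimizer {self.optimizer!r}")
        if self.schedule not in ("constant", "time_decay"):
            raise ValueError(f"unknown schedule {self.schedule!r}")
        if self.loss != "mae":
            raise ValueError("only MAE cost is supported")
        if self.schedule == "time_decay" and self.decay * self.epochs >= self.learning_rate:
            raise ValueError("decay schedule would drive the learning rate non-positive")

    def rate_at(self, epoch: int) -> float:
        """Effective learning rate during *epoch* (0-based)."""
        if self.schedule == "time_decay":
            return self.learning_rate - self.decay * epoch
        return self.learning_rate


@dataclass
class MappingModel:
    """A fitted metadata→latent mapping (weights + the frozen encoder)."""

    family: str
    weights: list  # [(W, b), ...]; linear stores a single (B, b0)
    input_encoder: EncoderSpec
    output_dim: int
    config: TrainingConfig | None = None
    training_history: dict = field(default_factory=dict)

    def forward(self, X: np.ndarray) -> np.ndarray:
        Z = np.asarray(X, dtype=float)
        for i, (W, b) in enumerate(self.weights):
            Z = Z @ W + b
            if i < len(self.weights) - 1:
                Z = np.maximum(Z, 0.0)  # ReLU on hidden layers only
        return Z

    def save(self, path) -> None:
        """Serialise to JSON; repr-based floats round-trip bit-exactly."""
        payload = {
            "family": self.family,
            "output_dim": self.output_dim,
            "weights": [[W.tolist(), b.tolist()] for W, b in self.weights],
            "encoder": self.input_encoder.to_dict(),
            "config": asdict(self.config) if self.config else None,
            "training_history": self.training_history,
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def load(cls, path) -> "MappingModel":
        d = json.loads(Path(path).read_text())
        return cls(
            family=d["family"],
            weights=[(np.array(W), np.array(b)) for W, b in d["weights"]],
            input_encoder=EncoderSpec.from_dict(d["encoder"]),
            output_dim=d["output_dim"],
            config=TrainingConfig(**d["config"]) if d["config"] else None,
            training_history=d["training_history"],
        )


def _check_xy(X: DesignMatrix, Z: np.ndarray) -> np.ndarray:
    Z = np.asarray(Z, dtype=float)
    if Z.ndim == 1:
        Z = Z[:, None]
    if len(X.node_ids) != Z.shape[0]:
        raise ValueError(
            f"design matrix has {len(X.node_ids)} rows but targets have {Z.shape[0]}"
        )
    if not np.isfinite(X.matrix).all():
        raise ValueError("NaN or infinite values in design matrix")
    if not np.isfinite(Z).all():
        raise ValueError("NaN or infinite values in latent targets")
    return Z


def _mae(pred: np.ndarray, target: np.ndarray) -> float:
    return float(np.abs(pred - target).mean())


def _init_layers(widths: list[int], rng: np.random.Generator) -> list:
    # uniform fan-in scaling: U(-1/sqrt(fan_in), 1/sqrt(fan_in))
    layers = []
    for fan_in, fan_out in zip(widths[:-1], widths[1:]):
        lim = 1.0 / np.sqrt(fan_in)
        W = rng.uniform(-lim, lim, size=(fan_in, fan_out))
        b = np.zeros(fan_out)
        layers.append((W, b))
    return layers


def _train_network(
    model: MappingModel,
    X: np.ndarray,
    Z: np.ndarray,
    config: TrainingConfig,
    test: tuple[np.ndarray, np.ndarray] | None,
) -> None:
    rng = np.random.default_rng(config.seed)
    model.weights = _init_layers(
        [X.shape[1], *_HIDDEN[model.family], Z.shape[1]], rng
    )
    params = [arr for Wb in model.weights for arr in Wb]
    m_t = [np.zeros_like(p) for p in params]
    v_t = [np.zeros_like(p) for p in params]
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    step = 0
    n = X.shape[0]
    history = {"train": [], "test": [], "learning_rate": []}
    for epoch in range(config.epochs):
        lr = config.rate_at(epoch)
        order = rng.permutation(n)
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            xb, zb = X[idx], Z[idx]
            # forward with cached activations
            acts = [xb]
            for i, (W, b) in enumerate(model.weights):
                out = acts[-1] @ W + b
                if i < len(model.weights) - 1:
                    out = np.maximum(out, 0.0)
                acts.append(out)
            # MAE gradient: sign of residual, averaged over batch cells
            delta = np.sign(acts[-1] - zb) / (zb.shape[0] * zb.shape[1])
            grads = []
            for i in range(len(model.weights) - 1, -1, -1):
                W, _ = model.weights[i]
                gW = acts[i].T @ delta
                gb = delta.sum(axis=0)
                grads[:0] = [gW, gb]
                if i > 0:
                    delta = (delta @ W.T) * (acts[i] > 0)
            step += 1
            new_params = []
            for j, (p, g) in enumerate(zip(params, grads)):
                m_t[j] = beta1 * m_t[j] + (1 - beta1) * g
                v_t[j] = beta2 * v_t[j] + (1 - beta2) * g**2
                mhat = m_t[j] / (1 - beta1**step)
                vhat = v_t[j] / (1 - beta2**step)
                new_params.append(p - lr * mhat / (np.sqrt(vhat) + eps))
            params = new_params
            model.weights = [
                (params[2 * i], params[2 * i + 1]) for i in range(len(model.weights))
            ]
        train_loss = _mae(model.forward(X), Z)
        if not np.isfinite(train_loss):
            raise ArithmeticError(f"training diverged (non-finite loss) at epoch {epoch}")
        history["train"].append(train_loss)
        history["learning_rate"].append(lr)
        if test is not None:
            history["test"].append(_mae(model.forward(test[0]), test[1]))
    model.training_history = history


def fit_mapping(
    X: DesignMatrix,
    Z: np.ndarray,
    family: str = "linear",
    config: TrainingConfig | None = None,
    test: tuple[DesignMatrix, np.ndarray] | None = None,
) -> MappingModel:
    """Fit a metadata→latent regression.

    Parameters
    ----------
    X, Z
        Row-aligned design matrix and ``nodes x d`` latent targets.
    family
        ``"linear"`` — exact minimum-norm least squares of ``Z ≈ [1, X]·B``;
        ``"mlp1"`` — one 200-unit ReLU hidden layer; ``"nn2"`` — two
        250-unit ReLU hidden layers, linear output either way.
    config
        Training protocol for the network families (default
        :class:`TrainingConfig`); ignored for ``"linear"``.
    test
        Optional held-out ``(DesignMatrix, targets)`` whose loss is
        recorded per epoch to monitor overfitting.
    """
    if family not in FAMILIES:
        raise ValueError(f"unknown family {family!r}; expected one of {FAMILIES}")
    Z = _check_xy(X, Z)
    test_arrays = None
    if test is not None:
        Zt = _check_xy(test[0], test[1])
        test_arrays = (test[0].matrix, Zt)
    model = MappingModel(
        family=family,
        weights=[],
        input_encoder=X.encoder_spec,
        output_dim=Z.shape[1],
        config=config if family != "linear" else None,
    )
    if family == "linear":
        design = np.hstack([np.ones((X.matrix.shape[0], 1)), X.matrix])
        B, *_ = np.linalg.lstsq(design, Z, rcond=None)
        model.weights = [(B[1:], B[0])]
        model.training_history = {"train": [_mae(model.forward(X.matrix), Z)]}
        if test_arrays is not None:
            model.training_history["test"] = [
                _mae(model.forward(test_arrays[0]), test_arrays[1])
            ]
    else:
        if config is None:
            config = TrainingConfig()
        model.config = config
        _train_network(model, X.matrix, Z, config, test_arrays)
    return model


def predict_latent(model: MappingModel, table) -> np.ndarray:
    """Predicted ``nodes x d`` latent positions for a metadata table (or an
    already-encoded :class:`DesignMatrix`)."""
    if isinstance(table, DesignMatrix):
        X = table
    elif isinstance(table, NodeMetadataTable):
        X = encode_features(table, model.input_encoder)
    else:
        raise TypeError("expected NodeMetadataTable or DesignMatrix")
    return model.forward(X.matrix)


def evaluate_mapping(model: MappingModel, X: DesignMatrix, Z: np.ndarray) -> dict:
    """Per-cell MAE and MSE of the mapping on aligned data."""
    Z = _check_xy(X, Z)
    if Z.size == 0:
        raise ValueError("empty evaluation input")
    resid = model.forward(X.matrix) - Z
    return {"mae": float(np.abs(resid).mean()), "mse": float((resid**2).mean())}
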