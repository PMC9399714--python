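"""Synthetic bipartite RDPG benchmarks with metadata coupled to latent positions.

The generator draws latent positions whose pairwise dot products are valid
probabilities by construction, samples a binary bipartite graph from
independent Bernoulli trials on those probabilities, and emits per-node
metadata tables that are noisy (linear or quadratic) transforms of the
latent coordinates — optionally discretised into categorical variables by
quantile binning, emulating survey-style data where one side carries only
categorical attributes and the other a categorical/continuous mix.  Every
output is reproducible from the scenario seed alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .graph import BipartiteGraph, NodeMetadataTable

__all__ = [
    "SyntheticScenario",
    "SyntheticTruth",
    "sample_latent_positions",
    "sample_graph",
    "generate_metadata",
    "make_benchmark",
]


@dataclass
class SyntheticScenario:
    """Study conditions for one synthetic benchmark.

    ``metadata_map`` controls how metadata derive from latent coordinates:
    ``"linear"`` applies a seeded full-rank linear map to ``x``;
    ``"quadratic"`` applies it to the elementwise squares ``x²``, making
    the inverse metadata→latent relationship genuinely nonlinear
    (square-root-like).
    ``categorical_spec`` lists ``(source_column, n_bins)`` pairs; each bins
    the given continuous metadata column into equal-frequency classes
    ``c1..ck`` appended as a categorical variable.
    """

    M: int = 100
    N: int = 100
    d_true: int = 2
    metadata_map: str = "linear"
    noise_sd: float = 0.0
    metadata_width: Optional[int] = None  # defaults to d_true
    categorical_spec: list = field(default_factory=list)
    density_target: Optional[float] = None
    seed: int = 0

    def __post_init__(self):
        if not (self.M >= self.d_true >= 1 and self.N >= self.d_true):
            raise ValueError("need M, N >= d_true >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.metadata_map not in ("linear", "quadratic"):
            raise ValueError(f"unknown metadata_map {self.metadata_map!r}")
        for src, bins in self.categorical_spec:
            if bins < 2:
                raise ValueError("categorical bins must be >= 2")

    @property
    def width(self) -> int:
        return self.metadata_width if self.metadata_width is not None else self.d_true


@dataclass
class SyntheticTruth:
    """Ground truth bundle: positions, probability matrix, sampled graph,
    and both metadata tables."""

    X_true: np.ndarray
    Y_true: np.ndarray
    B: np.ndarray
    graph: BipartiteGraph
    row_metadata: NodeMetadataTable
    col_metadata: NodeMetadataTable
    scenario: SyntheticScenario


def sample_latent_positions(
    M: int,
    N: int,
    d: int,
    seed: int = 0,
    density_target: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw latent positions uniform on ``[0, d^{-1/2}]`` per coordinate.

    The upper bound makes every dot product lie in ``[0, 1]`` (each of the
    ``d`` coordinate products is at most ``1/d``).  With
    ``density_target``, both matrices are rescaled by a common factor so
    the mean of ``B = X Yᵀ`` hits the target; the rescale must keep every
    entry of ``B`` within ``[0, 1]``.
    """
    if M < 1 or N < 1 or d < 1:
        raise ValueError("M, N, d must be positive")
    rng = np.random.default_rng(seed)
    hi = d ** -0.5
    X = rng.uniform(0.0, hi, size=(M, d))
    Y = rng.uniform(0.0, hi, size=(N, d))
    if density_target is not None:
        B = X @ Y.T
        mean, peak = float(B.mean()), float(B.max())
        attainable = mean / peak  # largest mean a common rescale can reach
        if not 0 < density_target <= attainable:
            raise ValueError(
                f"density target {density_target} unattainable; attainable "
                f"range is (0, {attainable:.4f}]"
            )
        c = np.sqrt(density_target / mean)
        X, Y = X * c, Y * c
    return X, Y


def sample_graph(X_true: np.ndarray, Y_true: np.ndarray, seed: int = 0) -> BipartiteGraph:
    """Sample each link as an independent Bernoulli(B_ij) trial."""
    B = np.asarray(X_true) @ np.asarray(Y_true).T
    if (B < 0).any() or (B > 1).any():
        raise ValueError("latent positions give probabilities outside [0, 1]")
    rng = np.random.default_rng(seed)
    A = (rng.random(B.shape) < B).astype(np.int8)
    M, N = B.shape
    return BipartiteGraph(
        [f"r{i}" for i in range(M)], [f"c{j}" for j in range(N)], A
    )


def _feature_map(positions: np.ndarray, kind: str) -> np.ndarray:
    if kind == "quadratic":
        # squares only: with the identity block included the latent
        # coordinates stay linearly recoverable from the metadata (the
        # coordinates are nonnegative and short-ranged), which would defeat
        # the purpose of a nonlinear scenario
        return positions**2
    return positions


def generate_metadata(
    positions: np.ndarray,
    scenario: SyntheticScenario,
    side: str = "row",
    node_ids=None,
    W: np.ndarray | None = None,
    b: np.ndarray | None = None,
) -> NodeMetadataTable:
    """Metadata statistically coupled to latent positions.

    Continuous features are ``g(x)·Wᵀ + b`` plus Gaussian noise of scale
    ``scenario.noise_sd``, with ``g`` the identity (linear map) or the
    identity with elementwise squares appended (quadratic map) and ``W`` a
    seeded full-rank matrix with at least ``d_true`` output rows.  Pass
    ``W``/``b`` explicitly to pin the transform (e.g. identity for exact
    recovery fixtures).  Categorical features quantile-bin a designated
    continuous column into classes ``c1..ck``.
    """
    positions = np.asarray(positions, dtype=float)
    if not np.isfinite(positions).all():
        raise ValueError("positions must be finite")
    d = positions.shape[1]
    width = scenario.width
    if width < d:
        raise ValueError(
            f"metadata width {width} < latent dimension {d}: the map cannot "
            "be injective in expectation"
        )
    g = _feature_map(positions, scenario.metadata_map)
    seed_seq = np.random.SeedSequence([scenario.seed, {"row": 1, "col": 2}[side]])
    rng = np.random.default_rng(seed_seq)
    if W is None:
        while True:
            W = rng.standard_normal((width, g.shape[1]))
            if np.linalg.matrix_rank(W) == min(W.shape):
                break
    if b is None:
        b = np.zeros(width)
    cont = g @ np.asarray(W, dtype=float).T + np.asarray(b, dtype=float)
    if scenario.noise_sd > 0:
        cont = cont + rng.normal(0.0, scenario.noise_sd, size=cont.shape)
    columns = {f"f{k + 1}": cont[:, k] for k in range(cont.shape[1])}
    schema = {name: "continuous" for name in columns}
    df = pd.DataFrame(columns)
    for i, (src, bins) in enumerate(scenario.categorical_spec):
        source = df[f"f{src + 1}"]
        name = f"cat{i + 1}"
        df[name] = pd.qcut(
            source.rank(method="first"), bins, labels=[f"c{k + 1}" for k in range(bins)]
        ).astype(str)
        schema[name] = "categorical"
    if node_ids is None:
        prefix = "r" if side == "row" else "c"
        node_ids = [f"{prefix}{i}" for i in range(positions.shape[0])]
    return NodeMetadataTable(node_ids, df, schema)


def make_benchmark(scenario: SyntheticScenario) -> SyntheticTruth:
    """Full reproducible bundle: positions, ``B``, sampled graph, metadata."""
    ss = np.random.SeedSequence(scenario.seed)
    pos_seed, graph_seed = [int(s) for s in ss.generate_state(2) >> np.uint32(1)]
    X, Y = sample_latent_positions(
        scenario.M, scenario.N, scenario.d_true, seed=pos_seed,
        density_target=scenario.density_target,
    )
    B = X @ Y.T
    graph = sample_graph(X, Y, seed=graph_seed)
    row_md = generate_metadata(X, scenario, side="row", node_ids=graph.row_ids)
    col_md = generate_metadata(Y, scenario, side="col", node_ids=graph.col_ids)
    return SyntheticTruth(X, Y, B, graph, row_md, col_md, scenario)
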