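"""Model/Results interface for metadata-driven bipartite link prediction.

:class:`RdpgLinkPredictor` bundles the full procedure: split the observed
graph (holding out whole nodes for cold-start validation), embed the
training adjacency by truncated SVD, regress encoded node metadata onto
the latent positions on a model-training node split (monitored on a
model-test split), and score every validation block by clipped dot
products.  ``fit()`` returns an :class:`RdpgLinkResults` carrying the
embedding, the fitted mappings, per-block scores, evaluation reports and
a ``summary()`` table.
"""

from __future__ import annotations

import numpy as np

from .embedding import LatentEmbedding, ase, scree, select_dimension
from .evaluation import EvaluationReport, ScoredLinks, auc, bootstrap_auc_ci
from .graph import BipartiteGraph, NodeMetadataTable, encode_features
from .linkpred import ProbabilityMatrix, predict_matrix
from .mapping import MappingModel, TrainingConfig, evaluate_mapping, fit_mapping, predict_latent
from .split import BLOCKS, SplitResult, SplitSpec, split_dataset

__all__ = ["RdpgLinkPredictor", "RdpgLinkResults"]


class RdpgLinkPredictor:
    """Random-dot-product-graph link predictor with metadata cold start.

    Parameters
    ----------
    graph
        The observed bipartite graph.
    row_metadata, col_metadata
        Per-side metadata tables covering every node of the graph.
    split_spec
        Node/edge holdout specification (defaults mirror a 70/30 edge
        split with 15% of nodes per side held out as new and a 50/50
        model-train/model-test node split).
    d
        Latent dimension; ``None`` selects it on the training adjacency's
        scree by the profile-likelihood elbow.
    family
        Mapping family for both sides, or a ``(row, col)`` pair from
        ``{"linear", "mlp1", "nn2"}``.
    training_config
        Network training protocol (ignored by the linear family).
    """

    def __init__(
        self,
        graph: BipartiteGraph,
        row_metadata: NodeMetadataTable,
        col_metadata: NodeMetadataTable,
        split_spec: SplitSpec | None = None,
        d: int | None = None,
        family="linear",
        training_config: TrainingConfig | None = None,
    ):
        self.graph = graph
        self.row_metadata = row_metadata
        self.col_metadata = col_metadata
        self.split_spec = split_spec or SplitSpec()
        self.d = d
        if isinstance(family, str):
            family = (family, family)
        self.family = tuple(family)
        self.training_config = training_config

    @classmethod
    def from_benchmark(cls, truth, **kwargs) -> "RdpgLinkPredictor":
        """Build from a :class:`~rdpglink.synthetic.SyntheticTruth` bundle."""
        return cls(truth.graph, truth.row_metadata, truth.col_metadata, **kwargs)

    def _fit_side(
        self,
        metadata: NodeMetadataTable,
        embedding_ids: list,
        positions: np.ndarray,
        model_train: list,
        model_test: list,
        family: str,
    ) -> MappingModel:
        pos_of = {n: i for i, n in enumerate(embedding_ids)}
        X_train = encode_features(metadata.subset(model_train))
        Z_train = positions[[pos_of[n] for n in model_train]]
        test = None
        if model_test:
            X_test = encode_features(metadata.subset(model_test), X_train.encoder_spec)
            Z_test = positions[[pos_of[n] for n in model_test]]
            test = (X_test, Z_test)
        return fit_mapping(X_train, Z_train, family, self.training_config, test=test)

    def fit(self) -> "RdpgLinkResults":
        split = split_dataset(self.graph, self.split_spec)
        scree_summary = scree(split.training_graph)
        d = self.d or select_dimension(scree_summary.singular_values)
        embedding = ase(split.training_graph, d)
        row_mapping = self._fit_side(
            self.row_metadata, embedding.row_ids, embedding.row_positions,
            split.row_model_train, split.row_model_test, self.family[0],
        )
        col_mapping = self._fit_side(
            self.col_metadata, embedding.col_ids, embedding.col_positions,
            split.col_model_train, split.col_model_test, self.family[1],
        )
        return RdpgLinkResults(
            self, split, scree_summary, embedding, d, row_mapping, col_mapping,
            d_was_selected=self.d is None,
        )


class RdpgLinkResults:
    """Fitted link-prediction procedure: embedding, mappings, scores."""

    def __init__(
        self,
        model: RdpgLinkPredictor,
        split: SplitResult,
        scree_summary,
        embedding: LatentEmbedding,
        d: int,
        row_mapping: MappingModel,
        col_mapping: MappingModel,
        d_was_selected: bool = False,
    ):
        self.model = model
        self.split = split
        self.scree = scree_summary
        self.embedding = embedding
        self.d = d
        self.row_mapping = row_mapping
        self.col_mapping = col_mapping
        self.d_was_selected = d_was_selected
        self._position_cache: dict = {}

    # -- positions ---------------------------------------------------------

    def positions(self, side: str, kind: str) -> tuple[list, np.ndarray]:
        """Latent positions for one side.

        ``kind="obs"`` returns the SVD-estimated positions of observed
        nodes; ``kind="new"`` returns metadata-predicted positions of the
        held-out new nodes.
        """
        key = (side, kind)
        if key in self._position_cache:
            return self._position_cache[key]
        if side == "row":
            meta, mapping = self.model.row_metadata, self.row_mapping
            obs_ids, pos = self.embedding.row_ids, self.embedding.row_positions
            new_ids = self.split.row_new
        else:
            meta, mapping = self.model.col_metadata, self.col_mapping
            obs_ids, pos = self.embedding.col_ids, self.embedding.col_positions
            new_ids = self.split.col_new
        if kind == "obs":
            out = (obs_ids, pos)
        else:
            out = (new_ids, predict_latent(mapping, meta.subset(new_ids)))
        self._position_cache[key] = out
        return out

    # -- probabilities and scoring ----------------------------------------

    def block_probabilities(self, block: str) -> ProbabilityMatrix:
        """Clipped dot-product probabilities for one validation block.

        Observed sides use SVD positions, new sides use metadata-predicted
        positions (``obs_obs`` = SVD×SVD … ``new_new`` = predicted×predicted).
        """
        if block not in BLOCKS:
            raise ValueError(f"unknown block {block!r}; expected one of {BLOCKS}")
        rkind = "obs" if block.startswith("obs") else "new"
        ckind = "obs" if block.endswith("obs") else "new"
        row_ids, X = self.positions("row", rkind)
        col_ids, Y = self.positions("col", ckind)
        prov = {"obs": "svd", "new": "metadata"}
        return predict_matrix(
            X, Y, row_ids, col_ids, provenance=(prov[rkind], prov[ckind])
        )

    def score_block(self, block: str) -> ScoredLinks:
        """All evaluable pairs of a block with observed 0/1 labels.

        For ``obs_obs`` the pairs already present as training edges are
        excluded (they are known links, not predictions); the other
        blocks score every pair.
        """
        probs = self.block_probabilities(block)
        src = self.split.source_graph
        ridx = {r: i for i, r in enumerate(src.row_ids)}
        cidx = {c: j for j, c in enumerate(src.col_ids)}
        A = src.toarray()
        labels = A[np.ix_([ridx[r] for r in probs.row_ids],
                          [cidx[c] for c in probs.col_ids])]
        mask = np.ones_like(labels, dtype=bool)
        if block == "obs_obs":
            mask = ~self.split.training_graph.toarray().astype(bool)
        rows, cols = np.nonzero(mask)
        pair_ids = [(probs.row_ids[i], probs.col_ids[j]) for i, j in zip(rows, cols)]
        return ScoredLinks(probs.values[mask], labels[mask], pair_ids)

    def pooled_scores(self, blocks=BLOCKS) -> ScoredLinks:
        return ScoredLinks.concat([self.score_block(b) for b in blocks])

    def block_auc(self, block: str) -> float:
        return auc(self.score_block(block))

    def evaluate(
        self,
        blocks=BLOCKS,
        n_sample: int = 1000,
        n_boot: int = 2000,
        level: float = 0.95,
        threshold: float = 0.5,
        seed: int = 0,
    ) -> EvaluationReport:
        """Pooled evaluation with the subsample + stratified-bootstrap CI."""
        return bootstrap_auc_ci(
            self.pooled_scores(blocks), n_sample=n_sample, n_boot=n_boot,
            level=level, seed=seed, threshold=threshold,
        )

    # -- diagnostics -------------------------------------------------------

    def mapping_metrics(self) -> dict:
        """Per-side model-train / model-test MAE and MSE of the mappings."""
        out = {}
        for side, mapping, meta, ids_pos in (
            ("row", self.row_mapping, self.model.row_metadata,
             (self.embedding.row_ids, self.embedding.row_positions)),
            ("col", self.col_mapping, self.model.col_metadata,
             (self.embedding.col_ids, self.embedding.col_positions)),
        ):
            pos_of = {n: i for i, n in enumerate(ids_pos[0])}
            metrics = {}
            for part, nodes in (
                ("train", getattr(self.split, f"{side}_model_train")),
                ("test", getattr(self.split, f"{side}_model_test")),
            ):
                X = encode_features(meta.subset(nodes), mapping.input_encoder)
                Z = ids_pos[1][[pos_of[n] for n in nodes]]
                metrics[part] = evaluate_mapping(mapping, X, Z)
            out[side] = metrics
        return out

    def summary(self) -> str:
        """Plain-text overview in the style of a regression results table."""
        g = self.split.source_graph
        tg = self.split.training_graph
        lines = [
            "RDPG link prediction results",
            "=" * 64,
            f"graph: {g.shape[0]} x {g.shape[1]} nodes, {g.n_edges} links",
            f"training graph: {tg.shape[0]} x {tg.shape[1]} nodes, {tg.n_edges} links",
            f"new nodes held out: {len(self.split.row_new)} rows, "
            f"{len(self.split.col_new)} cols",
            f"latent dimension d = {self.d} "
            f"({'profile-likelihood elbow' if self.d_was_selected else 'fixed'})",
            f"top singular values: "
            + ", ".join(f"{s:.3f}" for s in self.embedding.singular_values[:6]),
            f"mapping family: row={self.row_mapping.family}, "
            f"col={self.col_mapping.family}",
            "-" * 64,
            "mapping MAE (model-train / model-test):",
        ]
        mm = self.mapping_metrics()
        for side in ("row", "col"):
            lines.append(
                f"  {side}: {mm[side]['train']['mae']:.4f} / "
                f"{mm[side]['test']['mae']:.4f}"
            )
        lines.append("-" * 64)
        lines.append("validation blocks (pairs scored / links held out / AUC):")
        for block in BLOCKS:
            sc = self.score_block(block)
            n_pos = int(sc.labels.sum())
            try:
                a = f"{auc(sc):.4f}"
            except ValueError:
                a = "n/a"
            lines.append(f"  {block:8s}: {len(sc):7d} / {n_pos:6d} / {a}")
        return "\n".join(lines)
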