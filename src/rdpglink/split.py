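"""Training/validation splitting with genuine cold-start holdout.

A fraction of nodes on each side is removed from the network entirely —
every one of their edges goes to validation, so they are "new" nodes seen
only through metadata.  Edges among the remaining observed nodes are then
split Bernoulli(train_edge_fraction) into the training graph and the
observed×observed validation set.  Finally the training-graph nodes on
each side are partitioned into model-training and model-test lists used
to fit and monitor the metadata→latent regressions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .graph import BipartiteGraph

__all__ = ["SplitSpec", "SplitResult", "split_dataset", "BLOCKS"]

BLOCKS = ("obs_obs", "new_obs", "obs_new", "new_new")


@dataclass
class SplitSpec:
    train_edge_fraction: float = 0.70
    new_row_fraction: float = 0.15
    new_col_fraction: float = 0.15
    model_train_fraction: float = 0.50
    seed: int = 0

    def __post_init__(self):
        for name in ("train_edge_fraction", "model_train_fraction"):
            if not 0 < getattr(self, name) <= 1:
                raise ValueError(f"{name} must be in (0, 1]")
        for name in ("new_row_fraction", "new_col_fraction"):
            if not 0 <= getattr(self, name) < 1:
                raise ValueError(f"{name} must be in [0, 1)")


@dataclass
class SplitResult:
    training_graph: BipartiteGraph
    row_observed: list
    row_new: list
    col_observed: list
    col_new: list
    row_model_train: list
    row_model_test: list
    col_model_train: list
    col_model_test: list
    validation_edges: dict  # block -> list of (row_id, col_id) held-out links
    spec: SplitSpec
    source_graph: BipartiteGraph = field(repr=False, default=None)

    @property
    def n_validation_links(self) -> int:
        return sum(len(v) for v in self.validation_edges.values())

    def block_ids(self, block: str) -> tuple[list, list]:
        """Row/col id lists spanned by a validation block."""
        rows = self.row_observed if block.startswith("obs") else self.row_new
        cols = self.col_observed if block.endswith("obs") else self.col_new
        return rows, cols


def _holdout(ids: list, fraction: float, rng: np.random.Generator) -> tuple[list, list]:
    n_new = int(np.floor(fraction * len(ids)))
    new_idx = set(rng.choice(len(ids), size=n_new, replace=False).tolist())
    observed = [x for i, x in enumerate(ids) if i not in new_idx]
    new = [x for i, x in enumerate(ids) if i in new_idx]
    return observed, new


def _partition(ids: list, fraction: float, rng: np.random.Generator) -> tuple[list, list]:
    perm = rng.permutation(len(ids))
    k = int(np.floor(fraction * len(ids)))
    train = sorted(perm[:k].tolist())
    test = sorted(perm[k:].tolist())
    return [ids[i] for i in train], [ids[i] for i in test]


def split_dataset(graph: BipartiteGraph, spec: SplitSpec) -> SplitResult:
    """Partition a bipartite graph per the cold-start evaluation protocol.

    Every original edge lands in exactly one of training/validation; new
    nodes never appear in the training graph; held-out observed×observed
    edges appear as zeros in the training adjacency (which biases its
    density slightly downward — the standard link-prediction convention).
    """
    rng = np.random.default_rng(spec.seed)
    row_obs, row_new = _holdout(graph.row_ids, spec.new_row_fraction, rng)
    col_obs, col_new = _holdout(graph.col_ids, spec.new_col_fraction, rng)
    if len(row_obs) < 2 or len(col_obs) < 2:
        raise ValueError("fewer than 2 observed nodes on a side after holdout")

    A = graph.toarray()
    ridx = {r: i for i, r in enumerate(graph.row_ids)}
    cidx = {c: j for j, c in enumerate(graph.col_ids)}
    obs_r = [ridx[r] for r in row_obs]
    obs_c = [cidx[c] for c in col_obs]
    A_obs = A[np.ix_(obs_r, obs_c)]
    keep = rng.random(A_obs.shape) < spec.train_edge_fraction
    A_train = (A_obs.astype(bool) & keep).astype(np.int8)

    validation_edges = {b: [] for b in BLOCKS}
    heldout = A_obs.astype(bool) & ~keep
    for i, j in zip(*np.nonzero(heldout)):
        validation_edges["obs_obs"].append((row_obs[i], col_obs[j]))
    new_r = [ridx[r] for r in row_new]
    new_c = [cidx[c] for c in col_new]
    for i, j in zip(*np.nonzero(A[np.ix_(new_r, obs_c)])):
        validation_edges["new_obs"].append((row_new[i], col_obs[j]))
    for i, j in zip(*np.nonzero(A[np.ix_(obs_r, new_c)])):
        validation_edges["obs_new"].append((row_obs[i], col_new[j]))
    for i, j in zip(*np.nonzero(A[np.ix_(new_r, new_c)])):
        validation_edges["new_new"].append((row_new[i], col_new[j]))

    training_graph = BipartiteGraph(row_obs, col_obs, A_train)
    row_mt, row_ms = _partition(row_obs, spec.model_train_fraction, rng)
    col_mt, col_ms = _partition(col_obs, spec.model_train_fraction, rng)
    return SplitResult(
        training_graph=training_graph,
        row_observed=row_obs,
        row_new=row_new,
        col_observed=col_obs,
        col_new=col_new,
        row_model_train=row_mt,
        row_model_test=row_ms,
        col_model_train=col_mt,
        col_model_test=col_ms,
        validation_edges=validation_edges,
        spec=spec,
        source_graph=graph,
    )
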