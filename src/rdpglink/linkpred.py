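"""Interaction probabilities from latent positions.

Under the random dot product graph model the probability that a row node
with latent position ``x`` links to a column node with position ``y`` is
``x·y``; estimated positions can push the product outside ``[0, 1]``, so
values below zero are treated as zero and values above one as one.
Clipping applies to probabilities only — latent coordinates are never
clipped.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterator

import numpy as np

from .mapping import MappingModel, predict_latent

__all__ = ["ProbabilityMatrix", "predict_matrix", "predict_new_node", "iter_blocks"]


@dataclass
class ProbabilityMatrix:
    row_ids: list
    col_ids: list
    values: np.ndarray  # rows x cols, all in [0, 1]
    provenance: tuple[str, str] = ("unknown", "unknown")  # per-side position source

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.row_ids), len(self.col_ids)):
            raise ValueError("probability matrix shape does not match id lists")
        if (self.values < 0).any() or (self.values > 1).any():
            raise ValueError("probabilities must lie in [0, 1]")

    def write_tsv(self, path, top_k: int | None = None) -> None:
        """Sparse (row_id, col_id, probability) export; ``top_k`` keeps only
        the k most probable partners per row."""
        with open(path, "w") as fh:
            fh.write("row_id\tcol_id\tprobability\n")
            for i, rid in enumerate(self.row_ids):
                row = self.values[i]
                order = np.argsort(row)[::-1]
                if top_k is not None:
                    order = order[:top_k]
                for j in order:
                    fh.write(f"{rid}\t{self.col_ids[j]}\t{row[j]:.10g}\n")

    def write_mm(self, path) -> None:
        from scipy.io import mmwrite

        mmwrite(str(path), self.values)
        base = Path(path).with_suffix("")
        base.with_suffix(".rows.txt").write_text("".join(f"{r}\n" for r in self.row_ids))
        base.with_suffix(".cols.txt").write_text("".join(f"{c}\n" for c in self.col_ids))


def _clip01(values: np.ndarray) -> np.ndarray:
    return np.clip(values, 0.0, 1.0)


def predict_matrix(
    row_positions: np.ndarray,
    col_positions: np.ndarray,
    row_ids=None,
    col_ids=None,
    provenance: tuple[str, str] = ("unknown", "unknown"),
) -> ProbabilityMatrix:
    """Clipped dot-product probabilities for every row×column pair.

    Both sides must share the latent dimension ``d`` for the products to be
    meaningful.
    """
    X = np.atleast_2d(np.asarray(row_positions, dtype=float))
    Y = np.atleast_2d(np.asarray(col_positions, dtype=float))
    if X.shape[1] != Y.shape[1]:
        raise ValueError(
            f"latent spaces must be equidimensional: row d={X.shape[1]} vs "
            f"col d={Y.shape[1]}"
        )
    if row_ids is None:
        row_ids = list(range(X.shape[0]))
    if col_ids is None:
        col_ids = list(range(Y.shape[0]))
    return ProbabilityMatrix(list(row_ids), list(col_ids), _clip01(X @ Y.T), provenance)


def iter_blocks(
    row_positions: np.ndarray, col_positions: np.ndarray, block_size: int = 1024
) -> Iterator[np.ndarray]:
    """Stream the clipped probability matrix in row blocks.

    Concatenating the yielded blocks equals the dense result of
    :func:`predict_matrix`; memory use stays at ``block_size x N``.
    """
    X = np.asarray(row_positions, dtype=float)
    Y = np.asarray(col_positions, dtype=float)
    if X.shape[1] != Y.shape[1]:
        raise ValueError("latent spaces must be equidimensional")
    for start in range(0, X.shape[0], block_size):
        yield _clip01(X[start : start + block_size] @ Y.T)


def predict_new_node(
    model: MappingModel, metadata_row, opposite_positions: np.ndarray
) -> np.ndarray:
    """Cold-start prediction: probability vector of a brand-new node
    against ``K`` nodes of the opposite side.

    The node's metadata is mapped into the latent space by the fitted
    regression and dotted with the opposite side's positions — identical
    to a 1-row :func:`predict_matrix`.
    """
    pos = predict_latent(model, metadata_row)
    result = predict_matrix(pos, opposite_positions)
    return result.values[0]
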