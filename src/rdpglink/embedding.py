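"""Adjacency spectral embedding for bipartite graphs.

The truncated SVD ``A ≈ L̂ Σ̂ R̂ᵀ`` splits the square roots of the top ``d``
singular values between the two sides, giving row positions ``L̂ Σ̂^{1/2}``
and column positions ``R̂ Σ̂^{1/2}`` whose dot products estimate the
interaction probabilities of a random dot product graph.  The retained
dimension is chosen automatically with the Zhu–Ghodsi profile-likelihood
elbow on the scree of singular values.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .graph import BipartiteGraph

__all__ = ["LatentEmbedding", "ScreeSummary", "ase", "scree", "select_dimension"]

# below this size a dense LAPACK SVD is faster and exact; above it we use
# the iterative sparse solver
_DENSE_LIMIT = 500


@dataclass
class LatentEmbedding:
    """Latent positions for both sides plus the retained singular values."""

    row_ids: list
    col_ids: list
    row_positions: np.ndarray  # M x d
    col_positions: np.ndarray  # N x d
    singular_values: np.ndarray  # length d, non-increasing

    def __post_init__(self):
        sv = np.asarray(self.singular_values, dtype=float)
        if (sv < -1e-12).any() or (np.diff(sv) > 1e-9).any():
            raise ValueError("singular values must be non-negative and non-increasing")
        self.singular_values = sv

    @property
    def d(self) -> int:
        return self.row_positions.shape[1]

    def save(self, prefix) -> None:
        """Write row/col position CSVs plus a JSON sidecar."""
        prefix = Path(prefix)
        cols = [f"ld_{k + 1}" for k in range(self.d)]
        for side, ids, pos in (
            ("rows", self.row_ids, self.row_positions),
            ("cols", self.col_ids, self.col_positions),
        ):
            df = pd.DataFrame(pos, columns=cols)
            df.insert(0, "node_id", ids)
            df.to_csv(prefix.with_suffix(f".{side}.csv"), index=False)
        sidecar = {
            "d": self.d,
            "singular_values": self.singular_values.tolist(),
            "sign_convention": "largest-|entry| of each left singular vector positive",
        }
        prefix.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))

    @classmethod
    def load(cls, prefix) -> "LatentEmbedding":
        prefix = Path(prefix)
        rows = pd.read_csv(prefix.with_suffix(".rows.csv"))
        cols = pd.read_csv(prefix.with_suffix(".cols.csv"))
        meta = json.loads(prefix.with_suffix(".json").read_text())
        return cls(
            rows["node_id"].tolist(),
            cols["node_id"].tolist(),
            rows.iloc[:, 1:].to_numpy(),
            cols.iloc[:, 1:].to_numpy(),
            np.asarray(meta["singular_values"]),
        )


@dataclass
class ScreeSummary:
    singular_values: np.ndarray
    cumulative_energy: np.ndarray  # squared-share by default
    squared: bool = True

    def select(self, d_max: int | None = None) -> int:
        return select_dimension(self.singular_values, d_max=d_max)

    def plot(self, ax=None, chosen: int | None = None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        idx = np.arange(1, len(self.singular_values) + 1)
        ax.plot(idx, self.singular_values, "o-", label="singular values")
        ax2 = ax.twinx()
        ax2.plot(idx, 100 * self.cumulative_energy, "s--", color="grey",
                 label="% variability")
        if chosen is not None:
            ax.axvline(chosen, color="red", linestyle=":")
        ax.set_xlabel("singular value index")
        ax.set_ylabel("singular value")
        ax2.set_ylabel("% variability explained")
        return ax


def _canonical_signs(L: np.ndarray, R: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    # SVD is unique only up to paired sign flips; make the largest-|entry|
    # coordinate of each left vector positive so output is deterministic.
    for k in range(L.shape[1]):
        j = int(np.argmax(np.abs(L[:, k])))
        if L[j, k] < 0:
            L[:, k] = -L[:, k]
            R[:, k] = -R[:, k]
    return L, R


def ase(graph: BipartiteGraph, d: int) -> LatentEmbedding:
    """Adjacency spectral embedding at dimension *d*.

    Returns positions ``L̂·diag(√σ)`` and ``R̂·diag(√σ)`` whose product is the
    Frobenius-optimal rank-``d`` approximation of the adjacency matrix.
    """
    M, N = graph.shape
    S = min(M, N)
    if not 1 <= d <= S:
        raise ValueError(f"d={d} out of range [1, {S}]")
    A = graph.adjacency
    use_dense = max(M, N) < _DENSE_LIMIT or d >= S - 1
    if use_dense:
        Ad = graph.toarray().astype(float)
        L, s_all, Rt = np.linalg.svd(Ad, full_matrices=False)
        L, s, R = L[:, :d], s_all[:d], Rt[:d].T
        boundary = s_all[d] if d < len(s_all) else None
    else:
        Af = sp.csr_matrix(A, dtype=float)
        k = min(d + 1, S - 1)  # one extra value to detect boundary ties
        L, s_all, Rt = spla.svds(Af, k=k, tol=1e-10, random_state=0)
        order = np.argsort(s_all)[::-1]
        L, s_all, Rt = L[:, order], s_all[order], Rt[order]
        L, s, R = L[:, :d], s_all[:d], Rt[:d].T
        boundary = s_all[d] if d < len(s_all) else None
    if boundary is not None and abs(s[d - 1] - boundary) <= 1e-12 * max(1.0, s[0]):
        warnings.warn(
            "tied singular values at the truncation boundary; the retained "
            "subspace is not unique", RuntimeWarning,
        )
    L, R = _canonical_signs(L, R)
    root = np.sqrt(np.maximum(s, 0.0))
    return LatentEmbedding(
        list(graph.row_ids), list(graph.col_ids), L * root, R * root, s
    )


def scree(graph: BipartiteGraph, squared: bool = True) -> ScreeSummary:
    """All singular values of the adjacency, with cumulative explained share.

    ``squared=True`` (default) reports cumulative squared singular values
    over total squared — the Frobenius-energy share; ``squared=False`` uses
    the unsquared cumulative share.
    """
    s = np.linalg.svd(graph.toarray().astype(float), compute_uv=False)
    weights = s**2 if squared else s
    total = weights.sum()
    if total == 0:
        energy = np.ones_like(weights)
    else:
        energy = np.cumsum(weights) / total
    return ScreeSummary(s, energy, squared=squared)


def select_dimension(singular_values, d_max: int | None = None) -> int:
    """Zhu–Ghodsi profile-likelihood elbow.

    For each split point ``q`` the ordered values are modelled as two
    Gaussian groups sharing a pooled variance (denominator ``p - 2``,
    floored at ``1e-12·max σ²``); the returned dimension maximises the
    resulting log-likelihood, smallest ``q`` winning ties.
    """
    sv = np.asarray(singular_values, dtype=float)
    if sv.ndim != 1 or len(sv) < 2:
        raise ValueError("need at least two singular values")
    if not np.isfinite(sv).all() or (sv < 0).any():
        raise ValueError("singular values must be finite and non-negative")
    p = len(sv)
    q_hi = p - 1 if d_max is None else min(d_max, p - 1)
    floor = max(1e-12 * float(sv.max()) ** 2, np.finfo(float).tiny)
    best_q, best_ll = 1, -np.inf
    for q in range(1, q_hi + 1):
        g1, g2 = sv[:q], sv[q:]
        mu1, mu2 = g1.mean(), g2.mean()
        ss = ((g1 - mu1) ** 2).sum() + ((g2 - mu2) ** 2).sum()
        var = max(ss / max(p - 2, 1), floor)
        ll = -0.5 * p * np.log(2 * np.pi * var) - 0.5 * ss / var
        if ll > best_ll:  # strict: smallest q wins exact ties
            best_q, best_ll = q, ll
    return best_q
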