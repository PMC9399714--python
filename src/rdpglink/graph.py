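"""Bipartite graph and node-metadata containers.

A bipartite graph ``G(V, P, E)`` couples two disjoint node sets — rows
(e.g. visitors, pollinators) and columns (e.g. places, plants) — through a
binary ``M x N`` adjacency matrix ``A``.  Node metadata live in per-side
tables of mixed categorical/continuous variables; :func:`encode_features`
turns a table into the numeric design matrix fed to the latent-position
regressions (full one-hot for categoricals, centred/scaled columns for
continuous variables), with an encoder spec that can be re-applied
bit-identically to brand-new nodes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
import yaml

__all__ = [
    "BipartiteGraph",
    "NodeMetadataTable",
    "DesignMatrix",
    "EncoderSpec",
    "read_edge_list",
    "write_adjacency",
    "read_adjacency",
    "encode_features",
]


def _as_binary(adjacency, context: str = "adjacency"):
    """Validate that a dense/sparse matrix is strictly 0/1."""
    if sp.issparse(adjacency):
        data = adjacency.tocoo()
        bad = (data.data != 0) & (data.data != 1)
        if bad.any():
            coords = list(zip(data.row[bad][:10].tolist(), data.col[bad][:10].tolist()))
            raise ValueError(f"non-binary entries in {context} at coordinates {coords}")
        return adjacency.tocsr().astype(np.int8)
    arr = np.asarray(adjacency)
    bad = (arr != 0) & (arr != 1)
    if bad.any():
        coords = list(zip(*[c[:10].tolist() for c in np.nonzero(bad)]))
        raise ValueError(f"non-binary entries in {context} at coordinates {coords}")
    return arr.astype(np.int8)


@dataclass
class BipartiteGraph:
    """Two ordered node-id lists plus a binary ``M x N`` adjacency.

    ``adjacency`` may be dense (numpy) or sparse (scipy CSR); every entry
    is validated to be 0 or 1 and the id lists must be duplicate-free.
    """

    row_ids: list
    col_ids: list
    adjacency: object  # np.ndarray or scipy.sparse matrix

    def __post_init__(self):
        self.row_ids = list(self.row_ids)
        self.col_ids = list(self.col_ids)
        if len(set(self.row_ids)) != len(self.row_ids):
            raise ValueError("duplicate row node ids")
        if len(set(self.col_ids)) != len(self.col_ids):
            raise ValueError("duplicate column node ids")
        self.adjacency = _as_binary(self.adjacency)
        if self.shape != (len(self.row_ids), len(self.col_ids)):
            raise ValueError(
                f"adjacency shape {self.shape} does not match id counts "
                f"({len(self.row_ids)}, {len(self.col_ids)})"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return tuple(self.adjacency.shape)

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum())

    def toarray(self) -> np.ndarray:
        if sp.issparse(self.adjacency):
            return self.adjacency.toarray()
        return np.asarray(self.adjacency)

    def subgraph(self, row_ids: Sequence, col_ids: Sequence) -> "BipartiteGraph":
        """Induced subgraph on the given node ids (kept in the given order)."""
        ridx = [self.row_ids.index(r) for r in row_ids]
        cidx = [self.col_ids.index(c) for c in col_ids]
        A = self.toarray()[np.ix_(ridx, cidx)]
        return BipartiteGraph(list(row_ids), list(col_ids), A)

    def edges(self) -> list[tuple]:
        rows, cols = np.nonzero(self.toarray())
        return [(self.row_ids[i], self.col_ids[j]) for i, j in zip(rows, cols)]


def read_edge_list(path, sep: str = "\t", header: bool = False) -> BipartiteGraph:
    """Read a TSV edge list (row_id, col_id[, weight in {0,1}]).

    Node order is first-occurrence order; duplicate edges collapse to a
    single 1.  A third column, when present, must be 0 or 1: rows with 0
    register both nodes without adding the edge.
    """
    path = Path(path)
    row_index: dict = {}
    col_index: dict = {}
    edges: set[tuple[int, int]] = set()
    with open(path) as fh:
        lines = fh.read().splitlines()
    if header:
        lines = lines[1:]
    n_seen = 0
    for lineno, line in enumerate(lines, start=2 if header else 1):
        if not line.strip():
            continue
        parts = line.split(sep)
        if len(parts) < 2 or not parts[0].strip() or not parts[1].strip():
            raise ValueError(f"{path}: malformed edge-list line {lineno}: {line!r}")
        rid, cid = parts[0].strip(), parts[1].strip()
        keep = True
        if len(parts) >= 3 and parts[2].strip() != "":
            w = parts[2].strip()
            if w not in ("0", "1"):
                raise ValueError(
                    f"{path}: line {lineno}: weight must be 0 or 1, got {w!r}"
                )
            keep = w == "1"
        ri = row_index.setdefault(rid, len(row_index))
        ci = col_index.setdefault(cid, len(col_index))
        if keep:
            edges.add((ri, ci))
        n_seen += 1
    if n_seen == 0:
        raise ValueError(f"{path}: empty edge list")
    A = np.zeros((len(row_index), len(col_index)), dtype=np.int8)
    for ri, ci in edges:
        A[ri, ci] = 1
    return BipartiteGraph(list(row_index), list(col_index), A)


def write_adjacency(graph: BipartiteGraph, path) -> None:
    """Write a graph as Matrix Market coordinate + companion id files,
    or as a dense TSV when *path* ends in ``.tsv``.

    For ``foo.mtx`` the node ids go to ``foo.rows.txt`` / ``foo.cols.txt``
    (one id per line, file order = matrix order).
    """
    path = Path(path)
    if path.suffix == ".tsv":
        df = pd.DataFrame(graph.toarray(), index=graph.row_ids, columns=graph.col_ids)
        df.to_csv(path, sep="\t")
        return
    from scipy.io import mmwrite

    mmwrite(str(path), sp.coo_matrix(graph.toarray()), field="integer")
    base = path.with_suffix("")
    base.with_suffix(".rows.txt").write_text("".join(f"{r}\n" for r in graph.row_ids))
    base.with_suffix(".cols.txt").write_text("".join(f"{c}\n" for c in graph.col_ids))


def read_adjacency(path) -> BipartiteGraph:
    """Inverse of :func:`write_adjacency`; rejects non-binary entries."""
    path = Path(path)
    if path.suffix == ".tsv":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return BipartiteGraph(list(df.index), list(df.columns), df.to_numpy())
    from scipy.io import mmread

    A = mmread(str(path))
    base = path.with_suffix("")
    row_ids = base.with_suffix(".rows.txt").read_text().splitlines()
    col_ids = base.with_suffix(".cols.txt").read_text().splitlines()
    return BipartiteGraph(row_ids, col_ids, _as_binary(A, context=str(path)))


# ---------------------------------------------------------------------------
# metadata


@dataclass
class NodeMetadataTable:
    """Per-node metadata with a declared categorical/continuous schema."""

    node_ids: list
    data: pd.DataFrame  # index ignored; rows aligned with node_ids
    schema: dict  # column -> "categorical" | "continuous"

    def __post_init__(self):
        self.node_ids = list(self.node_ids)
        if len(set(self.node_ids)) != len(self.node_ids):
            raise ValueError("duplicate node ids in metadata table")
        if len(self.data) != len(self.node_ids):
            raise ValueError("metadata row count does not match node ids")
        unknown = set(self.schema) - set(self.data.columns)
        if unknown:
            raise ValueError(f"schema names absent columns: {sorted(unknown)}")
        for col, kind in self.schema.items():
            if kind not in ("categorical", "continuous"):
                raise ValueError(f"column {col!r}: unknown kind {kind!r}")
            if kind == "continuous":
                vals = pd.to_numeric(self.data[col], errors="coerce")
                if not np.isfinite(vals.to_numpy(dtype=float)).all():
                    raise ValueError(f"column {col!r}: non-finite continuous values")

    @classmethod
    def from_csv(cls, path, schema) -> "NodeMetadataTable":
        """Load CSV (first column = node id) with *schema* a mapping or a
        YAML/JSON file declaring each column categorical/continuous."""
        df = pd.read_csv(path)
        if not isinstance(schema, Mapping):
            text = Path(schema).read_text()
            schema = yaml.safe_load(text)
        ids = df.iloc[:, 0].tolist()
        return cls(ids, df.iloc[:, 1:].reset_index(drop=True), dict(schema))

    def to_csv(self, path, id_column: str = "node_id") -> None:
        out = self.data.copy()
        out.insert(0, id_column, self.node_ids)
        out.to_csv(path, index=False)

    def subset(self, node_ids: Sequence) -> "NodeMetadataTable":
        pos = {n: i for i, n in enumerate(self.node_ids)}
        idx = [pos[n] for n in node_ids]
        return NodeMetadataTable(
            list(node_ids), self.data.iloc[idx].reset_index(drop=True), dict(self.schema)
        )

    def row(self, node_id) -> "NodeMetadataTable":
        return self.subset([node_id])


@dataclass
class EncoderSpec:
    """Frozen per-variable encoding: one-hot class order for categoricals,
    (center, scale) for continuous columns.  Applying the same spec to the
    same table is bit-reproducible."""

    columns: list  # encoding order
    categories: dict = field(default_factory=dict)  # col -> ordered class list
    center_scale: dict = field(default_factory=dict)  # col -> (mean, sd)

    @property
    def width(self) -> int:
        return sum(
            len(self.categories[c]) if c in self.categories else 1 for c in self.columns
        )

    def feature_names(self) -> list[str]:
        names = []
        for c in self.columns:
            if c in self.categories:
                names += [f"{c}={k}" for k in self.categories[c]]
            else:
                names.append(c)
        return names

    def to_dict(self) -> dict:
        return {
            "columns": list(self.columns),
            "categories": {k: list(v) for k, v in self.categories.items()},
            "center_scale": {k: [float(v[0]), float(v[1])] for k, v in self.center_scale.items()},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "EncoderSpec":
        return cls(
            columns=list(d["columns"]),
            categories={k: list(v) for k, v in d["categories"].items()},
            center_scale={k: (v[0], v[1]) for k, v in d["center_scale"].items()},
        )


@dataclass
class DesignMatrix:
    node_ids: list
    matrix: np.ndarray
    encoder_spec: EncoderSpec

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (len(self.node_ids), self.encoder_spec.width):
            raise ValueError(
                f"design matrix shape {self.matrix.shape} inconsistent with "
                f"{len(self.node_ids)} nodes x encoder width {self.encoder_spec.width}"
            )


def encode_features(table: NodeMetadataTable, spec: EncoderSpec | None = None) -> DesignMatrix:
    """Encode a metadata table into a numeric design matrix.

    Without *spec*, class sets and standardisation constants are derived
    from *table* (training use); with *spec*, they are reused verbatim so
    new nodes are encoded identically.  Categorical variables expand to
    full one-hot (no reference class dropped); continuous variables map to
    ``(value - center) / scale``.  An unseen class under a reused spec is
    an error, never silently zeroed.
    """
    if spec is None:
        columns = [c for c in table.data.columns if c in table.schema]
        categories, center_scale = {}, {}
        for col in columns:
            if table.schema[col] == "categorical":
                seen = table.data[col].astype(str)
                categories[col] = sorted(seen.unique().tolist())
            else:
                vals = table.data[col].to_numpy(dtype=float)
                sd = float(vals.std(ddof=0))
                center_scale[col] = (float(vals.mean()), sd if sd > 0 else 1.0)
        spec = EncoderSpec(columns, categories, center_scale)

    blocks = []
    for col in spec.columns:
        if col not in table.data.columns:
            raise ValueError(f"metadata table lacks column {col!r} required by encoder")
        if col in spec.categories:
            classes = spec.categories[col]
            lookup = {k: i for i, k in enumerate(classes)}
            block = np.zeros((len(table.node_ids), len(classes)))
            for r, val in enumerate(table.data[col].astype(str)):
                if val not in lookup:
                    raise ValueError(
                        f"variable {col!r}: unseen categorical class {val!r}"
                    )
                block[r, lookup[val]] = 1.0
            blocks.append(block)
        else:
            center, scale = spec.center_scale[col]
            vals = table.data[col].to_numpy(dtype=float)
            blocks.append(((vals - center) / scale)[:, None])
    matrix = np.hstack(blocks) if blocks else np.zeros((len(table.node_ids), 0))
    return DesignMatrix(list(table.node_ids), matrix, spec)


def save_encoder_spec(spec: EncoderSpec, path) -> None:
    Path(path).write_text(json.dumps(spec.to_dict(), indent=1))


def load_encoder_spec(path) -> EncoderSpec:
    return EncoderSpec.from_dict(json.loads(Path(path).read_text()))
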