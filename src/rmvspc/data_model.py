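"""Core domain types and text-format I/O.

The package works with three kinds of objects:

* per-stage gene-expression matrices (:class:`ExpressionView`) — one matrix
  per clinical stage, samples in rows, genes in columns, all stages sharing
  one canonical gene ordering;
* an undirected, unweighted gene network (:class:`Network`) — typically a
  protein–protein interaction network over the same genes, carried as a
  binary adjacency matrix together with its combinatorial graph Laplacian
  ``L = D - A``;
* module partitions (:class:`ModulePartition`) — hard assignments of every
  gene to one of ``k`` modules.

All on-disk formats are plain UTF-8 tab-separated text: expression matrices
with a header row of gene identifiers and one row per sample; networks as
two-column edge lists; module assignments as two-column (gene, module)
tables.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionView",
    "Network",
    "RepresentationSet",
    "ModulePartition",
    "HyperParams",
    "load_expression_views",
    "load_network",
    "write_modules",
    "read_modules",
]


@dataclass
class ExpressionView:
    """One stage's expression matrix: ``n_samples x n_genes``, genes in columns."""

    stage_id: int
    values: np.ndarray
    gene_ids: list[str]
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("expression values must be a 2-D matrix")
        n_samples, n_genes = self.values.shape
        if len(self.gene_ids) != n_genes:
            raise ValueError(
                f"gene_ids length {len(self.gene_ids)} != number of columns {n_genes}"
            )
        if len(self.sample_ids) != n_samples:
            raise ValueError(
                f"sample_ids length {len(self.sample_ids)} != number of rows {n_samples}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression matrix contains non-finite entries")

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]


@dataclass
class Network:
    """Undirected, unweighted gene network with cached Laplacian.

    The adjacency matrix is binary and symmetric with a zero diagonal; the
    Laplacian is the combinatorial one, ``L = D - A``, whose quadratic form
    ``x' L x = sum over edges (x_i - x_j)^2`` penalizes differences between
    adjacent genes.
    """

    adjacency: np.ndarray
    gene_ids: list[str]

    def __post_init__(self) -> None:
        A = np.asarray(self.adjacency, dtype=float)
        if A.ndim != 2 or A.shape[0] != A.shape[1]:
            raise ValueError("adjacency must be square")
        if A.shape[0] != len(self.gene_ids):
            raise ValueError("adjacency size does not match gene_ids")
        if not np.array_equal(A, A.T):
            raise ValueError("adjacency must be symmetric")
        if np.any(np.diag(A) != 0):
            raise ValueError("adjacency diagonal must be zero")
        if not np.all(np.isin(A, (0.0, 1.0))):
            raise ValueError("adjacency entries must be 0 or 1")
        self.adjacency = A

    @property
    def n_genes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def degree(self) -> np.ndarray:
        return self.adjacency.sum(axis=1)

    @property
    def laplacian(self) -> np.ndarray:
        return np.diag(self.degree) - self.adjacency

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2


@dataclass
class RepresentationSet:
    """Output of the alternating optimization.

    Holds the per-view self-representation matrices ``C_s``, the consensus
    matrix ``C`` they are coupled to, the per-view residual norms
    ``||X_s - X_s C_s||_F``, and the value of the joint objective after each
    outer iteration.
    """

    view_reps: list[np.ndarray]
    consensus: np.ndarray
    residual_norms: list[float]
    objective_trace: list[float]
    converged: bool = True
    n_iter: int = 0


@dataclass
class ModulePartition:
    """Assignment of ``n`` genes to modules ``1..k`` (1-based labels)."""

    labels: np.ndarray
    k: int

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.ndim != 1 or self.labels.size == 0:
            raise ValueError("labels must be a non-empty 1-D vector")
        present = set(np.unique(self.labels))
        if not present <= set(range(1, self.k + 1)):
            raise ValueError(f"labels must lie in 1..{self.k}, got {sorted(present)}")
        if present != set(range(1, self.k + 1)):
            raise ValueError("every module index in 1..k must be non-empty")

    @property
    def n(self) -> int:
        return self.labels.size

    @property
    def module_members(self) -> list[np.ndarray]:
        """Gene indices per module, ordered by module index 1..k."""
        return [np.flatnonzero(self.labels == m) for m in range(1, self.k + 1)]


@dataclass
class HyperParams:
    """Regularization weights and run controls for the joint optimization.

    ``lambda_z`` weighs the self-representation residual, ``lambda_c`` the
    pull of each view matrix toward the consensus, and ``lambda_g`` the
    network-Laplacian smoothness of the consensus.  The default sets all
    three to 1, the single-knob setting used throughout the experiments.
    """

    lambda_z: float = 1.0
    lambda_c: float = 1.0
    lambda_g: float = 1.0
    k: int = 4
    max_outer_iters: int = 100
    tol: float = 1e-4
    inner_tol: float = 1e-6

    def __post_init__(self) -> None:
        if min(self.lambda_z, self.lambda_c, self.lambda_g) < 0:
            raise ValueError("regularization weights must be nonnegative")
        if self.k < 1:
            raise ValueError("k must be a positive integer")

    @classmethod
    def equal(cls, lam: float, **kwargs) -> "HyperParams":
        """All three weights set to one common value ``lam``."""
        return cls(lambda_z=lam, lambda_c=lam, lambda_g=lam, **kwargs)


def _read_expression_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    bad = df.map(lambda v: isinstance(v, str))
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"non-numeric entry {df.iat[r, c]!r} in {path} "
            f"(row {df.index[r]!r}, column {df.columns[c]!r})"
        )
    if df.isna().to_numpy().any():
        r, c = np.argwhere(df.isna().to_numpy())[0]
        raise ValueError(
            f"missing value in {path} (row {df.index[r]!r}, column {df.columns[c]!r})"
        )
    return df


def load_expression_views(
    paths: Sequence[str | Path],
    stage_labels: Sequence[int] | None = None,
) -> list[ExpressionView]:
    """Load per-stage expression TSVs and align them to a shared gene order.

    Each file has a header row of gene identifiers and one row per sample
    (first column = sample id).  Views are restricted to the intersection of
    their gene sets, in the sorted canonical order, so that downstream
    matrices are defined over one common gene axis.

    Raises ``ValueError`` on non-numeric cells (naming file/row/column) and
    when the gene intersection is empty.
    """
    if not paths:
        raise ValueError("no expression files given")
    if stage_labels is None:
        stage_labels = list(range(1, len(paths) + 1))
    if len(stage_labels) != len(paths):
        raise ValueError("stage_labels must match the number of files")

    tables = [_read_expression_table(p) for p in paths]
    common = set(tables[0].columns)
    for df in tables[1:]:
        common &= set(df.columns)
    if not common:
        raise ValueError("empty intersection of gene sets across expression files")
    gene_order = sorted(common)

    views = []
    for stage, path, df in zip(stage_labels, paths, tables):
        dropped = len(df.columns) - len(gene_order)
        if dropped:
            logger.info("%s: dropped %d genes outside the common set", path, dropped)
        sub = df.loc[:, gene_order]
        views.append(
            ExpressionView(
                stage_id=int(stage),
                values=sub.to_numpy(dtype=float),
                gene_ids=list(gene_order),
                sample_ids=[str(s) for s in sub.index],
            )
        )
    logger.info(
        "loaded %d views over %d common genes", len(views), len(gene_order)
    )
    return views


def load_network(path: str | Path, gene_ids: Sequence[str]) -> Network:
    """Read a two-column edge list and restrict it to ``gene_ids``.

    Duplicate and reversed edges are collapsed, self-loops removed, and edges
    touching genes outside ``gene_ids`` dropped; the counts are logged.  If no
    edge survives, an edgeless network (zero Laplacian) is returned with a
    warning.
    """
    gene_ids = list(gene_ids)
    index = {g: i for i, g in enumerate(gene_ids)}
    n = len(gene_ids)
    A = np.zeros((n, n))
    n_self = n_unknown = n_dup = 0
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.split()
            if not parts or parts[0].startswith("#"):
                continue
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: expected two columns, got {line!r}")
            u, v = parts[0], parts[1]
            if u == v:
                n_self += 1
                continue
            if u not in index or v not in index:
                n_unknown += 1
                continue
            i, j = index[u], index[v]
            if A[i, j]:
                n_dup += 1
            A[i, j] = A[j, i] = 1.0
    if n_self or n_unknown or n_dup:
        logger.info(
            "%s: removed %d self-loops, %d edges with unknown genes, "
            "%d duplicate edges",
            path, n_self, n_unknown, n_dup,
        )
    net = Network(adjacency=A, gene_ids=gene_ids)
    if net.n_edges == 0:
        logger.warning("%s: no edge survived restriction to the gene set", path)
    return net


def write_modules(
    partition: ModulePartition, gene_ids: Sequence[str], path: str | Path
) -> None:
    """Write a (gene_id, module_index) TSV, ordered by module then gene."""
    gene_ids = list(gene_ids)
    if not gene_ids:
        raise ValueError("empty gene list")
    if len(gene_ids) != partition.n:
        raise ValueError("gene_ids length does not match partition size")
    rows = sorted(zip(partition.labels.tolist(), gene_ids))
    with open(path, "w", encoding="utf-8") as fh:
        for label, gene in rows:
            fh.write(f"{gene}\t{label}\n")


def read_modules(path: str | Path, gene_ids: Sequence[str]) -> ModulePartition:
    """Read a (gene_id, module_index) TSV back into a partition over ``gene_ids``."""
    gene_ids = list(gene_ids)
    mapping: dict[str, int] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            mapping[parts[0]] = int(parts[1])
    missing = [g for g in gene_ids if g not in mapping]
    if missing:
        raise ValueError(f"module file {path} missing genes: {missing[:5]}...")
    labels = np.array([mapping[g] for g in gene_ids])
    # relabel onto 1..k preserving order of first appearance of each module id
    uniq = sorted(set(labels.tolist()))
    remap = {old: new for new, old in enumerate(uniq, start=1)}
    labels = np.array([remap[v] for v in labels])
    return ModulePartition(labels=labels, k=len(uniq))
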