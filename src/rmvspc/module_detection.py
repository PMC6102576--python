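"""From the consensus representation to gene modules.

Module extraction follows the standard sparse-subspace-clustering recipe:
normalize the columns of the consensus matrix, symmetrize it into a
nonnegative affinity ``W``, and run normalized spectral clustering on ``W``.

Because a self-representation matrix can carry negative coefficients, the
default affinity takes absolute values after the symmetrization ``C + C'``;
the signed (literal) variant is available through ``mode="literal"``.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy.linalg import eigh
from sklearn.cluster import KMeans

from .data_model import ModulePartition

logger = logging.getLogger(__name__)

__all__ = ["normalize_columns", "build_affinity", "spectral_modules", "detect_modules"]


def normalize_columns(C: np.ndarray, norm: str = "max") -> np.ndarray:
    """Scale each column of ``C`` by its max-abs entry (or L2 norm).

    All-zero columns are left untouched.
    """
    C = np.asarray(C, dtype=float)
    if norm == "max":
        scale = np.max(np.abs(C), axis=0)
    elif norm == "l2":
        scale = np.linalg.norm(C, axis=0)
    else:
        raise ValueError(f"unknown norm {norm!r}")
    scale = np.where(scale == 0, 1.0, scale)
    return C / scale


def build_affinity(C: np.ndarray, mode: str = "abs", norm: str = "max") -> np.ndarray:
    """Build the symmetric affinity ``W`` from the consensus matrix.

    Columns are normalized first.  ``mode="abs"`` (default) returns
    ``|C_norm| + |C_norm|'`` with a zero diagonal — symmetric and
    nonnegative, as spectral clustering requires.  ``mode="literal"``
    returns the raw symmetrization ``C_norm + C_norm'`` (may be signed).
    """
    C = np.asarray(C, dtype=float)
    if C.ndim != 2 or C.shape[0] != C.shape[1]:
        raise ValueError("consensus matrix must be square")
    if not np.all(np.isfinite(C)):
        raise ValueError("consensus matrix contains non-finite entries")
    Cn = normalize_columns(C, norm=norm)
    if mode == "abs":
        W = np.abs(Cn) + np.abs(Cn).T
    elif mode == "literal":
        W = Cn + Cn.T
    else:
        raise ValueError(f"unknown affinity mode {mode!r}")
    np.fill_diagonal(W, 0.0)
    return W


def _spectral_embedding(W: np.ndarray, k: int) -> np.ndarray:
    """Top-k eigenvectors of the symmetric normalized affinity, row-normalized."""
    d = W.sum(axis=1)
    inv_sqrt = np.zeros_like(d)
    nz = d > 0
    inv_sqrt[nz] = 1.0 / np.sqrt(d[nz])
    M = W * inv_sqrt[:, None] * inv_sqrt[None, :]
    n = W.shape[0]
    _, vecs = eigh(M, subset_by_index=(n - k, n - 1))
    rows = np.linalg.norm(vecs, axis=1)
    rows[rows == 0] = 1.0
    return vecs / rows[:, None]


def spectral_modules(
    W: np.ndarray, k: int, seed: int = 0, n_init: int = 20
) -> ModulePartition:
    """Normalized spectral clustering of a nonnegative affinity matrix.

    Embeds the genes with the top-``k`` eigenvectors of
    ``D^{-1/2} W D^{-1/2}``, row-normalizes the embedding, and clusters with
    k-means (``n_init`` restarts under ``seed``).  If k-means leaves a module
    empty, it is re-run with shifted seeds; as a last resort the most
    ambiguous points of the largest module are reassigned so the returned
    partition always covers ``1..k``.
    """
    W = np.asarray(W, dtype=float)
    n = W.shape[0]
    if W.shape != (n, n):
        raise ValueError("affinity must be square")
    if not np.allclose(W, W.T):
        raise ValueError("affinity must be symmetric")
    if np.any(W < 0):
        raise ValueError("affinity must be nonnegative")
    if not 2 <= k <= n:
        raise ValueError(f"k must lie in [2, {n}]")
    if int(np.sum(W.sum(axis=1) > 0)) < k:
        raise ValueError("fewer nonzero-degree nodes than requested modules")

    emb = _spectral_embedding(W, k)
    labels = None
    for attempt in range(5):
        km = KMeans(n_clusters=k, n_init=n_init, random_state=seed + attempt)
        cand = km.fit_predict(emb)
        if len(np.unique(cand)) == k:
            labels = cand
            break
    if labels is None:
        logger.warning("k-means left empty clusters; reassigning from largest module")
        labels = cand
        missing = [c for c in range(k) if c not in np.unique(cand)]
        for c in missing:
            big = np.bincount(labels, minlength=k).argmax()
            idx = np.flatnonzero(labels == big)
            labels[idx[0]] = c
    return ModulePartition(labels=labels + 1, k=k)


def detect_modules(
    C: np.ndarray,
    k: int,
    seed: int = 0,
    mode: str = "abs",
    norm: str = "max",
) -> ModulePartition:
    """Affinity construction plus spectral clustering in one call."""
    W = build_affinity(C, mode=mode, norm=norm)
    if mode == "literal":
        W = np.maximum(W, 0.0)  # spectral step still needs nonnegativity
    return spectral_modules(W, k=k, seed=seed)
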