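"""Evaluation stack: NMI, permutation-based module significance, activity features.

* :func:`nmi` scores a detected partition against a reference partition with
  normalized mutual information based on the confusion matrix of the two
  labelings (1 = identical up to relabeling, 0 = independent).
* :func:`permutation_significance` assesses whether a module's internal
  co-expression (average pairwise Pearson correlation) exceeds what the same
  pipeline produces on expression data whose sample order has been shuffled
  independently per gene, with Benjamini–Hochberg control of the false
  discovery rate across modules.
* :func:`module_activity` condenses a module into one per-sample feature —
  the mean of the z-scored expression of its genes — suitable as classifier
  input.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .data_model import ExpressionView, HyperParams, ModulePartition, Network

logger = logging.getLogger(__name__)

__all__ = [
    "confusion_matrix",
    "nmi",
    "module_score",
    "ModuleSignificance",
    "permutation_significance",
    "module_activity",
]


def confusion_matrix(P: ModulePartition, P_star: ModulePartition) -> np.ndarray:
    """Overlap counts N with N[i, j] = |module i of P ∩ module j of P_star|."""
    if P.n != P_star.n:
        raise ValueError("partitions must cover the same genes")
    N = np.zeros((P.k, P_star.k), dtype=int)
    for a, b in zip(P.labels, P_star.labels):
        N[a - 1, b - 1] += 1
    return N


def nmi(P: ModulePartition, P_star: ModulePartition) -> float:
    """Normalized mutual information between two partitions.

    Computed from the confusion matrix N (n genes total) as

        NMI = -2 * sum_ij N_ij log(N_ij n / (N_i. N_.j))
              / [ sum_i N_i. log(N_i./n) + sum_j N_.j log(N_.j/n) ]

    with 0 log 0 = 0.  The value is 1 for identical partitions (up to label
    permutation) and 0 for statistically independent ones.  When both
    partitions are a single cluster the denominator vanishes; the partitions
    are then identical and 1 is returned.
    """
    N = confusion_matrix(P, P_star).astype(float)
    n = N.sum()
    rows = N.sum(axis=1)
    cols = N.sum(axis=0)

    nz = N > 0
    logterm = np.zeros_like(N)
    logterm[nz] = np.log(N[nz] * n / np.outer(rows, cols)[nz])
    num = -2.0 * float(np.sum(N[nz] * logterm[nz]))
    denom = float(
        np.sum(np.where(rows > 0, rows * np.log(rows / n), 0.0))
        + np.sum(np.where(cols > 0, cols * np.log(cols / n), 0.0))
    )
    if denom == 0.0:
        # both partitions put everything in one cluster
        if np.array_equal(P.labels, P.labels[0] * np.ones_like(P.labels)) and \
           np.array_equal(P_star.labels, P_star.labels[0] * np.ones_like(P_star.labels)):
            return 1.0
        logger.warning("degenerate NMI denominator; returning 0")
        return 0.0
    return num / denom


def module_score(expr: np.ndarray, module: Sequence[int]) -> float:
    """Average pairwise Pearson correlation among a module's genes.

    ``expr`` is a samples x genes matrix; ``module`` lists gene column
    indices.  Pairs involving a constant gene contribute 0 (and are logged).
    """
    module = np.asarray(module, dtype=int)
    if module.size < 2:
        raise ValueError("module must contain at least 2 genes")
    sub = np.asarray(expr, dtype=float)[:, module]
    sd = sub.std(axis=0)
    const = sd == 0
    if const.any():
        logger.info("%d constant genes in module; their pairs score 0", const.sum())
    centered = sub - sub.mean(axis=0)
    safe_sd = np.where(const, 1.0, sd)
    zs = centered / safe_sd
    R = (zs.T @ zs) / sub.shape[0]
    R[const, :] = 0.0
    R[:, const] = 0.0
    iu = np.triu_indices(module.size, k=1)
    return float(R[iu].mean())


@dataclass
class ModuleSignificance:
    """Observed scores, permutation null, and BH-adjusted significance calls."""

    module_scores: np.ndarray
    null_scores: np.ndarray
    p_values: np.ndarray
    q_values: np.ndarray
    significant: np.ndarray
    alpha: float = 0.05


def _pooled_matrix(views: list[ExpressionView]) -> np.ndarray:
    return np.vstack([v.values for v in views])


def _permute_views(
    views: list[ExpressionView], rng: np.random.Generator, mode: str
) -> list[ExpressionView]:
    out = []
    for v in views:
        vals = v.values.copy()
        if mode == "per-gene":
            for j in range(vals.shape[1]):
                vals[:, j] = vals[rng.permutation(vals.shape[0]), j]
        elif mode == "whole-column":
            vals = vals[rng.permutation(vals.shape[0]), :]
        else:
            raise ValueError(f"unknown shuffle mode {mode!r}")
        out.append(
            ExpressionView(v.stage_id, vals, list(v.gene_ids), list(v.sample_ids))
        )
    return out


def empirical_p_values(observed: np.ndarray, null: np.ndarray) -> np.ndarray:
    """Add-one empirical p-values against a pooled null distribution."""
    null = np.asarray(null, dtype=float).ravel()
    return np.array(
        [(1.0 + np.sum(null >= obs)) / (1.0 + null.size) for obs in observed]
    )


def permutation_significance(
    views: list[ExpressionView],
    network: Network,
    partition: ModulePartition,
    params: HyperParams | None = None,
    n_perm: int = 1000,
    seed: int = 0,
    shuffle_mode: str = "per-gene",
    refit: bool = True,
    alpha: float = 0.05,
) -> ModuleSignificance:
    """Permutation test of module co-expression with BH correction.

    Observed module scores are the average pairwise Pearson correlations on
    the stage-pooled expression matrix.  For each of ``n_perm`` permutations
    the sample order is shuffled independently per gene within each view
    (destroying gene–gene correlation while preserving marginals); by default
    the full pipeline — fit, affinity, spectral clustering — is re-run on the
    permuted data (``refit=True``) and the resulting modules are scored into a
    pooled null.  ``refit=False`` rescores the fixed observed modules on the
    permuted data instead.  Empirical p-values use the add-one estimator
    ``p = (1 + #{null >= observed}) / (1 + #null)``; q-values are
    Benjamini–Hochberg step-up, flagged at ``q <= alpha``.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if params is None:
        params = HyperParams(k=partition.k)
    from . import module_detection, subspace_core  # deferred: avoids cycle at import

    pooled = _pooled_matrix(views)
    observed = np.array(
        [module_score(pooled, members) for members in partition.module_members]
    )
    rng = np.random.default_rng(seed)
    null: list[float] = []
    report_every = max(1, n_perm // 10)
    for b in range(n_perm):
        perm_views = _permute_views(views, rng, shuffle_mode)
        perm_pooled = _pooled_matrix(perm_views)
        if refit:
            rep = subspace_core.fit(perm_views, network, params)
            perm_part = module_detection.detect_modules(
                rep.consensus, k=params.k, seed=seed
            )
        else:
            perm_part = partition
        null.extend(
            module_score(perm_pooled, members)
            for members in perm_part.module_members
        )
        if (b + 1) % report_every == 0:
            logger.info("permutation %d/%d", b + 1, n_perm)
    null_arr = np.array(null)
    p = empirical_p_values(observed, null_arr)
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return ModuleSignificance(
        module_scores=observed,
        null_scores=null_arr,
        p_values=p,
        q_values=q,
        significant=q <= alpha,
        alpha=alpha,
    )


def module_activity(expr: np.ndarray, partition: ModulePartition) -> np.ndarray:
    """Per-sample module activity features.

    Each gene is z-scored across all samples (constant genes map to 0); the
    activity of module ``C`` in sample ``j`` is the mean z-scored expression
    of the module's genes.  Returns a samples x k matrix whose columns follow
    module indices 1..k.
    """
    expr = np.asarray(expr, dtype=float)
    sd = expr.std(axis=0)
    z = np.zeros_like(expr)
    nz = sd > 0
    z[:, nz] = (expr[:, nz] - expr[:, nz].mean(axis=0)) / sd[nz]
    feats = np.column_stack(
        [z[:, members].mean(axis=1) for members in partition.module_members]
    )
    return feats
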