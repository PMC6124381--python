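"""Preparing count data for balance analysis.

Sequencing count tables contain zeros that break every log-ratio
transformation, and usually come without a meaningful hierarchy over the
taxa. This module supplies both missing pieces:

* multiplicative zero replacement — zeros are imputed with a small value on
  the closed (sum-to-one) scale while the non-zero parts are shrunk by a
  common factor, so the ratios among observed parts are exactly preserved;
* a data-driven SBP — components are hierarchically clustered on the
  symmetric proportionality dissimilarity phi_s, joining parts that covary
  similarly across samples, and the resulting merge tree is converted to a
  sequential binary partition.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage as scipy_linkage, to_tree
from scipy.spatial.distance import squareform
from skbio import TreeNode

from .core import (CompositionTable, DomainError, clr, validate_composition)
from .sbp import MergeTree, SbpMatrix, tree_to_sbp

__all__ = [
    "DissimilarityMatrix",
    "replace_zeros",
    "phi_s",
    "cluster_components",
    "sbp_from_data",
]

LINKAGE_METHODS = ("complete", "average", "ward")


@dataclass(frozen=True)
class DissimilarityMatrix:
    """Symmetric non-negative component dissimilarities with zero diagonal."""

    data: pd.DataFrame

    def __post_init__(self):
        values = self.data.to_numpy(dtype=float)
        if not np.allclose(values, values.T, atol=1e-12):
            raise DomainError("dissimilarity matrix must be symmetric")
        if np.any(np.diag(values) != 0):
            raise DomainError("dissimilarity matrix diagonal must be 0")
        if np.any(values < 0):
            raise DomainError("dissimilarities must be non-negative")

    @property
    def component_ids(self) -> list:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)


def replace_zeros(counts, label_fraction: float = 0.65) -> CompositionTable:
    """Multiplicative zero replacement on the closed scale.

    Each zero in sample i becomes ``delta_i = label_fraction / (N_i + 1)``
    where ``N_i`` is the raw row total; the originally non-zero parts of
    that sample, closed to proportions, are then multiplied by
    ``1 - z_i * delta_i`` (``z_i`` = number of zeros), so their mutual
    ratios are untouched and the row sums to exactly 1. Zero-free rows come
    out identical to plain closure.
    """
    if not 0 < label_fraction < 1:
        raise DomainError(
            f"label_fraction must be in (0, 1), got {label_fraction}"
        )
    if not isinstance(counts, pd.DataFrame):
        counts = validate_composition(counts, allow_zero=True).data
    values = counts.to_numpy(dtype=float)
    if np.any(values < 0) or not np.all(np.isfinite(values)):
        raise DomainError("counts must be finite and non-negative")
    totals = values.sum(axis=1)
    if np.any(totals <= 0):
        i = int(np.argmax(totals <= 0))
        raise DomainError(f"sample {counts.index[i]!r} is all zero")
    zeros = values == 0
    n_zero = zeros.sum(axis=1)
    delta = label_fraction / (totals + 1.0)
    shrink = 1.0 - n_zero * delta
    if np.any(shrink <= 0):
        i = int(np.argmax(shrink <= 0))
        raise DomainError(
            f"sample {counts.index[i]!r} has too many zeros for "
            f"label_fraction={label_fraction}"
        )
    proportions = values / totals[:, None]
    out = np.where(zeros, delta[:, None], proportions * shrink[:, None])
    df = pd.DataFrame(out, index=counts.index, columns=counts.columns)
    return CompositionTable(df, has_zeros=False)


def phi_s(data: CompositionTable) -> DissimilarityMatrix:
    """Symmetric proportionality dissimilarity phi_s between components.

    For clr coordinates y_j, y_k,

        rho_jk  = 2 cov(y_j, y_k) / (var y_j + var y_k)
        phi_s   = (1 - rho) / (1 + rho)
                = var(y_j - y_k) / var(y_j + y_k)

    phi_s is 0 iff the two components are exactly proportional across
    samples. Both algebraic forms are evaluated (the second literally, from
    the per-pair difference and sum variances) and must agree to 1e-9;
    pairs whose denominator has zero variance are set to the largest finite
    dissimilarity observed, with a warning, so a degenerate component
    becomes a late-merging singleton instead of aborting the run.
    """
    if data.n_samples < 3:
        raise DomainError("phi_s needs at least 3 samples")
    y = clr(data).values  # n x D
    D = y.shape[1]
    var = y.var(axis=0, ddof=1)
    cov = np.cov(y, rowvar=False, ddof=1)
    denom_rho = var[:, None] + var[None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        rho = 2.0 * cov / denom_rho
        form_a = (1.0 - rho) / (1.0 + rho)

    # independent route: literal variances of column differences and sums
    form_b = np.empty((D, D))
    var_sum = np.empty((D, D))
    step = max(1, int(2_000_000 / max(1, y.shape[0] * D)))
    with np.errstate(divide="ignore", invalid="ignore"):
        for start in range(0, D, step):
            block = slice(start, min(start + step, D))
            diff = y[:, block, None] - y[:, None, :]
            summ = y[:, block, None] + y[:, None, :]
            vd = diff.var(axis=0, ddof=1)
            vs = summ.var(axis=0, ddof=1)
            form_b[block] = vd / vs
            var_sum[block] = vs

    flagged = ~np.isfinite(form_a) | ~np.isfinite(form_b) | (var_sum <= 0)
    np.fill_diagonal(flagged, False)
    ok = ~flagged
    np.fill_diagonal(form_a, 0.0)
    np.fill_diagonal(form_b, 0.0)
    if not np.allclose(form_a[ok], form_b[ok], atol=1e-9, rtol=1e-9):
        raise DomainError(
            "phi_s self-check failed: the two algebraic forms disagree"
        )
    out = form_a.copy()
    out[ok] = (form_a[ok] + form_b[ok]) / 2.0
    out = (out + out.T) / 2.0
    np.fill_diagonal(out, 0.0)
    out[out < 0] = 0.0  # clip tiny negative rounding
    if flagged.any():
        sentinel = float(out[~flagged].max()) if (~flagged).any() else 1.0
        sentinel = max(sentinel, 1.0)
        out[flagged] = sentinel
        warnings.warn(
            f"{int(flagged.sum() // 2)} component pair(s) have a zero-variance "
            f"denominator; phi_s set to sentinel {sentinel:.6g}",
            RuntimeWarning, stacklevel=2,
        )
    idx = pd.Index(data.component_ids)
    return DissimilarityMatrix(pd.DataFrame(out, index=idx, columns=idx))


def _cluster_node_to_tree(node, labels) -> TreeNode:
    if node.is_leaf():
        out = TreeNode(name=labels[node.id])
        out.height = 0.0
        return out
    out = TreeNode(children=[_cluster_node_to_tree(node.left, labels),
                             _cluster_node_to_tree(node.right, labels)])
    out.height = float(node.dist)  # merge height of this agglomeration step
    return out


def cluster_components(dist: DissimilarityMatrix,
                       linkage: str = "complete") -> MergeTree:
    """Agglomeratively cluster components into a strictly binary merge tree.

    Default linkage is complete; average and ward are also available.
    """
    if linkage not in LINKAGE_METHODS:
        raise DomainError(
            f"linkage must be one of {LINKAGE_METHODS}, got {linkage!r}"
        )
    values = dist.values
    if not np.all(np.isfinite(values)):
        raise DomainError("dissimilarity matrix contains non-finite entries")
    condensed = squareform(values, checks=False)
    Z = scipy_linkage(condensed, method=linkage)
    root = to_tree(Z)
    return MergeTree(_cluster_node_to_tree(root, dist.component_ids))


def sbp_from_data(counts, label_fraction: float = 0.65,
                  linkage: str = "complete",
                  flip: bool = False) -> tuple[CompositionTable, SbpMatrix]:
    """Full data-driven pipeline: impute zeros, cluster on phi_s, build SBP.

    Returns the zero-imputed composition table together with the SBP
    (D-1 balances for D components). Deterministic: the pipeline contains
    no randomness.
    """
    table = replace_zeros(counts, label_fraction=label_fraction)
    dist = phi_s(table)
    tree = cluster_components(dist, linkage=linkage)
    sbp = tree_to_sbp(tree, flip=flip)
    # align SBP row order with the data's component order for readability
    sbp = SbpMatrix(sbp.signs.loc[table.component_ids])
    return table, sbp
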