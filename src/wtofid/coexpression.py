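"""Base co-expression measures: Spearman, biweight midcorrelation, weights.

Two pairwise similarity metrics are supported for gene expression profiles:

* Spearman correlation — Pearson correlation of the average-rank transforms
  of the two profiles; non-parametric, invariant under strictly monotone
  transforms of either profile.
* Biweight midcorrelation (bicor) — a robust correlation built from
  median-centred, MAD-scaled observations with tricube-squared weights that
  smoothly down-weight outliers; observations further than 9 rescaled MADs
  from the median get zero weight.  Rows with zero MAD (more than half the
  values identical) fall back to Pearson centring for that row.

A correlation matrix is turned into an edge-weight matrix by taking absolute
values, optionally soft-thresholded by raising to an exponent beta (default
6 downstream) to accentuate strong links; the diagonal is zeroed by
convention since self-similarity carries no network information.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .expression import ExpressionMatrix

__all__ = [
    "CorrelationMatrix",
    "WeightMatrix",
    "spearman_matrix",
    "bicor_matrix",
    "soft_threshold",
    "to_weights",
]

logger = logging.getLogger(__name__)

_SYMMETRY_TOL = 1e-12


@dataclass(frozen=True)
class CorrelationMatrix:
    """Symmetric gene × gene correlation matrix in [−1, 1], unit diagonal."""

    gene_ids: list[str]
    values: np.ndarray = field(repr=False)
    metric_tag: str = "spearman"
    soft_power: float = 1.0

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        n = len(self.gene_ids)
        if values.shape != (n, n):
            raise ValueError(f"expected {n}×{n} matrix, got {values.shape}")
        if np.abs(values - values.T).max(initial=0.0) > _SYMMETRY_TOL:
            raise ValueError("correlation matrix is not symmetric")
        if self.soft_power == 1.0:
            if np.abs(values).max(initial=0.0) > 1.0 + _SYMMETRY_TOL:
                raise ValueError("correlation entries outside [−1, 1]")
            if np.abs(np.diag(values) - 1.0).max(initial=0.0) > _SYMMETRY_TOL:
                raise ValueError("correlation diagonal is not 1")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)


@dataclass(frozen=True)
class WeightMatrix:
    """Symmetric absolute edge weights in [0, 1] with a zero diagonal."""

    gene_ids: list[str]
    values: np.ndarray = field(repr=False)
    metric_tag: str = "spearman"
    soft_power: float = 1.0

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        n = len(self.gene_ids)
        if values.shape != (n, n):
            raise ValueError(f"expected {n}×{n} matrix, got {values.shape}")
        if np.abs(values - values.T).max(initial=0.0) > _SYMMETRY_TOL:
            raise ValueError("weight matrix is not symmetric")
        if values.min(initial=0.0) < -_SYMMETRY_TOL or values.max(
            initial=0.0
        ) > 1.0 + _SYMMETRY_TOL:
            raise ValueError("weights outside [0, 1]")
        if np.abs(np.diag(values)).max(initial=0.0) > _SYMMETRY_TOL:
            raise ValueError("weight diagonal must be zero")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)


def _correlate_normalized(A: np.ndarray, zero_rows: np.ndarray) -> np.ndarray:
    """Gram matrix of row-normalised vectors with exact-unit diagonal."""
    C = A @ A.T
    # zero-variance rows carry no information: define their correlations as 0
    C[zero_rows, :] = 0.0
    C[:, zero_rows] = 0.0
    np.clip(C, -1.0, 1.0, out=C)
    C = (C + C.T) / 2.0
    np.fill_diagonal(C, 1.0)
    return C


def _normalize_rows(A: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    norms = np.linalg.norm(A, axis=1)
    zero = norms == 0.0
    norms[zero] = 1.0
    return A / norms[:, None], zero


def spearman_matrix(X: ExpressionMatrix) -> CorrelationMatrix:
    """All-pairs Spearman correlation (average ranks for ties).

    A constant expression profile has zero rank variance; its correlations
    are defined as 0 and a warning is logged.
    """
    ranks = stats.rankdata(X.values, axis=1)
    centered = ranks - ranks.mean(axis=1, keepdims=True)
    A, zero = _normalize_rows(centered)
    if zero.any():
        logger.warning(
            "spearman_matrix: %d constant gene profile(s), correlations set to 0",
            int(zero.sum()),
        )
    C = _correlate_normalized(A, zero)
    return CorrelationMatrix(list(X.gene_ids), C, metric_tag="spearman")


def _bicor_transform(x: np.ndarray) -> np.ndarray | None:
    """Biweight midcovariance vector for one profile, or None if MAD = 0."""
    med = np.median(x)
    mad = np.median(np.abs(x - med))
    if mad == 0.0:
        return None
    u = (x - med) / (9.0 * mad)
    w = (1.0 - u**2) ** 2 * (np.abs(u) < 1.0)
    return (x - med) * w


def bicor_matrix(X: ExpressionMatrix) -> CorrelationMatrix:
    """All-pairs biweight midcorrelation.

    Per profile ``x``: ``u = (x − median) / (9·MAD)``, weights
    ``(1 − u²)²`` inside ``|u| < 1`` and zero outside; the correlation is
    the normalised cross-product of the weighted median-centred profiles.
    Rows with MAD = 0 fall back to Pearson centring (logged); pairs with a
    zero-variance row are set to 0.
    """
    V = X.values
    A = np.empty_like(V, dtype=float)
    n_fallback = 0
    for i in range(V.shape[0]):
        t = _bicor_transform(V[i])
        if t is None:
            n_fallback += 1
            t = V[i] - V[i].mean()
        A[i] = t
    if n_fallback:
        logger.warning(
            "bicor_matrix: %d profile(s) with zero MAD, Pearson fallback used",
            n_fallback,
        )
    A, zero = _normalize_rows(A)
    if zero.any():
        logger.warning(
            "bicor_matrix: %d zero-variance profile(s), correlations set to 0",
            int(zero.sum()),
        )
    C = _correlate_normalized(A, zero)
    return CorrelationMatrix(list(X.gene_ids), C, metric_tag="bicor")


def bicor_pair(x: np.ndarray, y: np.ndarray) -> float:
    """Scalar bicor of two profiles; the slow reference path for one pair."""
    tx = _bicor_transform(np.asarray(x, dtype=float))
    ty = _bicor_transform(np.asarray(y, dtype=float))
    if tx is None:
        tx = np.asarray(x, dtype=float) - np.mean(x)
    if ty is None:
        ty = np.asarray(y, dtype=float) - np.mean(y)
    nx, ny = np.linalg.norm(tx), np.linalg.norm(ty)
    if nx == 0.0 or ny == 0.0:
        return 0.0
    return float(np.clip(tx @ ty / (nx * ny), -1.0, 1.0))


def to_weights(C: CorrelationMatrix) -> WeightMatrix:
    """Absolute correlations with zero diagonal (soft power 1)."""
    return soft_threshold(C, beta=1.0)


def soft_threshold(C: CorrelationMatrix, beta: float = 6.0) -> WeightMatrix:
    """Edge weights ``|c_ij|^beta`` with zero diagonal.

    Raising to a power accentuates strong correlations relative to weak
    ones without imposing a hard cutoff; it never changes the relative
    ranking of the weights.
    """
    if beta < 1.0:
        raise ValueError(f"beta must be ≥ 1, got {beta}")
    W = np.abs(C.values) ** beta
    np.fill_diagonal(W, 0.0)
    return WeightMatrix(
        list(C.gene_ids), W, metric_tag=C.metric_tag, soft_power=beta * C.soft_power
    )
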