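"""Fidelity statistics between low-quality and reference score matrices.

A symmetric score matrix is flattened to a :class:`ScoreVector` over the
canonical upper-triangle pair order; all comparisons require matched pair
universes.  Two complementary statistics quantify agreement:

* :func:`rank_agreement` — Spearman correlation of the two score lists,
  sensitive to rank perturbations across the whole gene set;
* :func:`jaccard_top_k` — Jaccard index of the top-k pair sets (default
  k = 1000), focused on the strongest links that a biological study would
  actually follow up.

Across an ensemble of disjoint gene groups, per-group fidelity differences
between two methods are paired observations; :func:`paired_difference_test`
applies the two-sided Wilcoxon signed-rank test to them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .coexpression import WeightMatrix

__all__ = [
    "ScoreVector",
    "FidelityResult",
    "score_vector",
    "rank_agreement",
    "jaccard_top_k",
    "paired_difference_test",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ScoreVector:
    """Upper-triangle pair scores of a symmetric gene × gene matrix.

    ``scores[m]`` belongs to the m-th pair (i, j), i < j, in row-major
    upper-triangle order over ``gene_ids``.  Vectors are comparable only
    when their gene lists (hence pair universes) are identical.
    """

    gene_ids: list[str]
    scores: np.ndarray = field(repr=False)
    metric_tag: str = ""

    def __post_init__(self) -> None:
        scores = np.asarray(self.scores, dtype=float)
        object.__setattr__(self, "scores", scores)
        n = len(self.gene_ids)
        expected = n * (n - 1) // 2
        if scores.shape != (expected,):
            raise ValueError(
                f"{n} genes imply {expected} pairs, got {scores.shape}"
            )

    @property
    def n_pairs(self) -> int:
        return self.scores.shape[0]

    def pairs(self) -> list[tuple[str, str]]:
        """Materialise the canonical (gene_a, gene_b) pair list, a < b."""
        idx_i, idx_j = np.triu_indices(len(self.gene_ids), k=1)
        return [
            (self.gene_ids[i], self.gene_ids[j]) for i, j in zip(idx_i, idx_j)
        ]

    def top_k_indices(self, k: int) -> np.ndarray:
        """Indices of the k largest scores; ties broken by canonical order."""
        if k > self.n_pairs:
            raise ValueError(f"k = {k} exceeds {self.n_pairs} pairs")
        order = np.argsort(-self.scores, kind="stable")
        return order[:k]


@dataclass(frozen=True)
class FidelityResult:
    """Agreement of one group × quality score vector with its reference."""

    group: int
    quality: int
    metric_tag: str
    rank_agreement: float
    jaccard_top_k: float
    k: int


def score_vector(W: WeightMatrix) -> ScoreVector:
    """Flatten a symmetric score matrix to its canonical pair vector."""
    n = W.n_genes
    idx = np.triu_indices(n, k=1)
    return ScoreVector(list(W.gene_ids), W.values[idx], metric_tag=W.metric_tag)


def _check_same_universe(a: ScoreVector, b: ScoreVector) -> None:
    if a.gene_ids != b.gene_ids:
        raise ValueError("score vectors are over different pair universes")


def rank_agreement(a: ScoreVector, b: ScoreVector) -> float:
    """Spearman correlation of two matched score lists (average-rank ties).

    Identical rankings return exactly 1.0 (and reversed rankings exactly
    −1.0) rather than a value perturbed by floating-point round-off in the
    rank-correlation arithmetic.
    """
    _check_same_universe(a, b)
    ranks_a = stats.rankdata(a.scores)
    ranks_b = stats.rankdata(b.scores)
    if np.array_equal(ranks_a, ranks_b):
        return 1.0
    if np.array_equal(ranks_a, len(ranks_a) + 1 - ranks_b):
        return -1.0
    rho = stats.spearmanr(a.scores, b.scores).statistic
    return float(np.clip(rho, -1.0, 1.0))


def jaccard_top_k(a: ScoreVector, b: ScoreVector, k: int = 1000) -> float:
    """Jaccard index |Tₐ ∩ T_b| / |Tₐ ∪ T_b| of the top-k pair sets."""
    _check_same_universe(a, b)
    top_a = set(a.top_k_indices(k).tolist())
    top_b = set(b.top_k_indices(k).tolist())
    inter = len(top_a & top_b)
    return inter / (2 * k - inter)


def paired_difference_test(
    diffs: np.ndarray | list[float], exact: bool = True
) -> tuple[float, int]:
    """Two-sided Wilcoxon signed-rank test on per-group paired differences.

    Zero differences are dropped before ranking.  The exact null
    distribution is used by default (feasible for ensembles up to ~25
    groups); ``exact=False`` selects the normal approximation instead.

    Returns
    -------
    (p_value, n_positive)
        The two-sided p-value and the number of strictly positive
        differences (groups where the first method wins).
    """
    d = np.asarray(diffs, dtype=float)
    if d.size < 5:
        raise ValueError(f"need at least 5 paired differences, got {d.size}")
    n_positive = int((d > 0).sum())
    if np.all(d == 0.0):
        logger.warning("paired_difference_test: all differences are zero")
        return 1.0, 0
    method = "exact" if exact else "approx"
    res = stats.wilcoxon(
        d, zero_method="wilcox", alternative="two-sided", method=method
    )
    return float(res.pvalue), n_positive
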