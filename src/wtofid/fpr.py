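"""False-positive rates of correlation vs wTO networks on truth-free data.

Random expression data contains no true co-expression, so every gene pair
whose score exceeds a realistic network cutoff is a false positive.  The
experiment scores an ensemble of i.i.d. uniform-[0,1] matrices (Spearman
correlation is rank-based, so any i.i.d. continuous distribution gives the
same answer) with both the base Spearman weight and the wTO of that weight,
then counts exceedances of percentile-derived cutoffs.

The shipped :data:`REFERENCE_CUTOFFS` are the 90th/95th/99th percentiles of
Spearman and wTO scores over twenty full-quality (338-sample, 1000-gene)
human whole-blood reference groups, making the protocol self-contained;
:func:`percentile_cutoff` recomputes such cutoffs from any reference score
ensemble.

:func:`spearman_null_exceedance` is an independent oracle for the Spearman
side: the exceedance probability of |ρ| over the permutation null of two
independent rank vectors, by full enumeration for small sample counts or
by Monte-Carlo sampling of permutations otherwise.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .coexpression import spearman_matrix, to_weights
from .fidelity import ScoreVector, score_vector
from .simulate import (
    EnsembleDesign,
    child_seed,
    generate_random_expression,
    nested_subsample,
)
from .wto import wto_matrix

__all__ = [
    "REFERENCE_CUTOFFS",
    "FPRTable",
    "percentile_cutoff",
    "false_positive_rate",
    "spearman_null_exceedance",
    "run_fpr_experiment",
]

#: Reference network cutoffs, keyed by percentile:
#: ``{percentile: (spearman_cutoff, wto_cutoff)}``.  Derived from the
#: percentiles of each score over 20 disjoint 1000-gene groups of the
#: full-quality (338-sample) GTEx whole-blood expression set.
REFERENCE_CUTOFFS: dict[int, tuple[float, float]] = {
    90: (0.5879, 0.4826),
    95: (0.6848, 0.5202),
    99: (0.8303, 0.6321),
}


@dataclass(frozen=True)
class FPRTable:
    """Pooled false-positive rates plus per-group exceedance counts.

    ``table`` has one row per (percentile, quality) with pooled FPRs for
    both metrics; ``per_group`` keeps the raw exceedance counts per group,
    from which between-group uncertainty of the pooled rates can be judged.
    """

    table: pd.DataFrame = field(repr=False)
    per_group: pd.DataFrame = field(repr=False)


def percentile_cutoff(
    reference_scores: list[ScoreVector], percentile: float
) -> float:
    """Pooled percentile (linear interpolation) of absolute reference scores."""
    if not reference_scores:
        raise ValueError("no reference score vectors supplied")
    if not 0.0 < percentile <= 100.0:
        raise ValueError(f"percentile must be in (0, 100], got {percentile}")
    pooled = np.abs(np.concatenate([sv.scores for sv in reference_scores]))
    return float(np.percentile(pooled, percentile, method="linear"))


def false_positive_rate(null_scores: list[ScoreVector], cutoff: float) -> float:
    """Fraction of pooled null pairs scoring strictly above ``cutoff``."""
    if cutoff <= 0.0:
        raise ValueError(f"cutoff must be positive, got {cutoff}")
    total = sum(sv.n_pairs for sv in null_scores)
    exceed = sum(int((sv.scores > cutoff).sum()) for sv in null_scores)
    return exceed / total


_EXACT_LIMIT = 8


def spearman_null_exceedance(
    n_samples: int,
    cutoff: float,
    mode: str = "exact",
    reps: int = 1_000_000,
    seed: int = 0,
) -> float:
    """P(|ρ| > cutoff) for Spearman's ρ of two independent rank vectors.

    Under independence the null is uniform over the n! relative orderings,
    so the probability is computed from ρ between a fixed identity ranking
    and (exact mode) every permutation or (montecarlo mode) ``reps``
    uniformly sampled permutations.  Exact mode is limited to
    ``n_samples ≤ 8`` (full factorial enumeration).
    """
    n = int(n_samples)
    if n < 3:
        raise ValueError("need at least 3 samples")
    if mode == "exact":
        if n > _EXACT_LIMIT:
            raise ValueError(
                f"exact enumeration limited to n ≤ {_EXACT_LIMIT}, got {n}"
            )
        denom = n * (n**2 - 1)
        hits = 0
        for perm in itertools.permutations(range(n)):
            d2 = sum((p - k) ** 2 for k, p in enumerate(perm))
            rho = 1.0 - 6.0 * d2 / denom
            if abs(rho) > cutoff:
                hits += 1
        return hits / math.factorial(n)
    if mode == "montecarlo":
        rng = np.random.default_rng(seed)
        base = np.arange(n)
        reps = int(reps)
        hits = 0
        done = 0
        while done < reps:  # chunked to bound memory at large rep counts
            chunk = min(500_000, reps - done)
            perms = rng.permuted(np.tile(base, (chunk, 1)), axis=1)
            d2 = ((perms - base) ** 2).sum(axis=1)
            rho = 1.0 - 6.0 * d2 / (n * (n**2 - 1))
            hits += int((np.abs(rho) > cutoff).sum())
            done += chunk
        return hits / reps
    raise ValueError(f"mode must be 'exact' or 'montecarlo', got {mode!r}")


def null_score_vectors(
    n_genes: int, qualities: list[int], seed: int, group: int = 0
) -> dict[int, tuple[ScoreVector, ScoreVector]]:
    """Spearman-weight and wTO score vectors of one null group per quality.

    The group's full matrix has ``max(qualities)`` samples; lower qualities
    are nested subsamples of it, matching how reduced measurement counts
    arise from one underlying data set.
    """
    sizes = sorted(int(q) for q in qualities)
    full = generate_random_expression(
        n_genes, sizes[-1], seed=child_seed(seed, group, "null-data")
    )
    nested = nested_subsample(full, sizes, seed=child_seed(seed, group, "subsample"))
    out: dict[int, tuple[ScoreVector, ScoreVector]] = {}
    for quality, level in nested.levels.items():
        W = to_weights(spearman_matrix(level))
        out[quality] = (score_vector(W), score_vector(wto_matrix(W)))
    return out


def run_fpr_experiment(
    design: EnsembleDesign,
    qualities: list[int] = (10, 20, 50, 338),
    percentiles: list[int] = (90, 95, 99),
    cutoffs: dict[int, tuple[float, float]] | None = None,
    reference_scores: tuple[list[ScoreVector], list[ScoreVector]] | None = None,
    seed: int | None = None,
) -> FPRTable:
    """Score null ensembles and tabulate FPRs at percentile cutoffs.

    Cutoffs come either from ``cutoffs`` (explicit
    ``{percentile: (spearman, wto)}`` constants, e.g.
    :data:`REFERENCE_CUTOFFS`) or are recomputed from ``reference_scores``
    (a pair of Spearman-weight and wTO reference score-vector lists).
    """
    if cutoffs is None and reference_scores is None:
        raise ValueError("supply explicit cutoffs or reference score vectors")
    if cutoffs is None:
        ref_sp, ref_wto = reference_scores
        cutoffs = {
            int(p): (
                percentile_cutoff(ref_sp, p),
                percentile_cutoff(ref_wto, p),
            )
            for p in percentiles
        }
    root_seed = design.seed if seed is None else seed
    qualities = sorted(int(q) for q in qualities)

    rows = []
    for group in range(design.n_groups):
        scored = null_score_vectors(
            design.group_size, qualities, seed=root_seed, group=group
        )
        for quality, (sv_sp, sv_wto) in scored.items():
            for p in percentiles:
                cut_sp, cut_wto = cutoffs[int(p)]
                rows.append(
                    {
                        "group": group,
                        "quality": quality,
                        "percentile": int(p),
                        "cutoff_spearman": cut_sp,
                        "cutoff_wto": cut_wto,
                        "n_pairs": sv_sp.n_pairs,
                        "n_exceed_spearman": int((sv_sp.scores > cut_sp).sum()),
                        "n_exceed_wto": int((sv_wto.scores > cut_wto).sum()),
                    }
                )
    per_group = pd.DataFrame(rows)
    pooled = (
        per_group.groupby(
            ["percentile", "cutoff_spearman", "cutoff_wto", "quality"],
            as_index=False,
        )[["n_pairs", "n_exceed_spearman", "n_exceed_wto"]]
        .sum()
        .assign(
            fpr_spearman=lambda d: d.n_exceed_spearman / d.n_pairs,
            fpr_wto=lambda d: d.n_exceed_wto / d.n_pairs,
        )
        .sort_values(["quality", "percentile"], ignore_index=True)
    )
    return FPRTable(table=pooled, per_group=per_group)
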