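"""Synthetic expression data: null matrices, planted modules, subsampling.

Two generators stand in for real expression data:

* :func:`generate_random_expression` draws every entry i.i.d. uniform on
  [0, 1] — the truth-free null used for false-positive-rate experiments.
  Under a rank correlation any i.i.d. continuous distribution is equivalent;
  the uniform choice also keeps robust-correlation estimators well-behaved.
* :func:`generate_modular_expression` plants correlated gene modules via a
  single-factor model: within a block each gene is
  ``sqrt(rho)·factor + sqrt(1−rho)·noise`` with independent standard-normal
  factor and noise, giving exact pairwise correlation ``rho`` within the
  block and zero elsewhere.

:func:`nested_subsample` mimics measuring fewer samples per gene: one random
permutation of the sample order is drawn and level ``k`` keeps the first
``sizes[k]`` samples, so every low-quality sample set is contained in every
higher-quality one.  :func:`partition_genes` shuffles genes once and cuts
consecutive disjoint groups, equivalent to a draw without replacement.

All randomness flows through a single root seed with per-purpose derived
streams, so e.g. changing the group count cannot perturb sample selection.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field

import numpy as np

from .expression import ExpressionMatrix

__all__ = [
    "NestedSampleSet",
    "EnsembleDesign",
    "derived_rng",
    "child_seed",
    "generate_random_expression",
    "generate_modular_expression",
    "nested_subsample",
    "partition_genes",
]

logger = logging.getLogger(__name__)


def derived_rng(seed: int, purpose: str) -> np.random.Generator:
    """Independent random stream for one purpose under a common root seed.

    The purpose label is hashed (crc32, stable across runs and platforms)
    and mixed into the seed sequence, so streams for different purposes are
    statistically independent while each remains a pure function of
    ``(seed, purpose)``.
    """
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), zlib.crc32(purpose.encode())])
    )


def child_seed(seed: int, index: int, purpose: str) -> int:
    """Deterministic per-unit (e.g. per-group) child seed below 2^31."""
    ss = np.random.SeedSequence([int(seed), int(index), zlib.crc32(purpose.encode())])
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


@dataclass(frozen=True)
class NestedSampleSet:
    """A full matrix plus nested reduced-quality views of it.

    ``levels`` maps sample count ("quality") to the subsampled matrix; the
    sample set at each quality is a subset of every higher quality and of
    the full set, and gene order is identical throughout.
    """

    full: ExpressionMatrix
    levels: dict[int, ExpressionMatrix] = field(repr=False)

    def __post_init__(self) -> None:
        prev: set[str] | None = None
        for size in sorted(self.levels):
            level = self.levels[size]
            if level.gene_ids != self.full.gene_ids:
                raise ValueError("gene_ids differ between nesting levels")
            cur = set(level.sample_ids)
            if prev is not None and not prev < cur:
                raise ValueError("sample sets are not strictly nested")
            prev = cur
        if prev is not None and not prev <= set(self.full.sample_ids):
            raise ValueError("level samples not drawn from the full matrix")

    @property
    def qualities(self) -> list[int]:
        return sorted(self.levels)


@dataclass(frozen=True)
class EnsembleDesign:
    """Disjoint-group design: ``n_groups`` groups of ``group_size`` genes."""

    n_groups: int = 20
    group_size: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_groups < 1 or self.group_size < 1:
            raise ValueError("n_groups and group_size must be positive")


def _gene_names(n: int) -> list[str]:
    width = len(str(n - 1))
    return [f"g{i:0{width}d}" for i in range(n)]


def _sample_names(n: int) -> list[str]:
    width = len(str(n - 1))
    return [f"s{i:0{width}d}" for i in range(n)]


def generate_random_expression(
    n_genes: int, n_samples: int, seed: int
) -> ExpressionMatrix:
    """I.i.d. uniform-[0,1] null expression data (no true co-expression)."""
    if n_genes < 2:
        raise ValueError(f"n_genes must be at least 2, got {n_genes}")
    if n_samples < 3:
        raise ValueError(f"n_samples must be at least 3, got {n_samples}")
    rng = derived_rng(seed, "uniform-null-draw")
    values = rng.random((n_genes, n_samples))
    return ExpressionMatrix(_gene_names(n_genes), _sample_names(n_samples), values)


def generate_modular_expression(
    n_genes: int,
    n_samples: int,
    block_sizes: list[int],
    within_block_correlation: float,
    seed: int,
) -> ExpressionMatrix:
    """Expression with planted correlated blocks under a one-factor model.

    Genes are laid out block by block from the top of the matrix; genes not
    covered by ``block_sizes`` are independent standard-normal noise.  The
    population correlation between two genes of the same block is exactly
    ``within_block_correlation`` (the shared-factor loading is its square
    root); across blocks it is zero.
    """
    rho = float(within_block_correlation)
    if not 0.0 <= rho < 1.0:
        raise ValueError(f"within_block_correlation must be in [0, 1), got {rho}")
    if n_genes < 2 or n_samples < 3:
        raise ValueError("need at least 2 genes and 3 samples")
    block_sizes = [int(b) for b in block_sizes]
    if any(b < 1 for b in block_sizes):
        raise ValueError("block sizes must be positive")
    if sum(block_sizes) > n_genes:
        raise ValueError(
            f"block sizes sum to {sum(block_sizes)} > n_genes = {n_genes}"
        )
    rng = derived_rng(seed, "modular-draw")
    values = rng.standard_normal((n_genes, n_samples))
    row = 0
    for size in block_sizes:
        factor = rng.standard_normal(n_samples)
        values[row : row + size] = (
            np.sqrt(rho) * factor + np.sqrt(1.0 - rho) * values[row : row + size]
        )
        row += size
    return ExpressionMatrix(_gene_names(n_genes), _sample_names(n_samples), values)


def nested_subsample(
    full: ExpressionMatrix, sizes: list[int], seed: int
) -> NestedSampleSet:
    """Draw nested reduced-sample views of ``full``.

    One permutation of the sample order is drawn; quality ``sizes[k]`` keeps
    the first ``sizes[k]`` permuted samples, guaranteeing that smaller sets
    are contained in larger ones.
    """
    sizes = [int(s) for s in sizes]
    if any(b <= a for a, b in zip(sizes, sizes[1:])):
        raise ValueError(f"sizes must be strictly increasing, got {sizes}")
    if sizes and sizes[-1] > full.n_samples:
        raise ValueError(
            f"requested {sizes[-1]} samples but only {full.n_samples} available"
        )
    rng = derived_rng(seed, "sample-shuffle")
    order = rng.permutation(full.n_samples)
    levels = {size: full.subset_samples(order[:size]) for size in sizes}
    return NestedSampleSet(full=full, levels=levels)


def partition_genes(
    matrix: ExpressionMatrix, design: EnsembleDesign
) -> list[ExpressionMatrix]:
    """Split genes into ``design.n_groups`` disjoint groups of ``group_size``.

    Gene order is randomised once (stream derived from ``design.seed``) and
    consecutive groups are cut; genes beyond ``n_groups × group_size`` are
    omitted (and logged), which is equivalent to drawing the groups without
    replacement.
    """
    needed = design.n_groups * design.group_size
    if needed > matrix.n_genes:
        raise ValueError(
            f"partition needs {needed} genes, matrix has {matrix.n_genes}"
        )
    rng = derived_rng(design.seed, "gene-shuffle")
    order = rng.permutation(matrix.n_genes)
    leftover = matrix.n_genes - needed
    if leftover:
        logger.info("partition_genes: omitting %d leftover genes", leftover)
    return [
        matrix.subset_genes(
            order[g * design.group_size : (g + 1) * design.group_size]
        )
        for g in range(design.n_groups)
    ]
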