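"""Gene-expression matrix container and tab-separated text IO.

The matrix convention throughout the package is genes as rows and samples as
columns, the dominant layout for GTEx-style expression tables.  Values are
arbitrary expression units; the pipeline takes them as given (no
normalisation or log transform is applied here).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["ExpressionMatrix", "read_expression", "write_expression"]


@dataclass(frozen=True)
class ExpressionMatrix:
    """An expression matrix: genes × samples with string identifiers.

    Parameters
    ----------
    gene_ids : list of str
        Unique row identifiers.
    sample_ids : list of str
        Unique column identifiers.
    values : ndarray of shape (n_genes, n_samples)
        Expression values; finite, no missing entries.

    Notes
    -----
    At least 3 samples are required, the minimum for a correlation to be
    defined on more than a degenerate number of points.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "gene_ids", [str(g) for g in self.gene_ids])
        object.__setattr__(self, "sample_ids", [str(s) for s in self.sample_ids])
        if values.ndim != 2:
            raise ValueError(f"values must be 2-D, got shape {values.shape}")
        n_genes, n_samples = values.shape
        if len(self.gene_ids) != n_genes:
            raise ValueError(
                f"{len(self.gene_ids)} gene_ids but {n_genes} rows of values"
            )
        if len(self.sample_ids) != n_samples:
            raise ValueError(
                f"{len(self.sample_ids)} sample_ids but {n_samples} columns of values"
            )
        if n_samples < 3:
            raise ValueError(
                f"at least 3 samples are required for correlation, got {n_samples}"
            )
        _check_unique(self.gene_ids, "gene")
        _check_unique(self.sample_ids, "sample")
        if not np.isfinite(values).all():
            bad = np.argwhere(~np.isfinite(values))[0]
            raise ValueError(
                "non-finite value at gene "
                f"{self.gene_ids[bad[0]]!r}, sample {self.sample_ids[bad[1]]!r}"
            )

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset_genes(self, indices: np.ndarray) -> "ExpressionMatrix":
        """Row subset preserving sample order."""
        idx = np.asarray(indices)
        return ExpressionMatrix(
            gene_ids=[self.gene_ids[i] for i in idx],
            sample_ids=list(self.sample_ids),
            values=self.values[idx, :],
        )

    def subset_samples(self, indices: np.ndarray) -> "ExpressionMatrix":
        """Column subset preserving gene order."""
        idx = np.asarray(indices)
        return ExpressionMatrix(
            gene_ids=list(self.gene_ids),
            sample_ids=[self.sample_ids[i] for i in idx],
            values=self.values[:, idx],
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.gene_ids, columns=self.sample_ids
        )


def _check_unique(ids: list[str], kind: str) -> None:
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise ValueError(f"duplicate {kind} ID: {i!r}")
        seen.add(i)


def read_expression(path: str | Path, transposed: bool = False) -> ExpressionMatrix:
    """Read a tab-separated expression table.

    First column holds gene IDs, first row sample IDs (set ``transposed=True``
    for samples-as-rows input).  Gzip-compressed files are accepted via the
    usual ``.gz`` suffix.

    Raises
    ------
    ValueError
        On duplicate gene IDs, ragged rows or non-numeric cells, with the
        offending row/column named.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0, header=0, dtype=str)
    if transposed:
        df = df.T
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"duplicate gene ID: {dup!r} in {path}")
    if df.isna().any().any():
        row = df.index[df.isna().any(axis=1)][0]
        raise ValueError(f"ragged or missing entries at gene {row!r} in {path}")
    try:
        values = df.to_numpy(dtype=float)
    except ValueError:
        for col in df.columns:
            bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
            if bad.any():
                row = df.index[bad][0]
                raise ValueError(
                    f"non-numeric cell at gene {row!r}, sample {col!r}: "
                    f"{df.loc[row, col]!r}"
                ) from None
        raise
    return ExpressionMatrix(
        gene_ids=list(df.index), sample_ids=list(df.columns), values=values
    )


def write_expression(path: str | Path, matrix: ExpressionMatrix) -> None:
    """Write the matrix as tab-separated text (round-trips with read_expression)."""
    matrix.to_frame().to_csv(Path(path), sep="\t", index_label="gene_id")
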