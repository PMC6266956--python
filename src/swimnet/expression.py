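"""Genes x samples expression matrix with two-condition sample labels.

The container is a thin validated wrapper around a pandas DataFrame
(rows = genes, columns = samples) plus a sample -> condition map with
exactly two condition labels, ``A`` and ``B``.  Values may be on linear
or log2 scale; the ``scale`` flag decides how fold-changes are computed
downstream (ratio of means vs difference of means).  Missing values are
rejected outright.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CONDITION_A = "A"
CONDITION_B = "B"
VALID_SCALES = ("linear", "log2")


@dataclass
class ExpressionMatrix:
    """Expression intensities for a set of genes over two sample groups.

    Parameters
    ----------
    values
        DataFrame of shape (n_genes, n_samples); index = gene ids,
        columns = sample ids.  Must be numeric with no NaN.
    condition
        Series mapping every sample id to ``"A"`` or ``"B"``; each
        condition must contain at least two samples.
    scale
        ``"linear"`` or ``"log2"``; declares the scale of ``values``.
    """

    values: pd.DataFrame
    condition: pd.Series
    scale: str = "log2"

    def __post_init__(self) -> None:
        if self.values.empty:
            raise ValueError("expression matrix is empty")
        if self.values.index.has_duplicates:
            dup = self.values.index[self.values.index.duplicated()][0]
            raise ValueError(f"duplicate gene id: {dup!r}")
        if self.values.columns.has_duplicates:
            dup = self.values.columns[self.values.columns.duplicated()][0]
            raise ValueError(f"duplicate sample id: {dup!r}")
        arr = self.values.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise ValueError("expression values must be numeric")
        if np.isnan(arr).any():
            raise ValueError("expression matrix contains NaN; missing values are not supported")
        if self.scale not in VALID_SCALES:
            raise ValueError(f"scale must be one of {VALID_SCALES}, got {self.scale!r}")
        self.condition = self.condition.reindex(self.values.columns)
        if self.condition.isna().any():
            missing = self.condition.index[self.condition.isna()][0]
            raise ValueError(f"sample {missing!r} has no condition label")
        bad = set(self.condition.unique()) - {CONDITION_A, CONDITION_B}
        if bad:
            raise ValueError(f"condition labels must be 'A'/'B', got {sorted(bad)}")
        for cond in (CONDITION_A, CONDITION_B):
            if int((self.condition == cond).sum()) < 2:
                raise ValueError(f"condition {cond!r} needs at least 2 samples")

    # -- accessors ---------------------------------------------------------

    @property
    def gene_ids(self) -> list:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        """Total number of samples S (condition A + condition B)."""
        return self.values.shape[1]

    def samples_in(self, cond: str) -> list:
        return list(self.condition.index[self.condition == cond])

    def values_in(self, cond: str) -> pd.DataFrame:
        """Submatrix restricted to samples of one condition."""
        return self.values[self.samples_in(cond)]

    def profile(self, gene_id) -> np.ndarray:
        if gene_id not in self.values.index:
            raise KeyError(f"gene {gene_id!r} not in matrix")
        return self.values.loc[gene_id].to_numpy(dtype=float)

    def subset_genes(self, gene_ids) -> "ExpressionMatrix":
        """Row-subset preserving sample labels and scale; order preserved."""
        missing = [g for g in gene_ids if g not in self.values.index]
        if missing:
            raise KeyError(f"gene {missing[0]!r} not in matrix")
        return ExpressionMatrix(
            values=self.values.loc[list(gene_ids)].copy(),
            condition=self.condition.copy(),
            scale=self.scale,
        )
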