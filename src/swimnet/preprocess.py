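"""Low-information gene filtering and differential expression.

Two sequential pre-processing filters remove genes that are mostly zero
or nearly constant across samples, then an unpaired two-tailed t-test
with Benjamini-Hochberg correction plus a log2 fold-change cutoff
selects the differentially expressed genes (DEGs) between condition A
and condition B.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .expression import CONDITION_A, CONDITION_B, ExpressionMatrix

DEG_COLUMNS = ["gene_id", "log_fc", "p_value", "fdr", "direction"]


class NoGenesError(ValueError):
    """Raised when a filtering stage leaves no genes."""


def gene_iqr(values: pd.DataFrame) -> pd.Series:
    """Per-gene inter-quartile range across samples (linear interpolation)."""
    arr = values.to_numpy(dtype=float)
    q75, q25 = np.percentile(arr, [75, 25], axis=1)
    return pd.Series(q75 - q25, index=values.index)


def filter_low_expression(
    matrix: ExpressionMatrix,
    max_zero_samples: int,
    iqr_percentile: float,
) -> ExpressionMatrix:
    """Drop genes that are mostly zero or vary too little across samples.

    The zero filter runs first: genes with more than ``max_zero_samples``
    zero entries are removed.  The IQR percentile is then computed over
    the surviving genes, and genes whose IQR falls below that percentile
    are removed.  Gene order is preserved.  Note the percentile stage is
    relative by construction: re-applying it to its own output removes
    the bottom of the *remaining* IQR distribution again, so only the
    zero-count stage (or ``iqr_percentile=0``) is idempotent.
    """
    if max_zero_samples < 0:
        raise ValueError("max_zero_samples must be >= 0")
    if max_zero_samples > matrix.n_samples:
        raise ValueError("max_zero_samples cannot exceed the sample count")
    if not 0 <= iqr_percentile <= 100:
        raise ValueError("iqr_percentile must be in [0, 100]")

    n_zero = (matrix.values == 0).sum(axis=1)
    survivors = matrix.values.index[n_zero <= max_zero_samples]
    if len(survivors) == 0:
        raise NoGenesError("no genes survive filtering (zero-count threshold)")

    iqrs = gene_iqr(matrix.values.loc[survivors])
    cutoff = float(np.percentile(iqrs.to_numpy(), iqr_percentile))
    kept = [g for g in survivors if iqrs[g] >= cutoff]
    if not kept:
        raise NoGenesError("no genes survive filtering (IQR threshold)")
    return matrix.subset_genes(kept)


def log_fold_change(matrix: ExpressionMatrix, gene_id) -> float:
    """log2 fold-change of the gene between condition A and condition B.

    Linear-scale input: log2(mean_A / mean_B); log2-scale input:
    mean_A - mean_B (the log of the ratio of geometric means).
    """
    prof = matrix.profile(gene_id)
    in_a = (matrix.condition == CONDITION_A).to_numpy()
    mean_a = float(prof[in_a].mean())
    mean_b = float(prof[~in_a].mean())
    if matrix.scale == "log2":
        return mean_a - mean_b
    if mean_b <= 0:
        raise ValueError(f"gene {gene_id!r}: mean expression in condition B must be > 0 on linear scale")
    ratio = mean_a / mean_b
    if ratio < 0:
        raise ValueError(f"gene {gene_id!r}: negative expression ratio is undefined on linear scale")
    with np.errstate(divide="ignore"):
        return float(np.log2(ratio))


def differential_expression(
    matrix: ExpressionMatrix,
    fc_threshold: float,
    fdr_threshold: float,
    equal_var: bool = True,
) -> pd.DataFrame:
    """Identify DEGs by |log2 FC| >= fc_threshold and BH-FDR < fdr_threshold.

    Per gene an unpaired two-tailed t-test (classic pooled-variance
    Student's t by default, Welch if ``equal_var=False``) compares the
    two conditions; BH adjustment runs over *all* tested genes before
    thresholding.  Degenerate genes with zero variance in both groups
    get p = 1 if the group means are equal, else p = 0.

    Returns a DataFrame with columns gene_id, log_fc, p_value, fdr,
    direction ('up' iff log_fc > 0, in condition A), sorted by gene_id.
    """
    a = matrix.values_in(CONDITION_A).to_numpy(dtype=float)
    b = matrix.values_in(CONDITION_B).to_numpy(dtype=float)
    if a.shape[1] < 2 or b.shape[1] < 2:
        raise ValueError("both conditions need at least 2 samples")

    with np.errstate(divide="ignore", invalid="ignore"):
        _, p = stats.ttest_ind(a, b, axis=1, equal_var=equal_var)
    p = np.asarray(p, dtype=float)

    mean_a, mean_b = a.mean(axis=1), b.mean(axis=1)
    degenerate = (a.var(axis=1) == 0) & (b.var(axis=1) == 0)
    p[degenerate & (mean_a == mean_b)] = 1.0
    p[degenerate & (mean_a != mean_b)] = 0.0

    if matrix.scale == "log2":
        lfc = mean_a - mean_b
    else:
        if np.any(mean_b <= 0):
            bad = matrix.values.index[np.flatnonzero(mean_b <= 0)[0]]
            raise ValueError(f"gene {bad!r}: mean expression in condition B must be > 0 on linear scale")
        with np.errstate(divide="ignore"):
            lfc = np.log2(mean_a / mean_b)

    fdr = multipletests(p, method="fdr_bh")[1]
    table = pd.DataFrame(
        {
            "gene_id": matrix.values.index,
            "log_fc": lfc,
            "p_value": p,
            "fdr": fdr,
            "direction": np.where(lfc > 0, "up", "down"),
        }
    )
    keep = (np.abs(table["log_fc"]) >= fc_threshold) & (table["fdr"] < fdr_threshold)
    out = table[keep].sort_values("gene_id", kind="mergesort").reset_index(drop=True)
    return out[DEG_COLUMNS]
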