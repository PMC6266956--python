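"""Median-split Kaplan-Meier screening with log-rank tests and BH correction.

For each gene, patients are split at the 50th percentile of its
expression into low- and high-expression groups, the two Kaplan-Meier
curves are compared with a log-rank test, and the p-values over the
whole gene list are BH-adjusted.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test
from statsmodels.stats.multitest import multipletests

from .expression import ExpressionMatrix

logger = logging.getLogger(__name__)

CLINICAL_COLUMNS = ["sample_id", "time", "event"]


class DegenerateSplitError(ValueError):
    """Raised when a median split cannot produce two nonempty groups."""


def validate_clinical(clinical: pd.DataFrame) -> pd.DataFrame:
    """Check a (sample_id, time, event) table and coerce dtypes."""
    missing = [c for c in CLINICAL_COLUMNS if c not in clinical.columns]
    if missing:
        raise ValueError(f"clinical table is missing column {missing[0]!r}")
    out = clinical[CLINICAL_COLUMNS].copy()
    if out["sample_id"].duplicated().any():
        dup = out["sample_id"][out["sample_id"].duplicated()].iloc[0]
        raise ValueError(f"duplicate sample id in clinical table: {dup!r}")
    out["time"] = out["time"].astype(float)
    out["event"] = out["event"].astype(int)
    if (out["time"] < 0).any():
        raise ValueError("survival times must be nonnegative")
    if not set(out["event"].unique()) <= {0, 1}:
        raise ValueError("event indicator must be 0 (censored) or 1 (death)")
    return out


def median_split(expr: pd.Series) -> pd.Series:
    """Split samples at the 50th percentile of expression.

    'low' = strictly below the percentile, 'high' = strictly above;
    samples exactly at the percentile go to the low group.  Requires at
    least 4 samples and a non-degenerate split (both groups nonempty).
    """
    values = expr.astype(float)
    if len(values) < 4:
        raise ValueError("median split needs at least 4 samples")
    threshold = float(np.percentile(values.to_numpy(), 50))
    labels = pd.Series(np.where(values > threshold, "high", "low"), index=values.index)
    if labels.nunique() < 2:
        raise DegenerateSplitError("expression does not separate at the median")
    return labels


class KMCurve:
    """Kaplan-Meier product-limit survival curve as a right-continuous step function."""

    def __init__(self, times, events):
        times = np.asarray(times, dtype=float)
        events = np.asarray(events, dtype=int)
        if times.size == 0:
            raise ValueError("empty cohort")
        if (times < 0).any():
            raise ValueError("survival times must be nonnegative")
        kmf = KaplanMeierFitter()
        kmf.fit(times, event_observed=events)
        sf = kmf.survival_function_
        self.times = sf.index.to_numpy(dtype=float)
        self.survival = sf.iloc[:, 0].to_numpy(dtype=float)
        self._kmf = kmf

    def __call__(self, t: float) -> float:
        """Survival probability S(t); S(0) = 1 and nonincreasing in t."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        if idx < 0:
            return 1.0
        return float(self.survival[idx])

    def as_series(self) -> pd.Series:
        return pd.Series(self.survival, index=self.times, name="survival")


def km_curve(times, events) -> KMCurve:
    """Fit the product-limit estimator with right-censoring."""
    return KMCurve(times, events)


def logrank_p(group_a: tuple, group_b: tuple) -> float:
    """Two-group log-rank test p-value (chi-square on 1 df).

    Each group is a (times, events) pair.  If neither group observed
    any event the curves are indistinguishable and p = 1 is returned
    with a warning.
    """
    times_a, events_a = (np.asarray(x) for x in group_a)
    times_b, events_b = (np.asarray(x) for x in group_b)
    if times_a.size == 0 or times_b.size == 0:
        raise ValueError("both groups must be nonempty")
    if events_a.sum() + events_b.sum() == 0:
        warnings.warn("no events observed in either group; log-rank p set to 1")
        return 1.0
    result = logrank_test(times_a, times_b, event_observed_A=events_a, event_observed_B=events_b)
    return float(result.p_value)


def survival_screen(
    expr,
    clinical: pd.DataFrame,
    genes,
) -> pd.DataFrame:
    """Median-split log-rank screen over a gene list.

    ``expr`` is a genes x samples DataFrame (or ExpressionMatrix).
    Samples missing from either table are dropped (count logged).
    Genes whose expression cannot be split at the median are reported
    with p = NaN and excluded from the BH adjustment.  Rows are sorted
    by ascending p-value (NaN last).
    """
    if isinstance(expr, ExpressionMatrix):
        expr = expr.values
    clinical = validate_clinical(clinical)
    shared = [s for s in expr.columns if s in set(clinical["sample_id"])]
    n_dropped = (len(expr.columns) - len(shared)) + (len(clinical) - len(shared))
    if n_dropped:
        logger.info("survival screen: dropped %d samples absent from one of the tables", n_dropped)
    if len(shared) < 4:
        raise ValueError("fewer than 4 samples shared between expression and clinical tables")
    clin = clinical.set_index("sample_id").loc[shared]

    genes = list(genes)
    present = [g for g in genes if g in expr.index]
    if not present:
        raise ValueError("none of the requested genes are in the expression table")
    if len(present) < len(genes):
        warnings.warn(f"{len(genes) - len(present)} genes absent from the expression table were skipped")

    rows = []
    for gene in present:
        values = expr.loc[gene, shared]
        try:
            labels = median_split(values)
        except DegenerateSplitError:
            rows.append({"gene": gene, "p_value": np.nan})
            continue
        low = labels.index[labels == "low"]
        high = labels.index[labels == "high"]
        p = logrank_p(
            (clin.loc[low, "time"], clin.loc[low, "event"]),
            (clin.loc[high, "time"], clin.loc[high, "event"]),
        )
        rows.append({"gene": gene, "p_value": p})

    table = pd.DataFrame(rows)
    table["fdr"] = np.nan
    tested = table["p_value"].notna()
    if tested.any():
        table.loc[tested, "fdr"] = multipletests(
            table.loc[tested, "p_value"].to_numpy(), method="fdr_bh"
        )[1]
    table = table.sort_values(["p_value", "gene"], kind="mergesort", na_position="last")
    return table.reset_index(drop=True)
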