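"""Normalization, low-signal filtering, and paired differential expression.

The candidate-gene stage: quantile-normalize the log2 matrix, drop genes whose
signal sits below the global lowest quartile in every sample, then run a paired
t-test on metastasis-minus-primary differences per gene with Benjamini-Hochberg
FDR control. A gene is a candidate when it clears all three thresholds
(|mean log2 FC| > 0.9, p < 0.05, q < 0.25 by default).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datatypes import InputError, PairedExpressionCohort

log = logging.getLogger(__name__)


def quantile_normalize(cohort: PairedExpressionCohort) -> PairedExpressionCohort:
    """Force every sample to share the across-sample mean order-statistic profile.

    Ties within a sample receive the mean of the reference values over the tied
    rank span, which makes the operation idempotent.
    """
    X = cohort.values.to_numpy(dtype=float)
    if X.shape[1] < 2:
        raise InputError("quantile normalization requires at least 2 samples")
    reference = np.sort(X, axis=0).mean(axis=1)

    out = np.empty_like(X)
    for j in range(X.shape[1]):
        col = X[:, j]
        order = np.argsort(col, kind="mergesort")
        assigned = np.empty_like(col)
        assigned[order] = reference
        # average the reference over tied spans
        out[:, j] = pd.Series(assigned).groupby(pd.Series(col)).transform("mean").to_numpy()
    values = pd.DataFrame(out, index=cohort.values.index, columns=cohort.values.columns)
    return cohort.with_values(values)


def filter_low_signal(
    cohort: PairedExpressionCohort, fraction: float = 1.0
) -> tuple[PairedExpressionCohort, list[str]]:
    """Remove genes consistently below the global lowest quartile.

    A gene is removed when it is strictly below the 25th percentile of all
    matrix values in at least ``fraction`` of samples (default: all samples,
    the strictest reading of "consistent"). Percentiles use linear
    interpolation between order statistics.

    Returns the retained-gene cohort and the list of removed genes.
    """
    if cohort.values.empty:
        raise InputError("cannot filter an empty matrix")
    X = cohort.values.to_numpy(dtype=float)
    q1 = np.percentile(X, 25)
    below_frac = (X < q1).mean(axis=1)
    removed_mask = below_frac >= fraction
    removed = cohort.values.index[removed_mask].tolist()
    kept = cohort.with_values(cohort.values.loc[~removed_mask])
    return kept, removed


def paired_de(
    cohort: PairedExpressionCohort,
    fc_min: float = 0.9,
    p_max: float = 0.05,
    q_max: float = 0.25,
) -> pd.DataFrame:
    """Per-gene paired t-test of metastasis vs primary log2 expression.

    For each gene, differences ``d_i = met_i - primary_i`` over the n cases give
    ``t = mean(d) / (sd(d)/sqrt(n))`` with the n-1 sample SD, two-sided p from
    the t distribution with n-1 df, and BH step-up q-values over all tested
    genes. Genes whose differences have zero variance get p = 1 (t undefined)
    and stay in the BH family so the multiple-testing denominator is not
    silently shrunk.

    Returns a DataFrame indexed by gene with columns ``mean_paired_log2fc``,
    ``t``, ``p``, ``q``, ``passes_filter``.
    """
    diffs = cohort.paired_diffs()
    n = diffs.shape[1]
    if n < 3:
        raise InputError(f"paired DE requires >= 3 complete pairs, got {n}")

    d = diffs.to_numpy(dtype=float)
    mean = d.mean(axis=1)
    sd = d.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 1)

    zero_var = sd == 0
    t = np.where(zero_var, np.nan, t)
    p = np.where(zero_var, 1.0, p)

    _, q, _, _ = multipletests(p, method="fdr_bh")
    passes = (q < q_max) & (p < p_max) & (np.abs(mean) > fc_min)

    return pd.DataFrame(
        {
            "mean_paired_log2fc": mean,
            "t": t,
            "p": p,
            "q": q,
            "passes_filter": passes,
        },
        index=diffs.index.rename("gene"),
    )


def candidate_list(de: pd.DataFrame) -> pd.DataFrame:
    """Passing genes with their metastasis direction, sorted by ascending p."""
    hits = de[de["passes_filter"]].copy()
    if hits.empty:
        log.warning("no genes pass the differential-expression filter")
    hits["met_direction"] = np.where(hits["mean_paired_log2fc"] > 0, "up", "down")
    hits = hits.sort_values("p", kind="mergesort")
    return hits[["mean_paired_log2fc", "t", "p", "q", "met_direction"]]


@dataclass
class DEResults:
    """Fitted paired differential-expression results."""

    table: pd.DataFrame
    removed_genes: list[str]
    thresholds: dict

    @property
    def n_up(self) -> int:
        hits = self.table[self.table["passes_filter"]]
        return int((hits["mean_paired_log2fc"] > 0).sum())

    @property
    def n_down(self) -> int:
        hits = self.table[self.table["passes_filter"]]
        return int((hits["mean_paired_log2fc"] < 0).sum())

    def candidates(self) -> pd.DataFrame:
        return candidate_list(self.table)

    def summary(self) -> str:
        th = self.thresholds
        lines = [
            "Paired differential expression (metastasis vs primary)",
            "=" * 56,
            f"genes tested:            {len(self.table)}",
            f"genes removed (low sig): {len(self.removed_genes)}",
            f"thresholds:              |log2FC| > {th['fc_min']}, "
            f"p < {th['p_max']}, q < {th['q_max']}",
            f"up-regulated in mets:    {self.n_up}",
            f"down-regulated in mets:  {self.n_down}",
        ]
        return "\n".join(lines)


class PairedDifferentialExpression:
    """Paired DE model over a matched primary/metastasis cohort.

    Parameters
    ----------
    cohort : PairedExpressionCohort
    normalize : bool
        Quantile-normalize before testing (default True).
    low_signal_filter : bool
        Drop genes consistently below the global lowest quartile (default True).
    """

    def __init__(
        self,
        cohort: PairedExpressionCohort,
        normalize: bool = True,
        low_signal_filter: bool = True,
    ):
        self.cohort = cohort
        self.normalize = normalize
        self.low_signal_filter = low_signal_filter

    def fit(
        self, fc_min: float = 0.9, p_max: float = 0.05, q_max: float = 0.25
    ) -> DEResults:
        cohort = self.cohort
        if self.normalize:
            cohort = quantile_normalize(cohort)
        removed: list[str] = []
        if self.low_signal_filter:
            cohort, removed = filter_low_signal(cohort)
        table = paired_de(cohort, fc_min=fc_min, p_max=p_max, q_max=q_max)
        return DEResults(
            table=table,
            removed_genes=removed,
            thresholds={"fc_min": fc_min, "p_max": p_max, "q_max": q_max},
        )
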