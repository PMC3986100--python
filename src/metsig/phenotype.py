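"""Staining statistics and Ki-67-correlated gene ranking.

Percent-positive staining (Ki-67 proliferation index, TUNEL apoptotic index)
is approximately log-normal, so paired tests compare log-transformed
percentages between matched metastasis and primary tissue. A companion
operation ranks genes by the Pearson correlation of their paired expression
change with the paired change in Ki-67 staining, to ask which expression
changes track proliferation of the cancer cells themselves.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .datatypes import METASTASIS, PRIMARY, InputError, PairedExpressionCohort

log = logging.getLogger(__name__)


def _paired_percent(table: pd.DataFrame) -> pd.DataFrame:
    """Pivot a (case, tissue, percent) staining table to cases x tissues."""
    for col in ("case", "tissue", "percent"):
        if col not in table.columns:
            raise InputError(f"staining table missing column {col!r}")
    if (table["percent"] < 0).any() or (table["percent"] > 100).any():
        raise InputError("percent values must be in [0, 100]")
    wide = table.pivot_table(index="case", columns="tissue", values="percent")
    wide = wide.dropna(subset=[PRIMARY, METASTASIS])
    return wide


@dataclass
class PairedLogTestResult:
    n: int
    n_higher_in_met: int
    t: float
    p: float
    normality_p_raw: float
    normality_p_log: float
    zeros_replaced: int

    def summary(self) -> str:
        return (
            f"paired log-scale t-test: n={self.n}, higher in metastasis "
            f"{self.n_higher_in_met}/{self.n}, t={self.t:.3f}, p={self.p:.4g} "
            f"(Shapiro-Wilk raw diff p={self.normality_p_raw:.3g}, "
            f"log diff p={self.normality_p_log:.3g})"
        )


def paired_log_test(table: pd.DataFrame) -> PairedLogTestResult:
    """Paired t-test of log-transformed staining percentages, met vs primary.

    Zero percentages are replaced by half the smallest positive value before
    the log transform (flagged in the result). Shapiro-Wilk normality p-values
    are reported for both raw and log-scale paired differences. When every
    pair is identical the test is degenerate and reported as no difference
    (t = 0, p = 1).
    """
    wide = _paired_percent(table)
    n = len(wide)
    if n < 3:
        raise InputError(f"need >= 3 complete pairs, got {n}")

    vals = wide[[PRIMARY, METASTASIS]].to_numpy(dtype=float)
    zeros = int((vals == 0).sum())
    if zeros:
        positive_min = vals[vals > 0].min()
        vals = np.where(vals == 0, positive_min / 2.0, vals)
        log.info("replaced %d zero percentages by %g", zeros, positive_min / 2.0)

    raw_diff = wide[METASTASIS].to_numpy() - wide[PRIMARY].to_numpy()
    log_vals = np.log(vals)
    log_diff = log_vals[:, 1] - log_vals[:, 0]

    def _shapiro(x: np.ndarray) -> float:
        if np.ptp(x) == 0:
            return np.nan
        return float(stats.shapiro(x).pvalue)

    n_higher = int(np.sum(raw_diff > 0))
    if np.ptp(log_diff) == 0 and log_diff[0] == 0:
        return PairedLogTestResult(
            n=n, n_higher_in_met=n_higher, t=0.0, p=1.0,
            normality_p_raw=_shapiro(raw_diff), normality_p_log=_shapiro(log_diff),
            zeros_replaced=zeros,
        )
    if np.std(log_diff, ddof=1) == 0:
        # identical nonzero shift in every pair: direction certain, t undefined
        t_stat, p = np.inf if log_diff[0] > 0 else -np.inf, 0.0
    else:
        res = stats.ttest_rel(log_vals[:, 1], log_vals[:, 0])
        t_stat, p = float(res.statistic), float(res.pvalue)
    return PairedLogTestResult(
        n=n, n_higher_in_met=n_higher, t=t_stat, p=p,
        normality_p_raw=_shapiro(raw_diff), normality_p_log=_shapiro(log_diff),
        zeros_replaced=zeros,
    )


def ki67_correlated_genes(
    cohort: PairedExpressionCohort,
    table: pd.DataFrame,
    top_n: int = 250,
    log_delta: bool = False,
) -> pd.DataFrame:
    """Rank genes by Pearson correlation of paired expression change with
    paired Ki-67 change.

    Per gene, r is computed across shared cases between the metastasis-minus-
    primary log2 expression difference and the metastasis-minus-primary Ki-67
    percent difference (raw percent scale by default; ``log_delta=True``
    correlates against the log-scale difference instead). Genes with
    zero-variance expression differences are excluded. Returns the ``top_n``
    genes by descending signed r with columns ``r`` and ``rank``.
    """
    wide = _paired_percent(table)
    dexpr = cohort.paired_diffs()
    shared = [c for c in dexpr.columns if c in wide.index]
    if len(shared) < 4:
        raise InputError(f"need >= 4 shared cases, got {len(shared)}")
    dexpr = dexpr[shared]
    if log_delta:
        vals = wide.loc[shared, [PRIMARY, METASTASIS]].to_numpy(dtype=float)
        positive_min = vals[vals > 0].min() if (vals > 0).any() else 1.0
        vals = np.where(vals == 0, positive_min / 2.0, vals)
        dki = np.log(vals[:, 1]) - np.log(vals[:, 0])
    else:
        dki = (wide.loc[shared, METASTASIS] - wide.loc[shared, PRIMARY]).to_numpy()

    X = dexpr.to_numpy(dtype=float)
    xc = X - X.mean(axis=1, keepdims=True)
    yc = dki - dki.mean()
    sx = np.sqrt((xc**2).sum(axis=1))
    sy = np.sqrt((yc**2).sum())
    ok = (sx > 0) & (sy > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (xc @ yc) / (sx * sy)
    result = pd.DataFrame({"r": r}, index=dexpr.index)[ok]
    result = result.sort_values("r", ascending=False, kind="mergesort")
    if top_n > len(result):
        log.warning("top_n=%d exceeds %d rankable genes; returning all",
                    top_n, len(result))
        top_n = len(result)
    result = result.head(top_n)
    result["rank"] = np.arange(1, len(result) + 1)
    return result


@dataclass
class ExpressionClustering:
    linkage: np.ndarray
    samples: list[str]
    excluded: list[str]
    cluster_labels: pd.Series        # 1/2 cluster per sample at the 2-cut
    separation_fraction: float       # best agreement of the 2-cut with tissues

    def summary(self) -> str:
        return (
            f"expression clustering of {len(self.samples)} samples: "
            f"2-cluster cut separates tissues at fraction "
            f"{self.separation_fraction:.2f}"
        )


def cluster_expression(
    expr: pd.DataFrame, tissue_labels: pd.Series
) -> ExpressionClustering:
    """Cluster samples on a gene subset and score primary/metastasis separation.

    1 - Pearson distance with average linkage; the dendrogram's two-cluster
    cut is compared with the tissue labels and the best label matching's
    accuracy is the separation fraction (1.0 = perfect separation, ~0.5 =
    chance for balanced designs).
    """
    if expr.shape[1] < 4:
        raise InputError("clustering requires >= 4 samples")
    variances = expr.std(axis=0)
    excluded = variances.index[variances == 0].tolist()
    if excluded:
        log.warning("excluding zero-variance samples: %s", excluded)
    kept = [s for s in expr.columns if s not in set(excluded)]
    X = expr[kept].to_numpy(dtype=float).T
    Z = hierarchy.linkage(pdist(X, metric="correlation"), method="average")
    labels = hierarchy.fcluster(Z, t=2, criterion="maxclust")
    tissues = tissue_labels.loc[kept].to_numpy()
    is_met = tissues == METASTASIS
    acc1 = float(np.mean((labels == 1) == is_met))
    separation = max(acc1, 1.0 - acc1)
    return ExpressionClustering(
        linkage=Z,
        samples=kept,
        excluded=excluded,
        cluster_labels=pd.Series(labels, index=kept),
        separation_fraction=separation,
    )
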