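"""Kaplan-Meier estimation, log-rank testing, and signature evaluation.

KM curves (with Greenwood variance and log-log median confidence bands) come
from lifelines. The two-group log-rank test is implemented here as a
vectorised O(n log n) routine because the empirical-null stage evaluates it
tens of thousands of times per run; it follows the standard form — at each
event time the observed events in one group minus the hypergeometric
expectation, summed and divided by the summed hypergeometric variance, with a
1-df chi-square reference. Ties follow the usual risk-set convention
(patients censored at t remain at risk for events at t).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.utils import median_survival_times
from scipy import stats

from .datatypes import InputError, Signature, SurvivalCohort

log = logging.getLogger(__name__)


@dataclass
class KMCurve:
    """A fitted product-limit curve."""

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    median: float            # inf when the curve never reaches 0.5
    median_ci: tuple[float, float]
    n: int
    n_events: int

    @property
    def median_reached(self) -> bool:
        return np.isfinite(self.median)


def km_fit(cohort: SurvivalCohort, endpoint: str = "OS") -> KMCurve:
    """Kaplan-Meier product-limit estimator with median and 95% CI.

    The median is the smallest time with S(t) <= 0.5; when the curve never
    reaches 0.5 (e.g. everything censored) it is reported as not reached
    (``inf``). The median CI inverts log-log transformed pointwise bands.
    """
    time, event = cohort.endpoint(endpoint)
    if len(time) == 0:
        raise InputError("empty cohort")
    kmf = KaplanMeierFitter()
    kmf.fit(time, event_observed=event)
    ci = median_survival_times(kmf.confidence_interval_)
    lo, hi = float(ci.iloc[0, 0]), float(ci.iloc[0, 1])
    sf = kmf.survival_function_
    event_table = kmf.event_table
    return KMCurve(
        times=sf.index.to_numpy(dtype=float),
        survival=sf.iloc[:, 0].to_numpy(dtype=float),
        at_risk=event_table["at_risk"].to_numpy(dtype=float),
        median=float(kmf.median_survival_time_),
        median_ci=(lo, hi),
        n=len(time),
        n_events=int(np.sum(event)),
    )


@dataclass
class LogrankResult:
    statistic: float
    p: float
    observed_a: float
    expected_a: float


def fast_logrank(
    time: np.ndarray, event: np.ndarray, in_a: np.ndarray
) -> tuple[float, float]:
    """Two-group log-rank chi-square and p for a boolean group-a mask.

    Degenerate inputs (no events, or zero variance because one group is empty
    at every event time) return statistic 0 and p 1.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    in_a = np.asarray(in_a, dtype=bool)

    order = np.argsort(time, kind="mergesort")
    t, e, a = time[order], event[order], in_a[order]
    n = len(t)

    # unique event times and per-time counts
    is_event = e == 1
    if not is_event.any():
        return 0.0, 1.0
    uniq = np.unique(t[is_event])

    # at-risk counts just before each unique event time
    seg_starts = np.searchsorted(t, uniq, side="left")
    seg_ends = np.searchsorted(t, uniq, side="right")
    n_at_risk = n - seg_starts
    a_cum = np.concatenate([[0], np.cumsum(a)])
    n_a_at_risk = a.sum() - a_cum[seg_starts]

    # events per unique time, total and in group a
    cev = np.concatenate([[0.0], np.cumsum(is_event.astype(float))])
    cev_a = np.concatenate([[0.0], np.cumsum((is_event & a).astype(float))])
    d_total = cev[seg_ends] - cev[seg_starts]
    d_a = cev_a[seg_ends] - cev_a[seg_starts]

    with np.errstate(divide="ignore", invalid="ignore"):
        exp_a = d_total * n_a_at_risk / n_at_risk
        var = (
            d_total
            * (n_a_at_risk / n_at_risk)
            * (1.0 - n_a_at_risk / n_at_risk)
            * (n_at_risk - d_total)
            / np.maximum(n_at_risk - 1.0, 1.0)
        )
    var = np.where(n_at_risk > 1, var, 0.0)
    O = d_a.sum()
    E = exp_a.sum()
    V = var.sum()
    if V <= 0:
        return 0.0, 1.0
    chi2 = (O - E) ** 2 / V
    return float(chi2), float(stats.chi2.sf(chi2, df=1))


def logrank_test(a: SurvivalCohort, b: SurvivalCohort, endpoint: str = "OS") -> LogrankResult:
    """Standard two-group log-rank test between cohorts ``a`` and ``b``."""
    if a.n == 0 or b.n == 0:
        raise InputError("both groups must be nonempty")
    ta, ea = a.endpoint(endpoint)
    tb, eb = b.endpoint(endpoint)
    time = np.concatenate([ta, tb])
    event = np.concatenate([ea, eb])
    in_a = np.concatenate([np.ones(len(ta), bool), np.zeros(len(tb), bool)])
    chi2, p = fast_logrank(time, event, in_a)

    # observed / expected for reporting
    obs_a = float(np.sum(ea))
    # recompute expectation with the same machinery
    order = np.argsort(time, kind="mergesort")
    t, e, aa = time[order], event[order], in_a[order]
    uniq = np.unique(t[e == 1])
    seg = np.searchsorted(t, uniq, side="left")
    n_at_risk = len(t) - seg
    n_a = aa.sum() - np.concatenate([[0], np.cumsum(aa)])[seg]
    segr = np.searchsorted(t, uniq, side="right")
    cev = np.concatenate([[0.0], np.cumsum((e == 1).astype(float))])
    d_total = cev[segr] - cev[seg]
    exp_a = float(np.sum(d_total * n_a / n_at_risk))
    return LogrankResult(statistic=chi2, p=p, observed_a=obs_a, expected_a=exp_a)


@dataclass
class SignatureEvaluation:
    """Per-dataset / per-stratum KM comparison of the signature's risk groups."""

    table: pd.DataFrame
    curves: dict = field(default_factory=dict)  # (dataset, stratum) -> (km_high, km_low)

    def summary(self) -> str:
        lines = ["Signature survival evaluation", "=" * 72]
        with pd.option_context("display.width", 120):
            lines.append(self.table.to_string(index=False))
        return "\n".join(lines)


def _fmt_strata(strata):
    return tuple(strata) if strata else ("all",)


def evaluate_signature(
    datasets: dict[str, tuple[pd.DataFrame, SurvivalCohort]],
    sig: Signature,
    endpoint: str = "OS",
    strata: tuple[str, ...] = ("all",),
    treated_col: str = "treated",
) -> SignatureEvaluation:
    """Score each dataset and compare high vs low risk survival per stratum.

    For every dataset the treatment filter is applied first, then patients are
    scored (median cutpoints computed on the treatment-filtered cohort), then
    each stratum (``all`` | ``no-residual`` | ``residual``) is filtered and a
    KM pair plus log-rank p is produced. Strata with fewer than 2 patients in
    either risk group are skipped with a warning.
    """
    from .signature import score_patients

    rows = []
    curves: dict = {}
    for name, (expr, surv) in datasets.items():
        clin = surv.clinical
        if treated_col in clin.columns:
            treated_mask = clin[treated_col] == 1
        else:
            treated_mask = pd.Series(True, index=clin.index)
        cohort = surv.subset(treated_mask)
        expr_t = expr.loc[:, cohort.clinical.index]
        risk = score_patients(expr_t, sig)
        high = risk.high_mask()

        for stratum in _fmt_strata(strata):
            if stratum == "all":
                smask = pd.Series(True, index=cohort.clinical.index)
            elif stratum in ("no-residual", "no_residual"):
                smask = cohort.clinical["residual_disease"] == 0
            elif stratum == "residual":
                smask = cohort.clinical["residual_disease"] == 1
            else:
                raise InputError(f"unknown stratum {stratum!r}")

            hi_mask = smask & high
            lo_mask = smask & ~high
            if hi_mask.sum() < 2 or lo_mask.sum() < 2:
                log.warning(
                    "dataset %s stratum %s skipped: <2 patients in a risk group",
                    name,
                    stratum,
                )
                continue
            hi = cohort.subset(hi_mask)
            lo = cohort.subset(lo_mask)
            km_hi = km_fit(hi, endpoint)
            km_lo = km_fit(lo, endpoint)
            lr = logrank_test(hi, lo, endpoint)
            curves[(name, stratum)] = (km_hi, km_lo)
            rows.append(
                {
                    "dataset": name,
                    "stratum": stratum,
                    "endpoint": endpoint,
                    "n_high": hi.n,
                    "n_low": lo.n,
                    "median_high": km_hi.median,
                    "median_high_lo": km_hi.median_ci[0],
                    "median_high_hi": km_hi.median_ci[1],
                    "median_low": km_lo.median,
                    "median_low_lo": km_lo.median_ci[0],
                    "median_low_hi": km_lo.median_ci[1],
                    "logrank_p": lr.p,
                }
            )
    return SignatureEvaluation(table=pd.DataFrame(rows), curves=curves)
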