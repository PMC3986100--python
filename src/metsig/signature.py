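"""Median-vote signature scoring, per-gene Cox screening, and signature selection.

The vote score: for every signature gene the cohort median expression is the
cutpoint; a patient gains one point per up-in-metastasis gene expressed
strictly above its median and per down-in-metastasis gene strictly below it.
Patients scoring above the high-risk threshold (default floor(k/2); >3 points
for the canonical six-gene set) form the high-risk group. Because the rule
only uses order statistics and strict comparisons, scores are invariant to any
strictly monotone per-gene transform of expression.
"""
from __future__ import annotations

import itertools
import logging
import math

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter

from .datatypes import (
    InputError,
    RiskAssignment,
    Signature,
    SignatureGene,
    SurvivalCohort,
)
from .survival import fast_logrank

log = logging.getLogger(__name__)

# The published six-gene metastatic expression signature (gene symbols).
CANONICAL_SIGNATURE_GENES = ("CALB2", "CYP1B1", "EFTUD1", "IL7R", "RARRES2", "TIMP3")
CANONICAL_THRESHOLD = 3


def canonical_signature(directions: dict[str, str]) -> Signature:
    """The published six-gene signature with user-supplied metastasis directions.

    The published gene table lists the six genes but not their per-gene
    direction of change in metastases, so directions must come from a paired
    differential-expression run (or other training data) before scoring.
    """
    missing = set(CANONICAL_SIGNATURE_GENES) - set(directions)
    if missing:
        raise InputError(f"directions missing for genes: {sorted(missing)}")
    genes = [SignatureGene(g, directions[g]) for g in CANONICAL_SIGNATURE_GENES]
    return Signature(genes=genes, high_risk_threshold=CANONICAL_THRESHOLD)


def score_patients(expr: pd.DataFrame, sig: Signature) -> RiskAssignment:
    """Vote-score every patient of a cohort against per-cohort median cutpoints.

    Parameters
    ----------
    expr : DataFrame
        genes x patients log expression; must contain every signature gene.
    sig : Signature

    Notes
    -----
    Ties at the median contribute no point (strict inequalities), so a patient
    sitting exactly at every median scores 0 and is low risk.
    """
    absent = [g for g in sig.gene_ids if g not in expr.index]
    if absent:
        raise InputError(f"signature genes absent from expression matrix: {absent}")
    if expr.shape[1] < 2:
        raise InputError("scoring requires >= 2 patients (median degenerate)")

    sub = expr.loc[sig.gene_ids]
    cutpoints = sub.median(axis=1)
    up = np.array([g.met_direction == "up" for g in sig.genes])

    above = sub.gt(cutpoints, axis=0).to_numpy()
    below = sub.lt(cutpoints, axis=0).to_numpy()
    points = np.where(up[:, None], above, below)
    scores = points.sum(axis=0)

    table = pd.DataFrame(
        {
            "score": scores,
            "group": np.where(scores > sig.high_risk_threshold, "high", "low"),
        },
        index=expr.columns.rename("patient"),
    )
    return RiskAssignment(table=table, cutpoints=cutpoints, threshold=sig.high_risk_threshold)


def cox_screen(
    expr: pd.DataFrame,
    surv: SurvivalCohort,
    genes: list[str] | None = None,
    p_threshold: float = 0.05,
    endpoint: str = "OS",
) -> pd.DataFrame:
    """Univariate Cox proportional-hazards screen per gene on continuous expression.

    Fits one Cox model per gene (partial likelihood, Efron tie handling) and
    flags genes with Wald p below ``p_threshold``. Non-converging or
    degenerate fits are kept in the output with ``converged = False`` and
    excluded from the significant set.

    Returns a DataFrame indexed by gene: ``coef``, ``se``, ``p``,
    ``significant``, ``converged``.
    """
    if genes is None:
        genes = list(expr.index)
    absent = [g for g in genes if g not in expr.index]
    if absent:
        raise InputError(f"genes absent from expression matrix: {absent}")
    time, event = surv.endpoint(endpoint)
    if int(np.sum(event)) < 10:
        raise InputError(
            f"Cox screen requires >= 10 events, got {int(np.sum(event))}"
        )
    expr = expr.loc[:, surv.clinical.index]

    rows = []
    for gene in genes:
        df = pd.DataFrame(
            {"time": time, "event": event, "x": expr.loc[gene].to_numpy(dtype=float)}
        )
        try:
            cph = CoxPHFitter()
            cph.fit(df, duration_col="time", event_col="event")
            coef = float(cph.params_["x"])
            se = float(cph.standard_errors_["x"])
            p = float(cph.summary.loc["x", "p"])
            converged = np.isfinite(coef) and np.isfinite(se)
        except Exception as exc:  # ConvergenceError, monotone likelihood, singular fits
            log.warning("Cox fit failed for gene %s: %s", gene, exc)
            coef, se, p, converged = np.nan, np.nan, np.nan, False
        rows.append(
            {
                "gene": gene,
                "coef": coef,
                "se": se,
                "p": p,
                "converged": converged,
                "significant": bool(converged and p < p_threshold),
            }
        )
    return pd.DataFrame(rows).set_index("gene")


def _subset_criterion(
    gene_ids: tuple[str, ...],
    directions: pd.Series,
    datasets: list[tuple[pd.DataFrame, SurvivalCohort]],
    endpoint: str = "OS",
) -> float:
    """Max log-rank p across datasets for a candidate gene subset (lower = better)."""
    sig = Signature(
        genes=[SignatureGene(g, directions[g]) for g in gene_ids],
        high_risk_threshold=len(gene_ids) // 2,
    )
    worst = 0.0
    for expr, surv in datasets:
        risk = score_patients(expr.loc[:, surv.clinical.index], sig)
        high = risk.high_mask().to_numpy()
        if high.all() or (~high).all():
            p = 1.0  # degenerate grouping cannot support the subset
        else:
            time, event = surv.endpoint(endpoint)
            _, p = fast_logrank(time, event, high)
        worst = max(worst, p)
    return worst


def select_signature(
    candidates: pd.DataFrame,
    datasets: list[tuple[pd.DataFrame, SurvivalCohort]],
    k: int = 6,
    screen_p: float = 0.05,
    exhaustive_cap: int = 5000,
    endpoint: str = "OS",
) -> Signature:
    """Derive a k-gene signature from DE candidates across survival datasets.

    Candidate genes (rows indexed by gene with a ``met_direction`` column) are
    first screened by univariate Cox in the training dataset (the first one);
    among the retained genes, every size-k subset is scored by the *maximum*
    log-rank p over all datasets of the high-vs-low KM comparison, and the
    subset minimising that maximum wins. When C(n, k) exceeds
    ``exhaustive_cap`` a greedy forward search is used instead; ties break on
    lexicographic gene order. With fewer than k retained genes, all retained
    genes are returned with a warning.
    """
    if not datasets:
        raise InputError("at least one dataset is required")
    if candidates.empty:
        raise InputError("candidate list is empty")
    directions = candidates["met_direction"]

    train_expr, train_surv = datasets[0]
    genes = [g for g in candidates.index if g in train_expr.index]
    screen = cox_screen(train_expr, train_surv, genes, p_threshold=screen_p,
                        endpoint=endpoint)
    retained = sorted(screen.index[screen["significant"]])
    log.info("Cox screen retained %d/%d candidate genes", len(retained), len(genes))

    if len(retained) <= k:
        if len(retained) < k:
            log.warning(
                "only %d genes retained (< k=%d); returning all retained genes",
                len(retained),
                k,
            )
        chosen = tuple(retained)
    elif math.comb(len(retained), k) <= exhaustive_cap:
        best, best_p = None, np.inf
        for combo in itertools.combinations(retained, k):  # lexicographic order
            p = _subset_criterion(combo, directions, datasets, endpoint)
            if p < best_p:
                best, best_p = combo, p
        chosen = best
    else:
        chosen_list: list[str] = []
        remaining = list(retained)
        while len(chosen_list) < k:
            best_gene, best_p = None, np.inf
            for g in remaining:  # lexicographic; strict < keeps first on ties
                p = _subset_criterion(
                    tuple(chosen_list + [g]), directions, datasets, endpoint
                )
                if p < best_p:
                    best_gene, best_p = g, p
            chosen_list.append(best_gene)
            remaining.remove(best_gene)
        chosen = tuple(chosen_list)

    genes_out = [SignatureGene(g, directions[g]) for g in chosen]
    threshold = len(genes_out) // 2 if genes_out else 0
    if len(genes_out) == 6:
        threshold = CANONICAL_THRESHOLD
    return Signature(genes=genes_out, high_risk_threshold=threshold)
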