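"""Random gene-set specificity null for the signature's log-rank p.

How specific is the signature? Draw many random same-size gene sets, run each
through the identical median-vote scoring and log-rank machinery, and report
the proportion of random sets achieving a strictly lower log-rank p than the
observed signature. A random set that produces a degenerate grouping (all
patients in one risk group) is recorded with p = 1 — it cannot beat the
observed signature but still counts in the denominator.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import InputError, Signature, SignatureGene, SurvivalCohort
from .signature import score_patients
from .survival import fast_logrank


def random_signature(
    universe: list[str],
    k: int,
    rng: np.random.Generator,
    direction_mode: str = "random",
    directions: dict[str, str] | None = None,
    threshold: int | None = None,
) -> Signature:
    """Sample k distinct genes uniformly and orient them per the chosen mode.

    ``direction_mode='random'`` (default) assigns each gene an independent
    uniform up/down direction; ``'fixed'`` looks directions up in the supplied
    mapping (e.g. training Cox signs).
    """
    if len(universe) < k:
        raise InputError(f"universe has {len(universe)} genes, need >= {k}")
    if direction_mode not in ("random", "fixed"):
        raise InputError(f"unknown direction_mode {direction_mode!r}")
    chosen = list(rng.choice(np.asarray(universe, dtype=object), size=k, replace=False))
    genes = []
    for g in chosen:
        if direction_mode == "random":
            d = "up" if rng.random() < 0.5 else "down"
        else:
            if directions is None or g not in directions:
                raise InputError(f"direction for gene {g!r} not supplied")
            d = directions[g]
        genes.append(SignatureGene(str(g), d))
    return Signature(genes=genes, high_risk_threshold=threshold)


def empirical_p_from(
    observed_p: float, random_ps: np.ndarray, add_one: bool = False
) -> float:
    """Proportion of random p-values strictly below the observed one.

    ``add_one=True`` uses the (n_lower + 1) / (n_random + 1) convention that
    avoids exact zeros.
    """
    random_ps = np.asarray(random_ps, dtype=float)
    n_lower = int(np.sum(random_ps < observed_p))
    if add_one:
        return (n_lower + 1) / (len(random_ps) + 1)
    return n_lower / len(random_ps)


@dataclass
class EmpiricalNullResult:
    observed_p: float
    n_random: int
    n_lower: int
    empirical_p: float
    random_p_values: np.ndarray
    seed: int | None
    direction_mode: str
    add_one: bool

    def summary(self) -> str:
        lines = [
            "Random gene-set specificity null",
            "=" * 40,
            f"observed log-rank p:   {self.observed_p:.4g}",
            f"random sets evaluated: {self.n_random}",
            f"sets with lower p:     {self.n_lower}",
            f"empirical p:           {self.empirical_p:.4g}"
            + (" (add-one)" if self.add_one else ""),
            f"direction mode:        {self.direction_mode}",
        ]
        return "\n".join(lines)


class EmpiricalNull:
    """Specificity-null model for a signature on one expression/survival dataset.

    Parameters
    ----------
    expr : DataFrame
        genes x patients expression including the signature genes and the
        random-set universe.
    surv : SurvivalCohort aligned to ``expr`` columns.
    sig : Signature whose observed log-rank p is being calibrated.
    universe : optional explicit gene universe for random sets; defaults to
        all genes in ``expr`` not in the signature.
    """

    def __init__(
        self,
        expr: pd.DataFrame,
        surv: SurvivalCohort,
        sig: Signature,
        universe: list[str] | None = None,
        endpoint: str = "OS",
    ):
        self.expr = expr.loc[:, surv.clinical.index]
        self.surv = surv
        self.sig = sig
        self.endpoint = endpoint
        if universe is None:
            universe = [g for g in expr.index if g not in set(sig.gene_ids)]
        self.universe = list(universe)

    def _group_p(self, high: np.ndarray, time: np.ndarray, event: np.ndarray) -> float:
        if high.all() or (~high).all():
            return 1.0
        _, p = fast_logrank(time, event, high)
        return p

    def fit(
        self,
        n_random: int,
        seed: int | None = None,
        rng: np.random.Generator | None = None,
        direction_mode: str = "random",
        directions: dict[str, str] | None = None,
        add_one: bool = False,
    ) -> EmpiricalNullResult:
        if n_random < 1:
            raise InputError("n_random must be >= 1")
        if rng is None:
            rng = np.random.default_rng(seed)
        time, event = self.surv.endpoint(self.endpoint)
        k = self.sig.k
        threshold = self.sig.high_risk_threshold

        observed = score_patients(self.expr, self.sig)
        observed_p = self._group_p(observed.high_mask().to_numpy(), time, event)

        # Precompute strict above/below-median indicators for the whole
        # universe once; each random set is then a row-sum plus a log-rank.
        uni = self.expr.loc[self.universe]
        med = uni.median(axis=1)
        above = uni.gt(med, axis=0).to_numpy()
        below = uni.lt(med, axis=0).to_numpy()
        n_uni = len(self.universe)

        fixed_up = None
        if direction_mode == "fixed":
            if directions is None:
                raise InputError("direction_mode='fixed' requires directions")
            fixed_up = np.array(
                [directions.get(g, "up") == "up" for g in self.universe]
            )

        random_ps = np.empty(n_random)
        for i in range(n_random):
            idx = rng.choice(n_uni, size=k, replace=False)
            if direction_mode == "random":
                up = rng.random(k) < 0.5
            elif direction_mode == "fixed":
                up = fixed_up[idx]
            else:
                raise InputError(f"unknown direction_mode {direction_mode!r}")
            points = np.where(up[:, None], above[idx], below[idx])
            scores = points.sum(axis=0)
            high = scores > threshold
            random_ps[i] = self._group_p(high, time, event)

        emp = empirical_p_from(observed_p, random_ps, add_one=add_one)
        n_lower = int(np.sum(random_ps < observed_p))
        return EmpiricalNullResult(
            observed_p=observed_p,
            n_random=n_random,
            n_lower=n_lower,
            empirical_p=emp,
            random_p_values=random_ps,
            seed=seed,
            direction_mode=direction_mode,
            add_one=add_one,
        )


def empirical_null(
    expr: pd.DataFrame,
    surv: SurvivalCohort,
    sig: Signature,
    n_random: int,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    universe: list[str] | None = None,
    direction_mode: str = "random",
    directions: dict[str, str] | None = None,
    add_one: bool = False,
    endpoint: str = "OS",
) -> EmpiricalNullResult:
    """Functional wrapper around :class:`EmpiricalNull`."""
    model = EmpiricalNull(expr, surv, sig, universe=universe, endpoint=endpoint)
    return model.fit(
        n_random,
        seed=seed,
        rng=rng,
        direction_mode=direction_mode,
        directions=directions,
        add_one=add_one,
    )
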