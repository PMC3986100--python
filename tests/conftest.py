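import numpy as np
import pandas as pd
import pytest

from metsig.config import SimConfig
from metsig.datatypes import (
    PairedExpressionCohort,
    Signature,
    SignatureGene,
    SurvivalCohort,
)


@pytest.fixture
def tiny_cohort():
    """3-case matched cohort with 4 genes and hand-set values."""
    genes = ["g1", "g2", "g3", "g4"]
    samples = ["c1_P", "c1_M", "c2_P", "c2_M", "c3_P", "c3_M"]
    values = pd.DataFrame(
        [
            [5.0, 5.8, 5.1, 6.1, 4.9, 6.1],   # up gene, d = .8, 1.0, 1.2
            [7.0, 7.0, 7.2, 7.2, 6.8, 6.8],   # unchanged
            [6.0, 5.0, 6.1, 5.2, 6.2, 5.0],   # down gene
            [3.0, 3.1, 2.9, 3.0, 3.1, 3.2],   # low signal
        ],
        index=genes,
        columns=samples,
    )
    sample_map = pd.DataFrame(
        {
            "case": ["c1", "c1", "c2", "c2", "c3", "c3"],
            "tissue": ["primary", "metastasis"] * 3,
        },
        index=pd.Index(samples, name="sample"),
    )
    return PairedExpressionCohort(values=values, sample_map=sample_map)


@pytest.fixture
def six_gene_signature():
    return Signature(
        [SignatureGene(f"SIG{i}", "up" if i % 2 == 0 else "down") for i in range(6)],
        high_risk_threshold=3,
    )


@pytest.fixture
def small_sim_config():
    return SimConfig(
        n_cases=9, n_genes=300, n_de_up=20, n_de_down=5, n_patients=200,
        n_chroms=1, n_probes_per_chrom=120, seed=11,
    )


def make_survival(times, events, patients=None, **cols) -> SurvivalCohort:
    if patients is None:
        patients = [f"p{i}" for i in range(len(times))]
    clin = pd.DataFrame({"time": times, "event": events, **cols},
                        index=pd.Index(patients, name="patient"))
    return SurvivalCohort(clinical=clin)


def brute_force_score(expr: pd.DataFrame, sig) -> dict:
    """Independent loop-based median-vote scorer used as an oracle."""
    scores = {}
    medians = {}
    for g in sig.genes:
        vals = sorted(expr.loc[g.gene])
        n = len(vals)
        medians[g.gene] = (
            vals[n // 2] if n % 2 == 1 else (vals[n // 2 - 1] + vals[n // 2]) / 2
        )
    for patient in expr.columns:
        s = 0
        for g in sig.genes:
            x = expr.loc[g.gene, patient]
            if g.met_direction == "up" and x > medians[g.gene]:
                s += 1
            if g.met_direction == "down" and x < medians[g.gene]:
                s += 1
        scores[patient] = s
    return scores


def logrank_oracle(time, event, group):
    """Textbook log-rank via explicit 2x2 tables at each event time."""
    import numpy as np

    time = np.asarray(time, float)
    event = np.asarray(event, int)
    group = np.asarray(group, bool)
    O = E = V = 0.0
    for t in sorted(set(time[event == 1])):
        at_risk = time >= t
        n = at_risk.sum()
        n1 = (at_risk & group).sum()
        d = ((time == t) & (event == 1)).sum()
        d1 = ((time == t) & (event == 1) & group).sum()
        O += d1
        E += d * n1 / n
        if n > 1:
            V += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    if V == 0:
        return 0.0, 1.0
    from scipy import stats

    chi2 = (O - E) ** 2 / V
    return chi2, stats.chi2.sf(chi2, 1)


def bh_oracle(pvals):
    """Explicit Benjamini-Hochberg step-up over a p-vector."""
    import numpy as np

    p = np.asarray(pvals, float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    q = np.empty(m)
    prev = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        val = min(prev, p[i] * m / rank)
        q[i] = val
        prev = val
    return q
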