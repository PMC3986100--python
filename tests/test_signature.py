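"""Vote scoring correctness, Cox screen calibration, and signature selection."""
import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from conftest import brute_force_score
from metsig.config import SimConfig
from metsig.datatypes import InputError, Signature, SignatureGene
from metsig.signature import (
    CANONICAL_SIGNATURE_GENES,
    canonical_signature,
    cox_screen,
    score_patients,
    select_signature,
)
from metsig.simulate import simulate_survival_cohort


def _matrix(rows: dict, patients) -> pd.DataFrame:
    return pd.DataFrame(rows, index=patients).T


class TestScorePatients:
    def test_exhaustive_per_gene_rank_patterns(self):
        """Every ordering of 3 distinct values x both directions matches brute force."""
        patients = ["p1", "p2", "p3"]
        for perm in itertools.permutations([1.0, 2.0, 3.0]):
            for direction in ("up", "down"):
                sig = Signature([SignatureGene("g", direction)], 0)
                expr = pd.DataFrame([list(perm)], index=["g"], columns=patients)
                got = score_patients(expr, sig)
                want = brute_force_score(expr, sig)
                for p in patients:
                    assert got.scores[p] == want[p]
                # exactly one patient above and one below the median
                assert sorted(got.scores) == [0, 0, 1]

    def test_random_six_gene_matrices_match_brute_force(self):
        rng = np.random.default_rng(7)
        patients = [f"p{i}" for i in range(3)]
        genes = [f"g{i}" for i in range(6)]
        for _ in range(300):
            expr = pd.DataFrame(rng.standard_normal((6, 3)), index=genes,
                                columns=patients)
            dirs = rng.choice(["up", "down"], size=6)
            sig = Signature([SignatureGene(g, d) for g, d in zip(genes, dirs)], 3)
            got = score_patients(expr, sig)
            want = brute_force_score(expr, sig)
            assert all(got.scores[p] == want[p] for p in patients)
            assert all(
                (got.groups[p] == "high") == (want[p] > 3) for p in patients
            )

    def test_patient_at_every_median_scores_zero(self):
        patients = ["p1", "p2", "p3"]
        genes = [f"g{i}" for i in range(6)]
        # p2 holds the median value of every gene (odd cohort)
        expr = pd.DataFrame(
            [[1.0, 2.0, 3.0]] * 6, index=genes, columns=patients
        )
        sig = Signature([SignatureGene(g, "up") for g in genes], 3)
        risk = score_patients(expr, sig)
        assert risk.scores["p2"] == 0
        assert risk.groups["p2"] == "low"

    def test_threshold_rule_above_three_is_high(self):
        patients = [f"p{i}" for i in range(4)]
        genes = [f"g{i}" for i in range(6)]
        rng = np.random.default_rng(0)
        expr = pd.DataFrame(rng.standard_normal((6, 4)), index=genes, columns=patients)
        # force p0 above median on 4 up-genes, below on the rest
        expr.loc[genes[:4], "p0"] = expr.loc[genes[:4]].max(axis=1) + 1
        expr.loc[genes[4:], "p0"] = expr.loc[genes[4:]].min(axis=1) - 1
        sig = Signature([SignatureGene(g, "up") for g in genes], 3)
        risk = score_patients(expr, sig)
        assert risk.scores["p0"] == 4
        assert risk.groups["p0"] == "high"

    def test_direction_flip_complements_scores_off_median(self):
        patients = ["p1", "p2", "p3"]
        genes = [f"g{i}" for i in range(4)]
        rng = np.random.default_rng(3)
        expr = pd.DataFrame(rng.standard_normal((4, 3)), index=genes, columns=patients)
        sig_up = Signature([SignatureGene(g, "up") for g in genes], 1)
        sig_dn = Signature([SignatureGene(g, "down") for g in genes], 1)
        s_up = score_patients(expr, sig_up).scores
        s_dn = score_patients(expr, sig_dn).scores
        medians = expr.median(axis=1)
        for p in patients:
            at_median = int((expr[p] == medians).sum())
            assert s_up[p] + s_dn[p] == len(genes) - at_median

    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_monotone_transform_invariance(self, seed):
        rng = np.random.default_rng(seed)
        patients = [f"p{i}" for i in range(7)]
        genes = [f"g{i}" for i in range(5)]
        expr = pd.DataFrame(rng.standard_normal((5, 7)), index=genes, columns=patients)
        dirs = rng.choice(["up", "down"], size=5)
        sig = Signature([SignatureGene(g, d) for g, d in zip(genes, dirs)], 2)
        base = score_patients(expr, sig).scores
        transformed = score_patients(np.exp(expr * 3.0) + 1.0, sig).scores
        assert (base == transformed).all()

    def test_patient_permutation_equivariance(self):
        rng = np.random.default_rng(5)
        patients = [f"p{i}" for i in range(8)]
        genes = [f"g{i}" for i in range(4)]
        expr = pd.DataFrame(rng.standard_normal((4, 8)), index=genes, columns=patients)
        sig = Signature([SignatureGene(g, "up") for g in genes], 2)
        base = score_patients(expr, sig).scores
        shuffled = score_patients(expr[patients[::-1]], sig).scores
        assert all(base[p] == shuffled[p] for p in patients)

    def test_errors(self):
        expr = pd.DataFrame([[1.0, 2.0]], index=["g"], columns=["p1", "p2"])
        with pytest.raises(InputError, match="absent"):
            score_patients(expr, Signature([SignatureGene("missing", "up")], 0))
        one = pd.DataFrame([[1.0]], index=["g"], columns=["p1"])
        with pytest.raises(InputError):
            score_patients(one, Signature([SignatureGene("g", "up")], 0))


class TestCanonicalSignature:
    def test_packaged_gene_set(self):
        dirs = {g: "up" for g in CANONICAL_SIGNATURE_GENES}
        sig = canonical_signature(dirs)
        assert tuple(sig.gene_ids) == CANONICAL_SIGNATURE_GENES
        assert sig.high_risk_threshold == 3
        with pytest.raises(InputError):
            canonical_signature({"CALB2": "up"})


class TestCoxScreen:
    def test_null_calibration(self, six_gene_signature):
        flagged = []
        for rep in range(10):
            cfg = SimConfig(n_patients=150, log_hr_per_point=0.0, seed=300 + rep)
            sim = simulate_survival_cohort(cfg, six_gene_signature, n_extra_genes=20)
            nulls = [g for g in sim.cohort.expression.index if g.startswith("NULL")]
            res = cox_screen(sim.cohort.expression, sim.cohort, nulls)
            flagged.extend(res["significant"].tolist())
        rate = np.mean(flagged)
        assert rate < 0.05 + 2 * np.sqrt(0.05 * 0.95 / len(flagged)) + 1e-9

    def test_coefficient_recovery_linear_hazard(self, six_gene_signature):
        cfg = SimConfig(n_patients=300, log_hr_per_point=0.5, seed=17)
        one_gene = Signature([SignatureGene("SIG0", "up")], 0)
        sim = simulate_survival_cohort(cfg, one_gene, hazard_model="expression")
        res = cox_screen(sim.cohort.expression, sim.cohort, ["SIG0"])
        coef, se = res.loc["SIG0", "coef"], res.loc["SIG0", "se"]
        assert abs(coef - 0.5) < 1.96 * se * 1.5  # generous single-replicate check

    def test_all_censored_is_error(self, six_gene_signature):
        cfg = SimConfig(n_patients=50, seed=1)
        sim = simulate_survival_cohort(cfg, six_gene_signature)
        clin = sim.cohort.clinical.copy()
        clin["event"] = 0
        from metsig.datatypes import SurvivalCohort

        dead = SurvivalCohort(clinical=clin, expression=sim.cohort.expression)
        with pytest.raises(InputError, match="events"):
            cox_screen(sim.cohort.expression, dead, ["SIG0"])


class TestSelectSignature:
    def test_exact_k_candidates_returned(self, six_gene_signature):
        cfg = SimConfig(n_patients=200, log_hr_per_point=0.3, seed=21)
        sim = simulate_survival_cohort(cfg, six_gene_signature,
                                       hazard_model="expression")
        cand = pd.DataFrame(
            {"met_direction": six_gene_signature.directions}
        )
        sig = select_signature(cand, [(sim.cohort.expression, sim.cohort)], k=6,
                               screen_p=0.999)
        assert sorted(sig.gene_ids) == sorted(six_gene_signature.gene_ids)

    def test_fewer_than_k_retained_returns_all(self, six_gene_signature):
        cfg = SimConfig(n_patients=200, log_hr_per_point=0.0, seed=22)
        sim = simulate_survival_cohort(cfg, six_gene_signature)
        cand = pd.DataFrame({"met_direction": six_gene_signature.directions})
        sig = select_signature(cand, [(sim.cohort.expression, sim.cohort)], k=6,
                               screen_p=1e-6)
        assert sig.k < 6
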