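"""End-to-end pipeline runner with a machine-readable manifest.

Stages run in dependency order on a synthetic study generated from one seed:
simulate -> de -> derive -> score -> survival -> null -> cnv -> phenotype.
Every run writes its resolved configuration and a manifest (input hashes,
parameters, seed, package version) next to the outputs; no stage mutates its
inputs on disk.
"""
from __future__ import annotations

import hashlib
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, io
from .config import RunConfig
from .copynumber import gene_copy_number, met_specific_cnas, segment_cbs, smooth_outliers
from .datatypes import Signature, SignatureGene
from .nulls import empirical_null
from .phenotype import paired_log_test
from .preprocess import PairedDifferentialExpression
from .signature import select_signature
from .simulate import (
    simulate_paired_cohort,
    simulate_probe_track,
    simulate_survival_cohort,
)
from .survival import evaluate_signature

log = logging.getLogger(__name__)

ALL_STAGES = ("simulate", "de", "derive", "survival", "null", "cnv", "phenotype")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(cfg: RunConfig, stages=ALL_STAGES) -> dict:
    """Run the requested stages on a synthetic study; returns the manifest."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    io.write_json(cfg.to_dict(), out / "resolved_config.json")
    manifest: dict = {"version": __version__, "seed": cfg.seed, "stages": {}, "outputs": {}}
    sim = cfg.sim

    results: dict = {}
    if "simulate" in stages:
        paired = simulate_paired_cohort(sim)
        io.write_cohort(paired.cohort, out / "expression.tsv", out / "sample_map.tsv")
        io.write_json(
            {"up_genes": paired.up_genes, "down_genes": paired.down_genes},
            out / "truth.json",
        )
        results["paired"] = paired
        manifest["stages"]["simulate"] = {
            "n_cases": sim.n_cases,
            "n_genes": sim.n_genes,
            "planted": len(paired.planted),
        }

    if "de" in stages:
        cohort = results.get("paired").cohort if "paired" in results else io.read_cohort(
            out / "expression.tsv", out / "sample_map.tsv"
        )
        de = PairedDifferentialExpression(cohort).fit(
            fc_min=cfg.fc_min, p_max=cfg.p_max, q_max=cfg.q_max
        )
        de.table.to_csv(out / "de.tsv", sep="\t")
        cand = de.candidates()
        cand.to_csv(out / "candidates.tsv", sep="\t")
        results["de"] = de
        results["candidates"] = cand
        manifest["stages"]["de"] = {"n_up": de.n_up, "n_down": de.n_down}

    if "derive" in stages or "survival" in stages or "null" in stages:
        cand = results.get("candidates")
        if cand is None:
            cand = pd.read_csv(out / "candidates.tsv", sep="\t", index_col=0)
        # planted-signal survival dataset derived from the candidate genes
        top = cand.head(min(12, len(cand)))
        planted_sig = Signature(
            [SignatureGene(g, d) for g, d in top["met_direction"].items()][: cfg.k],
            high_risk_threshold=None,
        )
        surv_sim = simulate_survival_cohort(
            sim,
            planted_sig,
            n_extra_genes=200,
            extra_gene_ids=list(top.index),
            hazard_model="expression",
        )
        io.write_clinical(surv_sim.cohort, out / "clinical.tsv")
        io.write_expression(surv_sim.cohort.expression, out / "survival_expression.tsv")
        results["surv"] = surv_sim

    if "derive" in stages:
        surv = results["surv"]
        sig = select_signature(
            results["candidates"],
            [(surv.cohort.expression, surv.cohort)],
            k=cfg.k,
        )
        io.write_signature(sig, out / "signature.json")
        results["signature"] = sig
        manifest["stages"]["derive"] = {"genes": sig.gene_ids}
    elif "survival" in stages or "null" in stages:
        sig_path = out / "signature.json"
        results["signature"] = (
            io.read_signature(sig_path) if sig_path.exists() else planted_sig
        )

    if "survival" in stages:
        surv = results["surv"]
        ev = evaluate_signature(
            {"synthetic": (surv.cohort.expression, surv.cohort)},
            results["signature"],
            strata=("all",),
        )
        ev.table.to_csv(out / "survival_results.tsv", sep="\t", index=False)
        from .signature import score_patients

        risk = score_patients(surv.cohort.expression, results["signature"])
        io.write_risk(risk, out / "risk.tsv")
        results["evaluation"] = ev
        manifest["stages"]["survival"] = {
            "logrank_p": float(ev.table["logrank_p"].iloc[0]) if len(ev.table) else None
        }

    if "null" in stages:
        surv = results["surv"]
        nr = empirical_null(
            surv.cohort.expression,
            surv.cohort,
            results["signature"],
            n_random=cfg.n_random,
            seed=cfg.seed,
        )
        io.write_json(
            {
                "observed_p": nr.observed_p,
                "n_random": nr.n_random,
                "n_lower": nr.n_lower,
                "empirical_p": nr.empirical_p,
                "seed": cfg.seed,
                "direction_mode": nr.direction_mode,
            },
            out / "empirical_null.json",
        )
        pd.DataFrame({"p": nr.random_p_values}).to_csv(
            out / "random_p_values.tsv", sep="\t", index=False
        )
        results["null"] = nr
        manifest["stages"]["null"] = {"empirical_p": nr.empirical_p}

    if "cnv" in stages:
        probe_sim = simulate_probe_track(sim)
        io.write_probe_track(probe_sim.track, out / "probes.tsv")
        smoothed = smooth_outliers(
            probe_sim.track, region=cfg.smooth_region, nsd=cfg.smooth_nsd
        )
        segs = segment_cbs(
            smoothed, alpha=cfg.alpha, n_perm=cfg.n_perm,
            rng=np.random.default_rng(np.random.SeedSequence([cfg.seed, 97])),
        )
        io.write_segments(segs, out / "segments.seg")
        results["segments"] = segs
        manifest["stages"]["cnv"] = {"n_segments": segs.n}

    if "phenotype" in stages:
        rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 131]))
        # log-normal staining with a 1.5x multiplicative metastasis elevation
        n = sim.n_cases
        base = np.exp(rng.normal(np.log(20.0), 0.5, size=n))
        met = base * 1.5 * np.exp(rng.normal(0.0, 0.4, size=n))
        table = pd.DataFrame(
            {
                "case": [f"case{i + 1:02d}" for i in range(n)] * 2,
                "tissue": ["primary"] * n + ["metastasis"] * n,
                "percent": np.clip(np.concatenate([base, met]), 0.01, 100.0),
            }
        )
        table.to_csv(out / "staining.tsv", sep="\t", index=False)
        ph = paired_log_test(table)
        io.write_json(
            {
                "n": ph.n,
                "n_higher_in_met": ph.n_higher_in_met,
                "t": ph.t,
                "p": ph.p,
                "normality_p_raw": ph.normality_p_raw,
                "normality_p_log": ph.normality_p_log,
            },
            out / "phenotype.json",
        )
        manifest["stages"]["phenotype"] = {"p": ph.p}

    for f in sorted(out.iterdir()):
        if f.is_file() and f.name != "manifest.json":
            manifest["outputs"][f.name] = _sha256(f)
    io.write_json(manifest, out / "manifest.json")
    return manifest
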