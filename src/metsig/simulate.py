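"""Synthetic study generators.

Every generator draws from a named sub-stream of one global seed, so a whole
simulated study is reproducible from a single integer and each stage can be
regenerated independently.

The paired-expression generator models the matched-pair design directly: each
gene gets a per-case baseline shared by both tissues of the pair (this shared
baseline is what the paired t-test exploits), the metastasis sample of a
planted gene is shifted by +/- the configured effect, and independent Gaussian
measurement noise is added per tissue. Survival times are exponential under
proportional hazards in the signature score, with independent exponential
censoring scaled to hit the requested censoring fraction. Probe tracks are
piecewise-constant per chromosome with Gaussian noise and sign-symmetric
single-probe outlier spikes.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import SimConfig
from .datatypes import (
    METASTASIS,
    PRIMARY,
    InputError,
    PairedExpressionCohort,
    ProbeTrack,
    Signature,
    SurvivalCohort,
)


@dataclass
class PairedSimulation:
    cohort: PairedExpressionCohort
    up_genes: list[str]
    down_genes: list[str]

    @property
    def planted(self) -> list[str]:
        return self.up_genes + self.down_genes


@dataclass
class SurvivalSimulation:
    cohort: SurvivalCohort
    true_scores: pd.Series
    risk: "object"  # RiskAssignment


@dataclass
class ProbeSimulation:
    track: ProbeTrack
    breakpoints: dict[str, list[int]]   # probe indices where a new segment starts
    level_means: dict[str, np.ndarray]  # true mean per probe
    outliers: dict[str, np.ndarray]     # boolean mask of spiked probes


def simulate_paired_cohort(cfg: SimConfig) -> PairedSimulation:
    """Simulate a matched primary/metastasis expression cohort.

    Returns the cohort plus ground-truth planted up/down gene lists. The mean
    metastasis-minus-primary log2 difference of a planted up gene is
    ``+de_effect`` (down genes ``-de_effect``); per-pair differences have SD
    ``sqrt(2) * noise_sd`` because both tissues carry independent noise.
    """
    cfg.validate()
    rng = cfg.rng("paired_expression")

    genes = [f"G{i:05d}" for i in range(cfg.n_genes)]
    cases = [f"case{i + 1:02d}" for i in range(cfg.n_cases)]

    planted_idx = rng.choice(cfg.n_genes, size=cfg.n_de_up + cfg.n_de_down, replace=False)
    up_idx = planted_idx[: cfg.n_de_up]
    down_idx = planted_idx[cfg.n_de_up :]
    delta = np.zeros(cfg.n_genes)
    delta[up_idx] = cfg.de_effect
    delta[down_idx] = -cfg.de_effect

    mu = cfg.baseline_mean + cfg.baseline_gene_sd * rng.standard_normal(cfg.n_genes)
    baseline = mu[:, None] + cfg.baseline_case_sd * rng.standard_normal(
        (cfg.n_genes, cfg.n_cases)
    )
    primary = baseline + cfg.noise_sd * rng.standard_normal((cfg.n_genes, cfg.n_cases))
    met = (
        baseline
        + delta[:, None]
        + cfg.noise_sd * rng.standard_normal((cfg.n_genes, cfg.n_cases))
    )

    columns, data, records = [], [], []
    for j, case in enumerate(cases):
        for tissue, mat, suffix in ((PRIMARY, primary, "P"), (METASTASIS, met, "M")):
            sample = f"{case}_{suffix}"
            columns.append(sample)
            data.append(mat[:, j])
            records.append({"sample": sample, "case": case, "tissue": tissue})

    values = pd.DataFrame(np.column_stack(data), index=genes, columns=columns)
    sample_map = pd.DataFrame(records).set_index("sample")
    cohort = PairedExpressionCohort(values=values, sample_map=sample_map)
    return PairedSimulation(
        cohort=cohort,
        up_genes=[genes[i] for i in up_idx],
        down_genes=[genes[i] for i in down_idx],
    )


def simulate_survival_cohort(
    cfg: SimConfig,
    signature: Signature,
    n_extra_genes: int = 0,
    extra_gene_ids: list[str] | None = None,
    residual_rate: float = 0.0,
    signature_effect_stratum: str = "all",
    hazard_model: str = "score",
    rng: np.random.Generator | None = None,
) -> SurvivalSimulation:
    """Simulate a treated survival cohort whose hazard depends on the vote score.

    Each patient receives independent N(mu_g, 1) log2 expression for the
    signature genes (plus ``n_extra_genes`` null genes forming a background
    universe). The event hazard is ``baseline_hazard * exp(log_hr_per_point *
    score)``; censoring is independent exponential with per-patient rate chosen
    so the expected censored fraction equals ``censor_rate``.

    ``signature_effect_stratum='no_residual'`` restricts the score effect to
    patients without macroscopic residual disease, mirroring a design where
    residual tumor burden dominates outcome.

    ``hazard_model`` selects what drives the hazard: ``"score"`` (default)
    uses the integer vote score, emulating evaluation of an established
    signature; ``"expression"`` makes the log hazard linear in the sum of
    direction-signed standardized expression of the signature genes
    (``log_hr_per_point`` per gene SD), the design in which every signature
    gene is independently prognostic — the premise of a per-gene Cox screen.
    """
    cfg.validate()
    if signature.k < 1:
        raise InputError("signature must contain at least one gene")
    if signature_effect_stratum not in ("all", "no_residual"):
        raise InputError(
            f"signature_effect_stratum must be 'all' or 'no_residual', "
            f"got {signature_effect_stratum!r}"
        )
    if rng is None:
        rng = cfg.rng("survival")

    from .signature import score_patients  # local import avoids a cycle

    patients = [f"pt{i + 1:04d}" for i in range(cfg.n_patients)]
    named_extras = [] if extra_gene_ids is None else [
        g for g in extra_gene_ids if g not in set(signature.gene_ids)
    ]
    gene_ids = (
        list(signature.gene_ids)
        + named_extras
        + [f"NULL{i:04d}" for i in range(n_extra_genes)]
    )
    mu = cfg.baseline_mean + cfg.baseline_gene_sd * rng.standard_normal(len(gene_ids))
    expr = pd.DataFrame(
        mu[:, None] + rng.standard_normal((len(gene_ids), cfg.n_patients)),
        index=gene_ids,
        columns=patients,
    )

    if hazard_model not in ("score", "expression"):
        raise InputError(f"hazard_model must be 'score' or 'expression', got {hazard_model!r}")

    risk = score_patients(expr, signature)
    scores = risk.scores.to_numpy(dtype=float)

    residual = (rng.random(cfg.n_patients) < residual_rate).astype(int)
    if hazard_model == "score":
        effect = scores.copy()
    else:
        signs = np.array(
            [1.0 if g.met_direction == "up" else -1.0 for g in signature.genes]
        )
        sig_expr = expr.loc[signature.gene_ids].to_numpy()
        z = sig_expr - mu[: signature.k, None]  # unit-SD by construction
        effect = (signs[:, None] * z).sum(axis=0)
    if signature_effect_stratum == "no_residual":
        effect[residual == 1] = 0.0

    hazard = cfg.baseline_hazard * np.exp(cfg.log_hr_per_point * effect)
    t_event = rng.exponential(1.0 / hazard)
    if cfg.censor_rate > 0:
        # For competing exponentials P(censor first) = hc / (hc + he); a
        # per-patient censor hazard proportional to the event hazard makes that
        # probability exactly censor_rate for every patient.
        c_hazard = hazard * cfg.censor_rate / (1.0 - cfg.censor_rate)
        t_censor = rng.exponential(1.0 / c_hazard)
    else:
        t_censor = np.full(cfg.n_patients, np.inf)

    time = np.minimum(t_event, t_censor)
    event = (t_event <= t_censor).astype(int)

    clinical = pd.DataFrame(
        {
            "time": time,
            "event": event,
            "residual_disease": residual,
            "treated": np.ones(cfg.n_patients, dtype=int),
        },
        index=pd.Index(patients, name="patient"),
    )
    cohort = SurvivalCohort(clinical=clinical, expression=expr)
    return SurvivalSimulation(cohort=cohort, true_scores=risk.scores, risk=risk)


def simulate_probe_track(cfg: SimConfig, min_seg_probes: int = 10) -> ProbeSimulation:
    """Simulate aCGH probe tracks with planted piecewise-constant segments.

    Each chromosome receives ``n_segments`` breakpoints at random interior
    positions (segments at least ``min_seg_probes`` probes long); the level
    steps by +/- ``segment_effect`` log10 at every breakpoint. A fraction
    ``outlier_rate`` of probes is spiked by 5-8 noise SDs with random sign.
    """
    cfg.validate()
    rng = cfg.rng("probe_track")

    frames = []
    breakpoints: dict[str, list[int]] = {}
    level_means: dict[str, np.ndarray] = {}
    outliers: dict[str, np.ndarray] = {}
    probe_len = 60
    spacing = 5000

    for c in range(cfg.n_chroms):
        chrom = f"chr{c + 1}"
        n = cfg.n_probes_per_chrom
        n_bp = cfg.n_segments
        if n_bp > 0 and n >= (n_bp + 1) * min_seg_probes:
            candidates = np.arange(min_seg_probes, n - min_seg_probes + 1)
            bps: list[int] = []
            for _ in range(n_bp):
                ok = np.array(
                    [all(abs(c2 - b) >= min_seg_probes for b in bps) for c2 in candidates]
                )
                if not ok.any():
                    break
                bps.append(int(rng.choice(candidates[ok])))
            bps = sorted(bps)
        else:
            bps = []

        # first segment at baseline 0; the level steps +/- segment_effect at
        # each breakpoint so every breakpoint carries a real mean change
        levels = np.zeros(n)
        bounds = [0, *bps, n]
        current = 0.0
        for lo, hi in zip(bounds[:-1], bounds[1:]):
            levels[lo:hi] = current
            current += rng.choice([-1.0, 1.0]) * cfg.segment_effect

        ratios = levels + cfg.probe_noise_sd * rng.standard_normal(n)
        spike_mask = rng.random(n) < cfg.outlier_rate
        n_spike = int(spike_mask.sum())
        if n_spike:
            mags = rng.uniform(5.0, 8.0, size=n_spike) * cfg.probe_noise_sd
            signs = rng.choice([-1.0, 1.0], size=n_spike)
            ratios[spike_mask] += signs * mags

        starts = np.arange(n) * spacing
        frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "start": starts,
                    "end": starts + probe_len,
                    "probe": [f"{chrom}_p{i:05d}" for i in range(n)],
                    "log10_ratio": ratios,
                }
            )
        )
        breakpoints[chrom] = bps
        level_means[chrom] = levels
        outliers[chrom] = spike_mask

    track = ProbeTrack(probes=pd.concat(frames, ignore_index=True))
    return ProbeSimulation(
        track=track, breakpoints=breakpoints, level_means=level_means, outliers=outliers
    )
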