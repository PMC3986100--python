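"""Configuration objects for simulation and pipeline runs."""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Any

import numpy as np


class ConfigError(ValueError):
    """Raised when a configuration field is invalid; the message names the field."""


# Fixed sub-stream ids so one global seed deterministically governs every
# simulator without the streams overlapping.
_STREAMS = {
    "paired_expression": 11,
    "survival": 23,
    "probe_track": 37,
    "empirical_null": 53,
    "selection": 71,
}


def stream_rng(seed: int, stream: str) -> np.random.Generator:
    """Derive an independent generator for a named sub-stream of ``seed``."""
    if stream not in _STREAMS:
        raise KeyError(f"unknown RNG stream {stream!r}")
    return np.random.default_rng(np.random.SeedSequence([int(seed), _STREAMS[stream]]))


@dataclass
class SimConfig:
    """Parameters of the synthetic study generator.

    Defaults emulate the study design the analysis assumes: 9 matched
    primary/metastasis pairs with 77 up- and 10 down-regulated genes planted at a
    mean paired log2 shift of 1.2; survival cohorts of 400 chemotherapy-treated
    patients whose hazard increases multiplicatively per signature point; aCGH
    probe tracks with piecewise-constant segments plus isolated outlier spikes.
    """

    # paired expression cohort
    n_cases: int = 9
    n_genes: int = 2000
    n_de_up: int = 77
    n_de_down: int = 10
    de_effect: float = 1.2        # mean paired log2 shift of planted genes
    noise_sd: float = 0.4         # residual log2 SD per tissue measurement
    baseline_mean: float = 7.0    # log2 location of gene baselines
    baseline_gene_sd: float = 1.5 # between-gene SD of baselines
    baseline_case_sd: float = 0.5 # between-case SD shared by both tissues of a pair

    # survival cohort
    n_patients: int = 400
    baseline_hazard: float = 0.02    # events per month at score 0
    log_hr_per_point: float = 0.4    # log hazard ratio per signature point
    censor_rate: float = 0.3         # expected fraction censored

    # aCGH probe track
    n_chroms: int = 2
    n_probes_per_chrom: int = 200
    n_segments: int = 2              # planted breakpoints per chromosome
    segment_effect: float = 0.3      # log10 amplitude of level changes
    probe_noise_sd: float = 0.05     # per-probe log10 noise
    outlier_rate: float = 0.02       # fraction of single-probe spikes

    seed: int = 0

    def validate(self) -> None:
        counts = {
            "n_cases": self.n_cases,
            "n_genes": self.n_genes,
            "n_patients": self.n_patients,
            "n_chroms": self.n_chroms,
            "n_probes_per_chrom": self.n_probes_per_chrom,
        }
        for name, value in counts.items():
            if not isinstance(value, (int, np.integer)) or value < 1:
                raise ConfigError(f"{name} must be an integer >= 1, got {value!r}")
        for name in ("n_de_up", "n_de_down", "n_segments"):
            value = getattr(self, name)
            if not isinstance(value, (int, np.integer)) or value < 0:
                raise ConfigError(f"{name} must be a nonnegative integer, got {value!r}")
        if self.n_de_up + self.n_de_down > self.n_genes:
            raise ConfigError(
                "n_de_up + n_de_down exceeds n_genes "
                f"({self.n_de_up}+{self.n_de_down} > {self.n_genes})"
            )
        if not 0 <= self.censor_rate < 1:
            raise ConfigError(f"censor_rate must be in [0, 1), got {self.censor_rate!r}")
        if not self.noise_sd > 0:
            raise ConfigError(f"noise_sd must be > 0, got {self.noise_sd!r}")
        if not self.probe_noise_sd > 0:
            raise ConfigError(f"probe_noise_sd must be > 0, got {self.probe_noise_sd!r}")
        if not 0 <= self.outlier_rate < 1:
            raise ConfigError(f"outlier_rate must be in [0, 1), got {self.outlier_rate!r}")
        if self.baseline_hazard <= 0:
            raise ConfigError(f"baseline_hazard must be > 0, got {self.baseline_hazard!r}")

    def rng(self, stream: str) -> np.random.Generator:
        return stream_rng(self.seed, stream)


@dataclass
class RunConfig:
    """Resolved parameters of a pipeline run.

    Stage defaults mirror the analysis: |log2 FC| > 0.9, p < 0.05, q < 0.25 for
    the paired differential-expression filter; six signature genes with the
    high-risk cut at > 3 points; 10,000 random gene sets for the empirical null;
    CBS alpha 0.05 with smooth.region 10; gene copy number requires >= 3 probes;
    expression-copy-number correlation > 0.7; top 250 Ki-67-correlated genes.
    """

    fc_min: float = 0.9
    p_max: float = 0.05
    q_max: float = 0.25
    k: int = 6
    threshold: int = 3
    n_random: int = 10_000
    alpha: float = 0.05
    n_perm: int = 1000
    smooth_region: int = 10
    smooth_nsd: float = 3.0
    min_probes: int = 3
    amp_thresh: float = 0.1
    r_min: float = 0.7
    top_n: int = 250
    seed: int = 0
    out_dir: str = "metsig_out"
    sim: SimConfig = field(default_factory=SimConfig)

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "RunConfig":
        """Build from a mapping, rejecting unknown keys."""
        data = dict(data)
        sim_data = data.pop("sim", {})
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        sim_known = {f.name for f in dataclasses.fields(SimConfig)}
        sim_unknown = set(sim_data) - sim_known
        if sim_unknown:
            raise ConfigError(f"unknown sim config keys: {sorted(sim_unknown)}")
        cfg = cls(**data, sim=SimConfig(**sim_data))
        cfg.sim.validate()
        return cfg

    def to_dict(self) -> dict[str, Any]:
        out = dataclasses.asdict(self)
        return out
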