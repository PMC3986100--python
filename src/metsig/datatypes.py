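"""Core in-memory containers shared across the pipeline.

Expression matrices are pandas DataFrames with gene rows and sample columns,
on log2 scale. aCGH probe tracks use 0-based half-open genomic intervals with
log10 tumor/reference ratios, the scale the copy-number stage works in.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

PRIMARY = "primary"
METASTASIS = "metastasis"
TISSUES = (PRIMARY, METASTASIS)


class InputError(ValueError):
    """Invalid or inconsistent user-supplied input."""


@dataclass
class PairedExpressionCohort:
    """Log2 expression for matched primary/metastasis tumor pairs.

    Parameters
    ----------
    values : DataFrame
        genes x samples log2 expression; index = gene ids, columns = sample ids.
    sample_map : DataFrame
        Indexed by sample id with columns ``case`` and ``tissue``
        (``primary`` | ``metastasis``). Every case must contribute exactly one
        sample of each tissue.
    """

    values: pd.DataFrame
    sample_map: pd.DataFrame

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            dupes = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise InputError(f"duplicate gene ids: {dupes[:5]}")
        if not np.isfinite(self.values.to_numpy(dtype=float)).all():
            raise InputError("expression matrix contains non-finite values")
        missing = set(self.values.columns) - set(self.sample_map.index)
        if missing:
            raise InputError(f"samples missing from sample_map: {sorted(missing)[:5]}")
        bad = set(self.sample_map["tissue"]) - set(TISSUES)
        if bad:
            raise InputError(f"unknown tissue labels: {sorted(bad)}")
        for case, grp in self.sample_map.loc[list(self.values.columns)].groupby("case"):
            tissues = sorted(grp["tissue"])
            if tissues != sorted(TISSUES):
                raise InputError(
                    f"case {case!r} must have exactly one primary and one "
                    f"metastasis sample, got {tissues}"
                )

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    @property
    def cases(self) -> list:
        seen: dict = {}
        for s in self.values.columns:
            seen.setdefault(self.sample_map.loc[s, "case"], None)
        return list(seen)

    def sample_of(self, case, tissue: str) -> str:
        sub = self.sample_map[
            (self.sample_map["case"] == case) & (self.sample_map["tissue"] == tissue)
        ]
        return sub.index[0]

    def tissue_labels(self) -> pd.Series:
        """Tissue label per sample, aligned to the matrix columns."""
        return self.sample_map.loc[list(self.values.columns), "tissue"]

    def paired_diffs(self) -> pd.DataFrame:
        """Metastasis minus primary log2 differences, genes x cases."""
        cols = {}
        for case in self.cases:
            met = self.sample_of(case, METASTASIS)
            pri = self.sample_of(case, PRIMARY)
            cols[case] = self.values[met] - self.values[pri]
        return pd.DataFrame(cols, index=self.values.index)

    def with_values(self, values: pd.DataFrame) -> "PairedExpressionCohort":
        return PairedExpressionCohort(values=values, sample_map=self.sample_map)


@dataclass(frozen=True)
class SignatureGene:
    """A signature gene with its direction of change in metastases."""

    gene: str
    met_direction: str  # "up" | "down"

    def __post_init__(self) -> None:
        if self.met_direction not in ("up", "down"):
            raise InputError(
                f"met_direction must be 'up' or 'down', got {self.met_direction!r}"
            )


@dataclass
class Signature:
    """An ordered gene set scored by median-dichotomized directional votes.

    A patient gains one point per up-gene expressed strictly above the cohort
    median and per down-gene strictly below it; scores above
    ``high_risk_threshold`` define the high-risk group. Median cutpoints are a
    property of each evaluation cohort and are never stored here.
    """

    genes: list[SignatureGene]
    high_risk_threshold: int | None = None

    def __post_init__(self) -> None:
        ids = [g.gene for g in self.genes]
        if len(set(ids)) != len(ids):
            raise InputError("signature gene ids must be unique")
        if self.high_risk_threshold is None:
            self.high_risk_threshold = len(self.genes) // 2
        if not 0 <= self.high_risk_threshold < max(len(self.genes), 1):
            raise InputError(
                f"high_risk_threshold must be in [0, k), got {self.high_risk_threshold}"
            )

    @property
    def k(self) -> int:
        return len(self.genes)

    @property
    def gene_ids(self) -> list[str]:
        return [g.gene for g in self.genes]

    @property
    def directions(self) -> pd.Series:
        return pd.Series({g.gene: g.met_direction for g in self.genes})


@dataclass
class SurvivalCohort:
    """Censored survival times with optional covariates and expression.

    ``clinical`` is indexed by patient with columns ``time`` (months) and
    ``event`` (1 = death/progression observed, 0 = censored); optional columns:
    ``residual_disease`` (0 none / 1 macroscopic), ``treated`` (0/1),
    ``pfs_time`` / ``pfs_event`` for the progression-free endpoint.
    ``expression`` (genes x patients) aligns columns to the clinical index.
    """

    clinical: pd.DataFrame
    expression: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        for col in ("time", "event"):
            if col not in self.clinical.columns:
                raise InputError(f"clinical table missing column {col!r}")
        if (self.clinical["time"] <= 0).any():
            raise InputError("survival times must be > 0")
        if not self.clinical["event"].isin([0, 1]).all():
            raise InputError("event must be binary 0/1")
        if self.expression is not None:
            if list(self.expression.columns) != list(self.clinical.index):
                self.expression = self.expression.reindex(
                    columns=self.clinical.index
                )
                if self.expression.isna().any().any():
                    raise InputError("expression columns do not match clinical index")

    @property
    def n(self) -> int:
        return len(self.clinical)

    @property
    def n_events(self) -> int:
        return int(self.clinical["event"].sum())

    def subset(self, mask: pd.Series) -> "SurvivalCohort":
        clin = self.clinical.loc[mask]
        expr = None if self.expression is None else self.expression.loc[:, mask]
        return SurvivalCohort(clinical=clin, expression=expr)

    def endpoint(self, which: str = "OS") -> tuple[np.ndarray, np.ndarray]:
        """Return (time, event) arrays for the requested endpoint."""
        if which == "OS":
            return (
                self.clinical["time"].to_numpy(dtype=float),
                self.clinical["event"].to_numpy(dtype=int),
            )
        if which == "PFS":
            for col in ("pfs_time", "pfs_event"):
                if col not in self.clinical.columns:
                    raise InputError(f"PFS endpoint requires column {col!r}")
            return (
                self.clinical["pfs_time"].to_numpy(dtype=float),
                self.clinical["pfs_event"].to_numpy(dtype=int),
            )
        raise InputError(f"unknown endpoint {which!r}")


@dataclass
class RiskAssignment:
    """Per-patient vote scores and risk groups for one evaluation cohort."""

    table: pd.DataFrame        # index patient; columns: score, group
    cutpoints: pd.Series       # per-gene median used for this cohort
    threshold: int

    @property
    def scores(self) -> pd.Series:
        return self.table["score"]

    @property
    def groups(self) -> pd.Series:
        return self.table["group"]

    def high_mask(self) -> pd.Series:
        return self.table["group"] == "high"


@dataclass
class ProbeTrack:
    """aCGH probes with log10 tumor/reference ratios, sorted by (chrom, start)."""

    probes: pd.DataFrame  # columns: chrom, start, end, probe, log10_ratio

    REQUIRED = ("chrom", "start", "end", "probe", "log10_ratio")

    def __post_init__(self) -> None:
        for col in self.REQUIRED:
            if col not in self.probes.columns:
                raise InputError(f"probe track missing column {col!r}")
        if not np.isfinite(self.probes["log10_ratio"].to_numpy(dtype=float)).all():
            raise InputError("probe ratios must be finite")
        self.probes = (
            self.probes.sort_values(["chrom", "start"], kind="mergesort")
            .reset_index(drop=True)
        )

    @property
    def chroms(self) -> list[str]:
        return list(dict.fromkeys(self.probes["chrom"]))

    def chrom_values(self, chrom: str) -> np.ndarray:
        return self.probes.loc[
            self.probes["chrom"] == chrom, "log10_ratio"
        ].to_numpy(dtype=float)

    def with_ratios(self, ratios: np.ndarray) -> "ProbeTrack":
        probes = self.probes.copy()
        probes["log10_ratio"] = np.asarray(ratios, dtype=float)
        return ProbeTrack(probes=probes)


@dataclass
class SegmentSet:
    """Piecewise-constant copy-number segments covering the probe extent."""

    segments: pd.DataFrame  # columns: chrom, start, end, n_probes, mean

    def __post_init__(self) -> None:
        if (self.segments["n_probes"] < 1).any():
            raise InputError("every segment must contain at least one probe")

    @property
    def n(self) -> int:
        return len(self.segments)
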