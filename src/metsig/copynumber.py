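"""aCGH copy-number analysis: outlier smoothing, circular binary segmentation,
gene-level scoring, metastasis-specific recurrent CNA calls, and CNA-profile
clustering.

Circular binary segmentation (CBS) treats each segment as a circle and looks
for the arc whose mean differs most from its complement by a two-sample
t-like statistic; a split is accepted when a within-segment permutation test
puts the observed maximum below ``alpha``. Accepted splits recurse until no
segment can be divided further. Probe-level log10 ratios are first smoothed by
clamping single-probe outliers toward a running window median.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .datatypes import InputError, PairedExpressionCohort, ProbeTrack, SegmentSet

log = logging.getLogger(__name__)

MIN_SPLIT_PROBES = 4  # segments smaller than this are never split


def _robust_sd(x: np.ndarray) -> float:
    """SD estimate from the median absolute successive difference.

    Robust to segment-level mean shifts: for piecewise-constant signal plus
    N(0, s^2) noise, successive differences are N(0, 2 s^2) away from the few
    breakpoints, so MAD(diff)/(1.4826... * sqrt(2)) estimates s.
    """
    if len(x) < 2:
        return 0.0
    d = np.diff(x)
    mad = np.median(np.abs(d - np.median(d)))
    return float(mad * 1.482602218505602 / np.sqrt(2.0))


def smooth_outliers(
    track: ProbeTrack, region: int = 10, nsd: float = 3.0
) -> ProbeTrack:
    """Clamp single-probe outliers toward the local window median.

    Per chromosome, a probe deviating more than ``nsd`` track SDs from the
    median of its +/- ``region`` probe window is moved to the window median
    plus ``nsd`` SDs in the original direction; other probes are untouched.
    Windows truncate at chromosome boundaries. The track SD is estimated
    robustly from successive probe differences so planted segments do not
    inflate it.
    """
    out = track.probes["log10_ratio"].to_numpy(dtype=float).copy()
    for chrom in track.chroms:
        mask = (track.probes["chrom"] == chrom).to_numpy()
        x = out[mask]
        sd = _robust_sd(x)
        if sd == 0:
            continue
        med = (
            pd.Series(x)
            .rolling(window=2 * region + 1, center=True, min_periods=1)
            .median()
            .to_numpy()
        )
        dev = x - med
        limit = nsd * sd
        clamped = med + np.clip(dev, -limit, limit)
        out[mask] = np.where(np.abs(dev) > limit, clamped, x)
    return track.with_ratios(out)


@lru_cache(maxsize=64)
def _arc_indices(n: int) -> tuple[np.ndarray, np.ndarray]:
    """All (i, j) arc boundaries 0 <= i < j <= n with 1 <= j-i <= n-1.

    Wrap-around arcs are complements of these, and the statistic is symmetric
    under group swap, so interior arcs cover the circular search.
    """
    i, j = np.triu_indices(n + 1, k=1)
    keep = (j - i) < n
    return i[keep].copy(), j[keep].copy()


def _max_arc_stat(x: np.ndarray) -> tuple[float, int, int]:
    """Maximum |two-sample t| over all arcs of x; returns (stat, i, j)."""
    n = len(x)
    i, j = _arc_indices(n)
    S = np.concatenate([[0.0], np.cumsum(x)])
    total = S[-1]
    ss_total = float(np.sum(x * x))

    n_in = (j - i).astype(float)
    n_out = n - n_in
    sum_in = S[j] - S[i]
    mean_in = sum_in / n_in
    mean_out = (total - sum_in) / n_out
    ss_within = ss_total - n_in * mean_in**2 - n_out * mean_out**2
    df = max(n - 2, 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        s2 = np.maximum(ss_within, 0.0) / df
        t = np.abs(mean_in - mean_out) / np.sqrt(s2 * (1.0 / n_in + 1.0 / n_out))
    t = np.where(np.isfinite(t), t, np.inf)
    best = int(np.argmax(t))
    return float(t[best]), int(i[best]), int(j[best])


def _max_stat_only(x: np.ndarray, i: np.ndarray, j: np.ndarray) -> float:
    n = len(x)
    S = np.concatenate([[0.0], np.cumsum(x)])
    total = S[-1]
    ss_total = float(np.sum(x * x))
    n_in = (j - i).astype(float)
    n_out = n - n_in
    sum_in = S[j] - S[i]
    mean_in = sum_in / n_in
    mean_out = (total - sum_in) / n_out
    ss_within = ss_total - n_in * mean_in**2 - n_out * mean_out**2
    df = max(n - 2, 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        s2 = np.maximum(ss_within, 0.0) / df
        t = np.abs(mean_in - mean_out) / np.sqrt(s2 * (1.0 / n_in + 1.0 / n_out))
    t = np.where(np.isfinite(t), t, np.inf)
    return float(np.max(t))


def _split_segment(
    x: np.ndarray, alpha: float, n_perm: int, rng: np.random.Generator
) -> list[tuple[int, int]] | None:
    """Try to split x; return sub-segment bounds (relative) or None."""
    n = len(x)
    if n < MIN_SPLIT_PROBES:
        return None
    obs, bi, bj = _max_arc_stat(x)
    i_idx, j_idx = _arc_indices(n)
    count = 0
    for _ in range(n_perm):
        if _max_stat_only(rng.permutation(x), i_idx, j_idx) >= obs:
            count += 1
    p = count / n_perm
    if p >= alpha:
        return None
    bounds = sorted({0, bi, bj, n})
    pieces = [(a, b) for a, b in zip(bounds[:-1], bounds[1:]) if b > a]
    if len(pieces) < 2:
        return None
    return pieces


def segment_chromosome(
    x: np.ndarray, alpha: float, n_perm: int, rng: np.random.Generator
) -> list[tuple[int, int]]:
    """Recursive CBS over one chromosome; returns probe-index segment bounds."""
    segments: list[tuple[int, int]] = []
    stack = [(0, len(x))]
    while stack:
        lo, hi = stack.pop()
        pieces = _split_segment(x[lo:hi], alpha, n_perm, rng)
        if pieces is None:
            segments.append((lo, hi))
        else:
            # push in reverse so output order stays left-to-right
            for a, b in reversed(pieces):
                stack.append((lo + a, lo + b))
    return sorted(segments)


def segment_cbs(
    track: ProbeTrack,
    alpha: float = 0.05,
    n_perm: int = 1000,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
) -> SegmentSet:
    """Circular binary segmentation of a (smoothed) probe track.

    Splits are accepted at permutation p < ``alpha`` (``n_perm`` within-segment
    permutations); segments of fewer than 4 probes are never split further.
    """
    if n_perm < 100:
        raise InputError(f"n_perm must be >= 100, got {n_perm}")
    if rng is None:
        rng = np.random.default_rng(seed)
    rows = []
    for chrom in track.chroms:
        sub = track.probes[track.probes["chrom"] == chrom]
        x = sub["log10_ratio"].to_numpy(dtype=float)
        for lo, hi in segment_chromosome(x, alpha, n_perm, rng):
            rows.append(
                {
                    "chrom": chrom,
                    "start": int(sub["start"].iloc[lo]),
                    "end": int(sub["end"].iloc[hi - 1]),
                    "n_probes": hi - lo,
                    "mean": float(x[lo:hi].mean()),
                }
            )
    return SegmentSet(segments=pd.DataFrame(rows))


def segment_values(track: ProbeTrack, segments: SegmentSet) -> np.ndarray:
    """Per-probe segmented value (the mean of the segment containing the probe)."""
    out = np.full(len(track.probes), np.nan)
    for _, seg in segments.segments.iterrows():
        mask = (
            (track.probes["chrom"] == seg["chrom"])
            & (track.probes["start"] >= seg["start"])
            & (track.probes["end"] <= seg["end"])
        ).to_numpy()
        out[mask] = seg["mean"]
    return out


def gene_copy_number(
    segments: SegmentSet,
    track: ProbeTrack,
    genes: pd.DataFrame,
    min_probes: int = 3,
) -> pd.DataFrame:
    """Average segmented log10 ratio of probes overlapping each gene.

    ``genes`` is a BED-like DataFrame with columns chrom, start, end, gene
    (0-based half-open intervals; any overlap with a probe counts). Genes with
    fewer than ``min_probes`` overlapping probes, or on chromosomes absent from
    the track, are dropped.
    """
    for col in ("chrom", "start", "end", "gene"):
        if col not in genes.columns:
            raise InputError(f"gene model missing column {col!r}")
    seg_vals = segment_values(track, segments)
    track_chroms = set(track.chroms)
    rows = []
    for _, g in genes.iterrows():
        if g["chrom"] not in track_chroms:
            log.info("gene %s on chromosome %s absent from track; dropped",
                     g["gene"], g["chrom"])
            continue
        mask = (
            (track.probes["chrom"] == g["chrom"])
            & (track.probes["start"] < g["end"])
            & (track.probes["end"] > g["start"])
        ).to_numpy()
        n = int(mask.sum())
        if n < min_probes:
            continue
        rows.append(
            {
                "gene": g["gene"],
                "chrom": g["chrom"],
                "n_probes": n,
                "log10_ratio": float(np.nanmean(seg_vals[mask])),
            }
        )
    return pd.DataFrame(rows, columns=["gene", "chrom", "n_probes", "log10_ratio"])


def met_specific_cnas(
    gene_cn: dict,
    expression: PairedExpressionCohort | None = None,
    amp_thresh: float = 0.1,
    r_min: float = 0.7,
    min_cases: int = 2,
) -> pd.DataFrame:
    """Recurrent tissue-specific amplification/loss calls with expression support.

    Parameters
    ----------
    gene_cn : mapping case -> {"primary": DataFrame, "metastasis": DataFrame}
        Gene copy-number tables as produced by :func:`gene_copy_number`.
    expression : optional matched cohort used for the expression-copy-number
        Pearson correlation; genes without expression are flagged
        ``uncorrelatable`` and reported without r.

    A gene is called amplified in a sample when its log10 score exceeds
    ``amp_thresh`` (lost below ``-amp_thresh``); tissue-specific when called in
    one tissue of a case and not the other; recurrent when tissue-specific the
    same way in at least ``min_cases`` cases. Reported genes must have
    expression-CN Pearson r > ``r_min`` (across all samples with both values)
    unless uncorrelatable.
    """
    if len(gene_cn) < min_cases:
        raise InputError(f"need >= {min_cases} cases with both tissues")

    # collect per (gene, direction, specificity) the supporting cases
    support: dict[tuple[str, str, str], list] = {}
    cn_values: dict[str, dict[tuple, float]] = {}
    for case, tissues in gene_cn.items():
        if "primary" not in tissues or "metastasis" not in tissues:
            raise InputError(f"case {case!r} lacks a tissue")
        pri = tissues["primary"].set_index("gene")["log10_ratio"]
        met = tissues["metastasis"].set_index("gene")["log10_ratio"]
        shared = pri.index.intersection(met.index)
        for gene in shared:
            cn_values.setdefault(gene, {})[(case, "primary")] = float(pri[gene])
            cn_values.setdefault(gene, {})[(case, "metastasis")] = float(met[gene])
            for direction, sign in (("amplified", 1.0), ("lost", -1.0)):
                called_pri = sign * pri[gene] > amp_thresh
                called_met = sign * met[gene] > amp_thresh
                if called_met and not called_pri:
                    support.setdefault((gene, direction, "met-only"), []).append(case)
                elif called_pri and not called_met:
                    support.setdefault((gene, direction, "primary-only"), []).append(case)

    rows = []
    for (gene, direction, spec), cases in sorted(support.items()):
        if len(cases) < min_cases:
            continue
        r = np.nan
        correlatable = False
        if expression is not None and gene in expression.values.index:
            pairs = []
            for (case, tissue), cn in cn_values[gene].items():
                try:
                    sample = expression.sample_of(case, tissue)
                except IndexError:
                    continue
                pairs.append((cn, float(expression.values.loc[gene, sample])))
            if len(pairs) >= 3:
                arr = np.asarray(pairs)
                if arr[:, 0].std() > 0 and arr[:, 1].std() > 0:
                    r = float(np.corrcoef(arr[:, 0], arr[:, 1])[0, 1])
                    correlatable = True
        if correlatable and not r > r_min:
            continue
        rows.append(
            {
                "gene": gene,
                "direction": direction,
                "specificity": spec,
                "n_cases": len(cases),
                "cases": ",".join(map(str, cases)),
                "pearson_r": r,
                "uncorrelatable": not correlatable,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "gene", "direction", "specificity", "n_cases", "cases",
            "pearson_r", "uncorrelatable",
        ],
    )


@dataclass
class CNAClustering:
    linkage: np.ndarray
    samples: list[str]
    excluded: list[str]
    pair_table: pd.DataFrame | None  # case, primary, metastasis, co_clustered

    @property
    def n_pairs_coclustered(self) -> int:
        if self.pair_table is None:
            return 0
        return int(self.pair_table["co_clustered"].sum())


def cluster_cna_profiles(
    matrix: pd.DataFrame, sample_map: pd.DataFrame | None = None
) -> CNAClustering:
    """Average-linkage clustering of samples under 1 - Pearson distance.

    ``matrix`` is genes x samples. Zero-variance samples have undefined
    correlation and are excluded with a warning. When ``sample_map`` (sample ->
    case, tissue) is given, the report marks a case's primary and metastasis as
    co-clustering when the linkage merges them while both are still singleton
    clusters — i.e. each is the other's nearest neighbour in the dendrogram.
    """
    if matrix.shape[1] < 3:
        raise InputError("clustering requires >= 3 samples")
    variances = matrix.std(axis=0)
    excluded = variances.index[variances == 0].tolist()
    if excluded:
        log.warning("excluding zero-variance samples: %s", excluded)
    kept = [s for s in matrix.columns if s not in set(excluded)]
    X = matrix[kept].to_numpy(dtype=float).T
    dist = pdist(X, metric="correlation")
    Z = hierarchy.linkage(dist, method="average")

    pair_table = None
    if sample_map is not None:
        idx = {s: i for i, s in enumerate(kept)}
        # merges of two singletons
        n = len(kept)
        singleton_merges = set()
        for row in Z:
            a, b = int(row[0]), int(row[1])
            if a < n and b < n:
                singleton_merges.add(frozenset((a, b)))
        rows = []
        for case, grp in sample_map.groupby("case"):
            tissues = grp["tissue"]
            try:
                pri = grp.index[tissues == "primary"][0]
                met = grp.index[tissues == "metastasis"][0]
            except IndexError:
                continue
            if pri not in idx or met not in idx:
                continue
            rows.append(
                {
                    "case": case,
                    "primary": pri,
                    "metastasis": met,
                    "co_clustered": frozenset((idx[pri], idx[met])) in singleton_merges,
                }
            )
        pair_table = pd.DataFrame(rows)
    return CNAClustering(linkage=Z, samples=kept, excluded=excluded, pair_table=pair_table)
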