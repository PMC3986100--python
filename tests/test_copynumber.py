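"""Smoothing, CBS segmentation, gene-level scoring, CNA calls, clustering."""
import numpy as np
import pandas as pd
import pytest

from metsig.config import SimConfig
from metsig.datatypes import InputError, ProbeTrack, SegmentSet
from metsig.copynumber import (
    cluster_cna_profiles,
    gene_copy_number,
    met_specific_cnas,
    segment_cbs,
    segment_values,
    smooth_outliers,
)
from metsig.simulate import simulate_probe_track


def _track(values, chrom="chr1", spacing=1000, length=60) -> ProbeTrack:
    n = len(values)
    starts = np.arange(n) * spacing
    return ProbeTrack(
        probes=pd.DataFrame(
            {
                "chrom": chrom,
                "start": starts,
                "end": starts + length,
                "probe": [f"p{i}" for i in range(n)],
                "log10_ratio": np.asarray(values, dtype=float),
            }
        )
    )


class TestSmoothOutliers:
    def test_constant_track_unchanged(self):
        track = _track(np.zeros(50))
        out = smooth_outliers(track)
        assert np.array_equal(out.probes["log10_ratio"], track.probes["log10_ratio"])

    def test_spike_pulled_to_window_median(self):
        rng = np.random.default_rng(1)
        x = rng.normal(0, 0.05, 101)
        x[50] = 10.0
        out = smooth_outliers(_track(x), region=10, nsd=3.0)
        smoothed = out.probes["log10_ratio"].to_numpy()
        assert abs(smoothed[50]) < 0.5  # pulled into the window-median neighborhood
        # non-outlier probes untouched
        untouched = np.delete(np.arange(101), 50)
        assert np.allclose(smoothed[untouched], x[untouched])

    def test_no_point_beyond_nsd_is_identity(self):
        rng = np.random.default_rng(2)
        x = rng.normal(0, 0.05, 80)
        x = np.clip(x, -0.1, 0.1)  # well within 3 SD of the rolling median
        out = smooth_outliers(_track(x), region=10, nsd=5.0)
        assert np.allclose(out.probes["log10_ratio"], x)

    def test_short_chromosome_truncates_windows(self):
        # fewer probes than a full 2*region+1 window: truncated, no error
        rng = np.random.default_rng(0)
        x = rng.normal(0, 0.05, 15)
        x[7] = 5.0
        out = smooth_outliers(_track(x), region=10, nsd=3.0)
        assert out.probes["log10_ratio"].iloc[7] < 5.0


class TestSegmentCBS:
    def test_constant_track_single_segment(self):
        rng = np.random.default_rng(3)
        track = _track(rng.normal(0, 0.05, 150))
        segs = segment_cbs(track, alpha=0.05, n_perm=200, seed=1)
        assert segs.n == 1
        assert segs.segments["n_probes"].iloc[0] == 150

    def test_single_breakpoint_located(self):
        rng = np.random.default_rng(4)
        x = np.concatenate([rng.normal(0, 0.05, 100), rng.normal(0.3, 0.05, 100)])
        segs = segment_cbs(_track(x), alpha=0.05, n_perm=200, seed=2)
        assert segs.n == 2
        # boundary probe index of the second segment
        bp = segs.segments["start"].iloc[1] // 1000
        assert abs(bp - 100) <= 2

    def test_two_breakpoints_recover_levels(self):
        rng = np.random.default_rng(5)
        x = np.concatenate(
            [rng.normal(0, 0.05, 70), rng.normal(0.3, 0.05, 60),
             rng.normal(0, 0.05, 70)]
        )
        segs = segment_cbs(_track(x), alpha=0.05, n_perm=200, seed=3)
        assert segs.n == 3
        means = segs.segments["mean"].to_numpy()
        for got, want, n in zip(means, [0.0, 0.3, 0.0],
                                segs.segments["n_probes"]):
            assert abs(got - want) < 3 * 0.05 / np.sqrt(n)

    def test_track_mean_reconstructed_from_segments(self):
        rng = np.random.default_rng(6)
        x = np.concatenate([rng.normal(0, 0.05, 80), rng.normal(0.25, 0.05, 60)])
        track = _track(x)
        segs = segment_cbs(track, alpha=0.05, n_perm=150, seed=4)
        vals = segment_values(track, segs)
        assert not np.isnan(vals).any()
        # probe-weighted mean of segment means equals the track mean
        assert vals.mean() == pytest.approx(x.mean(), abs=1e-12)

    def test_min_perm_enforced(self):
        with pytest.raises(InputError):
            segment_cbs(_track(np.zeros(10)), n_perm=10)

    def test_null_first_split_rate_controlled(self):
        # type-I control at the first split under a constant-mean null
        rng = np.random.default_rng(7)
        alpha = 0.05
        splits = 0
        R = 120
        for _ in range(R):
            x = rng.normal(0, 0.05, 60)
            segs = segment_cbs(_track(x), alpha=alpha, n_perm=100,
                               rng=np.random.default_rng(rng.integers(2**31)))
            splits += segs.n > 1
        rate = splits / R
        assert rate <= alpha + 2 * np.sqrt(alpha * (1 - alpha) / R)


class TestGeneCopyNumber:
    def _segments(self):
        return SegmentSet(
            segments=pd.DataFrame(
                {
                    "chrom": ["chr1", "chr1"],
                    "start": [0, 3000],
                    "end": [3000 - 940, 5060],
                    "n_probes": [3, 2],
                    "mean": [0.2, -0.1],
                }
            )
        )

    def test_weighted_average_across_segments(self):
        # 3 probes in a 0.2 segment, 2 in a -0.1 segment -> 0.08
        x = [0.2, 0.2, 0.2, -0.1, -0.1]
        track = _track(x)
        segs = SegmentSet(
            segments=pd.DataFrame(
                {
                    "chrom": ["chr1", "chr1"],
                    "start": [0, 3000],
                    "end": [2060, 4060],
                    "n_probes": [3, 2],
                    "mean": [0.2, -0.1],
                }
            )
        )
        genes = pd.DataFrame(
            {"chrom": ["chr1"], "start": [0], "end": [4060], "gene": ["G1"]}
        )
        out = gene_copy_number(segs, track, genes)
        assert out.loc[0, "log10_ratio"] == pytest.approx((3 * 0.2 + 2 * -0.1) / 5)
        assert out.loc[0, "n_probes"] == 5

    def test_gene_inside_one_segment_gets_segment_mean(self):
        x = [0.15] * 6
        track = _track(x)
        segs = SegmentSet(
            segments=pd.DataFrame(
                {"chrom": ["chr1"], "start": [0], "end": [5060],
                 "n_probes": [6], "mean": [0.15]}
            )
        )
        genes = pd.DataFrame(
            {"chrom": ["chr1"], "start": [500], "end": [4700], "gene": ["G1"]}
        )
        out = gene_copy_number(segs, track, genes)
        assert out.loc[0, "log10_ratio"] == pytest.approx(0.15)

    def test_fewer_than_three_probes_dropped(self):
        x = [0.1] * 6
        track = _track(x)
        segs = SegmentSet(
            segments=pd.DataFrame(
                {"chrom": ["chr1"], "start": [0], "end": [5060],
                 "n_probes": [6], "mean": [0.1]}
            )
        )
        genes = pd.DataFrame(
            {
                "chrom": ["chr1", "chr1", "chr2"],
                "start": [0, 0, 0],
                "end": [1500, 5000, 5000],  # 2 probes, 5 probes, absent chrom
                "gene": ["small", "big", "elsewhere"],
            }
        )
        out = gene_copy_number(segs, track, genes)
        assert list(out["gene"]) == ["big"]

    def test_probe_order_shuffle_invariant(self):
        rng = np.random.default_rng(8)
        x = rng.normal(0.1, 0.02, 12)
        track = _track(x)
        shuffled = ProbeTrack(probes=track.probes.sample(frac=1, random_state=1))
        segs = SegmentSet(
            segments=pd.DataFrame(
                {"chrom": ["chr1"], "start": [0], "end": [11060],
                 "n_probes": [12], "mean": [float(x.mean())]}
            )
        )
        genes = pd.DataFrame(
            {"chrom": ["chr1"], "start": [0], "end": [11060], "gene": ["G"]}
        )
        a = gene_copy_number(segs, track, genes)
        b = gene_copy_number(segs, shuffled, genes)
        assert a.loc[0, "log10_ratio"] == pytest.approx(b.loc[0, "log10_ratio"])


class TestMetSpecificCNAs:
    def _gene_cn(self, met_vals, pri_vals, gene="ERBB2"):
        def table(v):
            return pd.DataFrame(
                {"gene": [gene], "chrom": ["chr1"], "n_probes": [4],
                 "log10_ratio": [v]}
            )

        return {
            f"case{i}": {"metastasis": table(m), "primary": table(p)}
            for i, (m, p) in enumerate(zip(met_vals, pri_vals))
        }

    def test_recurrent_met_only_amplification_called(self, tiny_cohort):
        gene_cn = self._gene_cn([0.3, 0.25, 0.0], [0.0, 0.02, 0.0], gene="g1")
        out = met_specific_cnas(gene_cn, expression=None, amp_thresh=0.1)
        row = out[(out["gene"] == "g1") & (out["specificity"] == "met-only")]
        assert len(row) == 1
        assert row["n_cases"].iloc[0] == 2
        assert bool(row["uncorrelatable"].iloc[0])

    def test_single_case_not_recurrent(self):
        gene_cn = self._gene_cn([0.3, 0.0, 0.0], [0.0, 0.0, 0.0])
        out = met_specific_cnas(gene_cn, amp_thresh=0.1)
        assert out.empty

    def test_correlation_filter(self):
        rng = np.random.default_rng(9)
        # build an expression cohort where g1 tracks copy number
        from metsig.datatypes import PairedExpressionCohort

        cases = [f"case{i}" for i in range(4)]
        cn_met = [0.3, 0.28, 0.0, 0.02]
        cn_pri = [0.0, 0.0, 0.0, 0.0]
        samples, rows_map = [], []
        expr_vals = []
        for i, c in enumerate(cases):
            for tissue, cn in (("primary", cn_pri[i]), ("metastasis", cn_met[i])):
                s = f"{c}_{tissue[0].upper()}"
                samples.append(s)
                rows_map.append({"sample": s, "case": c, "tissue": tissue})
                expr_vals.append(5.0 + 10.0 * cn + rng.normal(0, 0.01))
        cohort = PairedExpressionCohort(
            values=pd.DataFrame([expr_vals], index=["g1"], columns=samples),
            sample_map=pd.DataFrame(rows_map).set_index("sample"),
        )
        gene_cn = self._gene_cn(cn_met, cn_pri, gene="g1")
        gene_cn = {c: gene_cn[f"case{i}"] for i, c in enumerate(cases)}
        out = met_specific_cnas(gene_cn, expression=cohort, amp_thresh=0.1, r_min=0.7)
        assert list(out["gene"]) == ["g1"]
        assert out["pearson_r"].iloc[0] > 0.9


class TestClusterCNAProfiles:
    def test_duplicated_sample_merges_first(self):
        rng = np.random.default_rng(10)
        base = rng.normal(0, 1, 30)
        m = pd.DataFrame(
            {"a": base, "b": base.copy(), "c": rng.normal(0, 1, 30),
             "d": rng.normal(0, 1, 30)}
        )
        res = cluster_cna_profiles(m)
        first = res.linkage[0]
        merged = {res.samples[int(first[0])], res.samples[int(first[1])]}
        assert merged == {"a", "b"}
        assert first[2] == pytest.approx(0.0, abs=1e-12)

    def test_sign_flip_maximal_distance(self):
        rng = np.random.default_rng(11)
        base = rng.normal(0, 1, 40)
        m = pd.DataFrame({"a": base, "b": -base, "c": rng.normal(0, 1, 40)})
        from scipy.spatial.distance import pdist

        d_ab = pdist(m[["a", "b"]].to_numpy().T, metric="correlation")[0]
        assert d_ab == pytest.approx(2.0, abs=1e-12)
        res = cluster_cna_profiles(m)
        assert res.pair_table is None

    def test_zero_variance_sample_excluded(self):
        rng = np.random.default_rng(12)
        m = pd.DataFrame(
            {"a": rng.normal(0, 1, 20), "b": rng.normal(0, 1, 20),
             "c": rng.normal(0, 1, 20), "flat": np.zeros(20)}
        )
        res = cluster_cna_profiles(m)
        assert res.excluded == ["flat"]
        assert "flat" not in res.samples

    def test_planted_case_backbones_cocluster(self):
        """Pairs sharing a case-specific CNA backbone should co-cluster."""
        rng = np.random.default_rng(13)
        n_genes, n_cases = 200, 12
        samples, rows = [], []
        cols = {}
        for i in range(n_cases):
            case = f"case{i:02d}"
            backbone = rng.normal(0, 0.25, n_genes)  # shared CNA profile
            for tissue in ("primary", "metastasis"):
                s = f"{case}_{tissue[0].upper()}"
                cols[s] = backbone + rng.normal(0, 0.08, n_genes)
                rows.append({"sample": s, "case": case, "tissue": tissue})
        m = pd.DataFrame(cols)
        smap = pd.DataFrame(rows).set_index("sample")
        res = cluster_cna_profiles(m, sample_map=smap)
        assert res.pair_table is not None and len(res.pair_table) == 12
        assert res.n_pairs_coclustered >= 8
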