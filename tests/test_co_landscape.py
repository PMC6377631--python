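"""Bin calling, filtering, CO calling, map tracks, hot regions, profiles."""

import numpy as np
import pandas as pd
import pytest

from gametoco.co_landscape import (
    COCalls,
    GenotypeMatrix,
    arm_normalize,
    call_bins,
    call_cos,
    filter_bins,
    gene_distance_profile,
    genetic_map,
    hot_regions,
    resolution_stats,
)


def _geno(rows):
    return GenotypeMatrix(
        calls=pd.DataFrame(rows, columns=["sample", "chrom", "pos", "allele"])
    )


def _runs(sample, chrom, spec, start=1000, step=1000):
    """spec: list of (allele, count) -> rows with evenly spaced positions."""
    rows, pos = [], start
    for allele, k in spec:
        for _ in range(k):
            rows.append((sample, chrom, pos, allele))
            pos += step
    return rows


class TestCallBins:
    def test_two_clean_bins_one_junction(self):
        g = _geno(_runs("s1", "c1", [("P1", 25), ("P2", 25)]))
        bins = call_bins(g, min_snps=20)
        assert len(bins.bins) == 2
        assert list(bins.bins["parent"]) == ["P1", "P2"]
        cos = call_cos(bins, drop_short=False)
        assert len(cos.calls) == 1

    def test_short_interior_run_absorbed(self):
        g = _geno(_runs("s1", "c1", [("P1", 25), ("P2", 5), ("P1", 25)]))
        bins = call_bins(g, min_snps=20)
        assert len(bins.bins) == 1
        assert bins.bins.iloc[0]["parent"] == "P1"
        assert bins.bins.iloc[0]["n_snps"] == 50
        assert any(e["event"] == "absorbed_short_run" for e in bins.log)
        assert len(call_cos(bins, drop_short=False).calls) == 0

    def test_threshold_boundary_inclusive(self):
        g = _geno(_runs("s1", "c1", [("P1", 20), ("P2", 20)]))
        bins = call_bins(g, min_snps=20)
        assert len(bins.bins) == 2

    def test_missing_calls_skipped_not_run_breaking(self):
        rows = _runs("s1", "c1", [("P1", 12)])
        rows += [("s1", "c1", 13_000, "NA")]
        rows += _runs("s1", "c1", [("P1", 12), ("P2", 25)], start=14_000)
        bins = call_bins(_geno(rows), min_snps=20)
        assert len(bins.bins) == 2
        assert bins.bins.iloc[0]["n_snps"] == 24

    def test_unsorted_input_rejected(self):
        rows = [("s1", "c1", 2000, "P1"), ("s1", "c1", 1000, "P1")]
        with pytest.raises(ValueError):
            _geno(rows)


class TestFilterBins:
    def _multi_sample(self, n_samples=10, flip_in=()):
        """P1 chromosome with an interior P2 segment in selected samples."""
        rows = []
        for i in range(n_samples):
            s = f"s{i}"
            if i in flip_in:
                rows += _runs(s, "c1", [("P1", 40), ("P2", 25), ("P1", 40)])
            else:
                rows += _runs(s, "c1", [("P1", 105)])
        return _geno(rows)

    def test_shared_interior_bins_removed_everywhere(self):
        g = self._multi_sample(10, flip_in=(1, 3, 5, 7, 9))
        bins = filter_bins(call_bins(g), short_bp=10_000, shared_min_samples=3)
        shared = bins.bins[bins.bins["shared_removed"]]
        assert shared["sample"].nunique() == 5
        assert all(shared["parent"] == "P2")
        # COs flanking the artifact vanish after filtering
        cos = call_cos(bins, drop_short=False)
        assert len(cos.calls) == 0

    def test_rare_segment_not_removed(self):
        g = self._multi_sample(10, flip_in=(1, 3))
        bins = filter_bins(call_bins(g), short_bp=10_000, shared_min_samples=3)
        assert bins.bins["shared_removed"].sum() == 0

    def test_short_bin_flagging_threshold(self):
        # each bin spans 29 gaps x 10 kb = 290 kb
        g = _geno(_runs("s1", "c1", [("P1", 30), ("P2", 30)], step=10_000))
        b1 = filter_bins(call_bins(g), short_bp=300_000)
        assert b1.bins["short_flagged"].all()
        b2 = filter_bins(call_bins(g), short_bp=290_000)
        assert not b2.bins["short_flagged"].any()


class TestCallCOs:
    def test_midpoint_and_width(self):
        rows = _runs("s1", "c1", [("P1", 25)], start=1_000_000, step=1000)
        rows += _runs("s1", "c1", [("P2", 25)], start=10_200_000, step=1000)
        cos = call_cos(call_bins(_geno(rows)), drop_short=False)
        r = cos.calls.iloc[0]
        assert r["start"] == 1_024_000
        assert r["end"] == 10_200_000
        assert r["midpoint"] == pytest.approx((1_024_000 + 10_200_000) / 2)
        assert r["width"] == 10_200_000 - 1_024_000

    def test_single_bin_chromosome_no_cos(self):
        cos = call_cos(call_bins(_geno(_runs("s1", "c1", [("P1", 30)]))))
        assert len(cos.calls) == 0

    def test_resolution_stats(self):
        calls = COCalls(
            calls=pd.DataFrame(
                dict(sample=["a", "a"], chrom=["c1", "c1"],
                     start=[0, 0], end=[100_000, 300_000],
                     midpoint=[50_000, 150_000], width=[100_000, 300_000])
            ),
            n_samples=1,
        )
        assert resolution_stats(calls, 200_000) == pytest.approx(0.5)
        assert resolution_stats(calls, 400_000) == pytest.approx(1.0)


class TestGeneticMap:
    def _calls(self, midpoints, n_samples=100, chrom="c1"):
        df = pd.DataFrame(
            dict(sample=["s"] * len(midpoints), chrom=[chrom] * len(midpoints),
                 start=np.array(midpoints) - 50, end=np.array(midpoints) + 50,
                 midpoint=midpoints, width=[100] * len(midpoints))
        )
        return COCalls(calls=df, n_samples=n_samples)

    def test_window_cm_per_mb(self):
        calls = self._calls([1_000_000] * 6)
        track = genetic_map(calls, {"c1": 3_000_000}, window_bp=3_000_000)
        # 6 COs / 100 gametes in one 3 Mb window -> 3 cM over 3 Mb = 1 cM/Mb
        assert track.windows.iloc[0]["cm_per_mb"] == pytest.approx(1.0)

    def test_zero_cos_zero_rate(self):
        calls = self._calls([])
        track = genetic_map(calls, {"c1": 3_000_000})
        assert track.windows["cm_per_mb"].sum() == 0

    def test_total_cm_counting_identity(self):
        rng = np.random.default_rng(8)
        mids = rng.uniform(0, 9_000_000, 400)
        track = genetic_map(self._calls(list(mids)), {"c1": 9_000_000})
        mean_cos_per_gamete = 400 / 100
        assert track.total_cm == pytest.approx(50 * mean_cos_per_gamete)

    def test_missing_chromosome_size_rejected(self):
        with pytest.raises(ValueError):
            genetic_map(self._calls([100.0]), {"other": 1_000_000})


class TestHotRegions:
    def _track(self, values, chrom="c1"):
        w = pd.DataFrame(
            dict(chrom=[chrom] * len(values),
                 start=np.arange(len(values)) * 3_000_000,
                 end=(np.arange(len(values)) + 1) * 3_000_000,
                 n_cos=0, cm=0.0, cm_per_mb=values)
        )
        from gametoco.co_landscape import MapTrack

        return MapTrack(windows=w, n_samples=100, window_bp=3_000_000)

    def test_preference_rules(self):
        a = self._track([2.5, 1.5, 0.9, 1.2])
        b = self._track([1.0, 1.4, 0.9, 0.0])
        hot = hot_regions(a, b)
        labels = dict(zip(hot.regions["start"], hot.regions["label"]))
        assert labels[0] == "a_preferred"  # 2.5 >= 2*1.0
        assert labels[3_000_000] == "shared"  # 1.5 vs 1.4
        assert 6_000_000 not in labels  # 0.9/0.9 not hot
        assert labels[9_000_000] == "a_preferred"  # other sex zero

    def test_swap_symmetry(self):
        a = self._track([2.5, 1.5, 0.4, 1.2])
        b = self._track([1.0, 1.4, 1.8, 0.0])
        ab = hot_regions(a, b).regions
        ba = hot_regions(b, a).regions
        swap = {"a_preferred": "b_preferred", "b_preferred": "a_preferred",
                "shared": "shared"}
        assert list(ba["label"]) == [swap[x] for x in ab["label"]]

    def test_window_mismatch_rejected(self):
        a = self._track([1.5, 1.5])
        b = self._track([1.5])
        with pytest.raises(ValueError):
            hot_regions(a, b)


class TestArmNormalize:
    def _calls(self, mids):
        df = pd.DataFrame(
            dict(sample=["s"] * len(mids), chrom=["c1"] * len(mids),
                 start=np.array(mids) - 10, end=np.array(mids) + 10,
                 midpoint=mids, width=[20] * len(mids))
        )
        return COCalls(calls=df, n_samples=1)

    def test_fraction_from_telomere(self):
        out = arm_normalize(
            self._calls([10e6]), {"c1": (50e6, 51e6)}, {"c1": 100_000_000}
        )
        assert out.iloc[0]["arm"] == "short"
        assert out.iloc[0]["frac"] == pytest.approx(0.2)

    def test_centromere_co_excluded(self):
        out = arm_normalize(
            self._calls([50.5e6]), {"c1": (50e6, 51e6)}, {"c1": 100_000_000}
        )
        assert out.iloc[0]["in_centromere"]
        assert np.isnan(out.iloc[0]["frac"])

    def test_opposite_convention(self):
        out = arm_normalize(
            self._calls([10e6]), {"c1": (50e6, 51e6)}, {"c1": 100_000_000},
            convention="from_centromere",
        )
        assert out.iloc[0]["frac"] == pytest.approx(0.8)


class TestGeneDistanceProfile:
    def _genes(self, n=50, size=10_000, chrom_len=5_000_000):
        starts = np.linspace(100_000, chrom_len - 100_000, n).astype(int)
        return pd.DataFrame(
            dict(chrom=["c1"] * n, start=starts, end=starts + size,
                 gene_id=[f"g{i}" for i in range(n)])
        )

    def _calls(self, mids):
        df = pd.DataFrame(
            dict(sample=["s"] * len(mids), chrom=["c1"] * len(mids),
                 start=np.array(mids) - 100, end=np.array(mids) + 100,
                 midpoint=mids, width=[200] * len(mids))
        )
        return COCalls(calls=df, n_samples=1)

    def test_gene_start_anchor_zero(self):
        genes = self._genes()
        calls = self._calls([float(genes.iloc[0]["start"])])
        prof = gene_distance_profile(calls, genes, {"c1": 5_000_000}, seed=1)
        assert prof.observed[0] == pytest.approx(0.0)

    def test_gene_end_enrichment_detected(self):
        genes = self._genes()
        mids = [float(e) for e in genes["end"][:40]]
        prof = gene_distance_profile(
            self._calls(mids), genes, {"c1": 5_000_000}, n_null=5, seed=2
        )
        assert prof.ks_pvalue < 1e-3

    def test_uniform_positions_not_rejected(self):
        rng = np.random.default_rng(9)
        mids = list(rng.uniform(100_000, 4_900_000, 60))
        prof = gene_distance_profile(
            self._calls(mids), self._genes(), {"c1": 5_000_000}, seed=3
        )
        assert prof.ks_pvalue > 0.01

    def test_empty_annotation_rejected(self):
        with pytest.raises(ValueError):
            gene_distance_profile(
                self._calls([1000.0]), pd.DataFrame(), {"c1": 5_000_000}, seed=0
            )
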