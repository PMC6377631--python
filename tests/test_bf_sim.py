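"""Beam-Film simulator: precursor laws, designation, maturation, thinning."""

import numpy as np
import pytest

from gametoco.bf_sim import (
    BFParams,
    CLASS_I_IMMATURE,
    CLASS_I_MATURE,
    CLASS_II,
    PrecursorArray,
    apply_maturation,
    designate_class1,
    place_precursors,
    simulate_bivalents,
    sprinkle_class2,
    to_chromatid,
)


class TestBFParams:
    @pytest.mark.parametrize(
        "kw",
        [dict(N=0), dict(N=-1), dict(E=1.2), dict(B=-0.1), dict(Y=2),
         dict(A=0.5), dict(Smax=0), dict(L=0), dict(L=1.5), dict(M=-0.2),
         dict(T2prob=1.1)],
    )
    def test_invalid_values_rejected(self, kw):
        with pytest.raises(ValueError):
            BFParams(**kw)

    def test_json_roundtrip_lossless(self):
        p = BFParams(N=16, E=0.7, B=0.3, Y=0.9, A=2.5, Smax=3.1, L=0.23,
                     M=0.84, T2prob=0.062)
        assert BFParams.from_json(p.to_json()) == p


class TestPlacePrecursors:
    def test_fixed_count_when_B1_Y1(self):
        arrays = place_precursors(BFParams(N=16, B=1, Y=1), 100, seed=0)
        assert all(a.n_active == 16 for a in arrays)
        assert all(len(a.positions) == 16 for a in arrays)

    def test_active_count_binomial_mean(self):
        arrays = place_precursors(BFParams(N=16, B=1, Y=0.5), 5000, seed=1)
        active = np.array([a.n_active for a in arrays])
        se = np.sqrt(16 * 0.25 / 5000)
        assert abs(active.mean() - 8.0) < 3 * se

    def test_sensitivity_skew_lowers_median(self):
        a1 = place_precursors(BFParams(N=16, A=1), 5000, seed=2)
        a6 = place_precursors(BFParams(N=16, A=6), 5000, seed=2)
        med1 = np.median(np.concatenate([a.sensitivities for a in a1]))
        med6 = np.median(np.concatenate([a.sensitivities for a in a6]))
        assert med6 < med1
        assert med1 == pytest.approx(0.5, abs=0.02)

    def test_jittered_even_grid_at_E1(self):
        arrays = place_precursors(BFParams(N=4, E=1, B=1), 500, seed=3)
        grid = np.array([0.125, 0.375, 0.625, 0.875])
        for arr in arrays:
            # each precursor stays within a quarter-stratum of its grid point
            assert np.all(np.abs(arr.positions - grid) <= 0.25 / 4 + 1e-12)
        pooled = np.concatenate([a.positions - grid for a in arrays])
        assert abs(pooled.mean()) < 0.005  # jitter is centred

    def test_uniform_law_at_E0(self):
        arrays = place_precursors(BFParams(N=8, E=0, B=1), 4000, seed=4)
        pooled = np.concatenate([a.positions for a in arrays])
        # i.i.d. uniform: mean 1/2, variance 1/12
        assert abs(pooled.mean() - 0.5) < 0.01
        assert abs(pooled.var() - 1 / 12) < 0.005

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            place_precursors(BFParams(), 0, seed=0)


class TestDesignation:
    def test_single_hot_precursor_designates(self):
        arr = PrecursorArray([0.5], [0.9], [True])
        (idx,) = designate_class1([arr], Smax=2.0, L=0.2)
        assert list(idx) == [0]

    def test_zero_distance_relief_annihilates_twin(self):
        arr = PrecursorArray([0.5, 0.5], [0.9, 0.8], [True, True])
        (idx,) = designate_class1([arr], Smax=5.0, L=0.2)
        assert len(idx) == 1

    def test_empty_precursors_empty_designation(self):
        arr = PrecursorArray([], [], [])
        (idx,) = designate_class1([arr], Smax=2.0, L=0.2)
        assert len(idx) == 0

    def test_inactive_precursors_never_designate(self):
        arr = PrecursorArray([0.2, 0.8], [0.9, 0.9], [False, False])
        (idx,) = designate_class1([arr], Smax=5.0, L=0.2)
        assert len(idx) == 0

    @pytest.mark.parametrize("bad", [dict(Smax=0), dict(L=0)])
    def test_invalid_arguments(self, bad):
        arr = PrecursorArray([0.5], [0.9], [True])
        kw = dict(Smax=2.0, L=0.2)
        kw.update(bad)
        with pytest.raises(ValueError):
            designate_class1([arr], **kw)

    def test_mean_class1_decreases_with_L(self):
        means = []
        for L in (0.15, 0.3, 0.45):
            s = simulate_bivalents(BFParams(Smax=3.0, L=L), 5000, seed=5)
            means.append(s.counts([CLASS_I_MATURE]).mean())
        assert means[0] >= means[1] >= means[2]
        assert means[0] > means[2]

    def test_mean_class1_increases_with_Smax(self):
        means = []
        for smax in (1.5, 2.5, 4.0):
            s = simulate_bivalents(BFParams(Smax=smax, L=0.3), 5000, seed=6)
            means.append(s.counts([CLASS_I_MATURE]).mean())
        assert means[0] <= means[1] <= means[2]
        assert means[0] < means[2]


class TestMaturationAndClass2:
    def test_M_extremes(self):
        des = [np.arange(5), np.arange(3)]
        assert all(m.all() for m in apply_maturation(des, 1.0, seed=0))
        assert not any(m.any() for m in apply_maturation(des, 0.0, seed=0))

    def test_maturation_binomial(self):
        # the fitted KYS male maturation rate
        des = [np.arange(10) for _ in range(1000)]
        mats = apply_maturation(des, 0.84, seed=1)
        total = sum(m.sum() for m in mats)
        sd = np.sqrt(10000 * 0.84 * 0.16)
        assert abs(total - 8400) < 3 * sd

    def test_T2_zero_gives_no_class2(self):
        arrays = place_precursors(BFParams(N=16), 200, seed=2)
        des = designate_class1(arrays, Smax=2.5, L=0.3)
        c2 = sprinkle_class2(arrays, des, 0.0, seed=3)
        assert sum(len(c) for c in c2) == 0

    def test_class2_closed_form_expectation(self, female_like):
        s = simulate_bivalents(female_like, 5000, seed=7)
        des = s.counts([CLASS_I_MATURE, CLASS_I_IMMATURE]).mean()
        c2 = s.counts([CLASS_II])
        expected = female_like.T2prob * (female_like.N - des)
        se = c2.std(ddof=1) / np.sqrt(len(c2))
        assert abs(c2.mean() - expected) < 3 * se + 0.01

    def test_class2_never_on_designated_precursor(self):
        arrays = place_precursors(BFParams(N=16), 200, seed=4)
        des = designate_class1(arrays, Smax=2.5, L=0.3)
        c2 = sprinkle_class2(arrays, des, 1.0, seed=5)
        for d, c in zip(des, c2):
            assert not set(d) & set(c)


class TestSimulateBivalents:
    def test_zero_bivalents_rejected(self, female_like):
        with pytest.raises(ValueError):
            simulate_bivalents(female_like, 0, seed=0)

    def test_tiny_smax_gives_no_class1(self):
        s = simulate_bivalents(BFParams(Smax=1e-6), 500, seed=1)
        assert s.counts([CLASS_I_MATURE, CLASS_I_IMMATURE]).sum() == 0

    def test_recommended_size_runs(self, female_bivalents):
        assert female_bivalents.n_bivalents == 5000

    def test_determinism(self, female_like):
        a = simulate_bivalents(female_like, 300, seed=42)
        b = simulate_bivalents(female_like, 300, seed=42)
        assert all(np.array_equal(x, y) for x, y in zip(a.positions, b.positions))
        assert all(np.array_equal(x, y) for x, y in zip(a.classes, b.classes))

    def test_prefix_stability_when_n_grows(self, female_like):
        big = simulate_bivalents(female_like, 500, seed=42)
        small = simulate_bivalents(female_like, 100, seed=42)
        assert all(
            np.array_equal(x, y)
            for x, y in zip(big.positions[:100], small.positions)
        )

    def test_maturation_thinning_identity(self):
        p = BFParams(Smax=2.6, L=0.25, M=0.7)
        s = simulate_bivalents(p, 5000, seed=8)
        mature = s.counts([CLASS_I_MATURE])
        immature = s.counts([CLASS_I_IMMATURE])
        des = mature + immature
        frac = mature.sum() / des.sum()
        se = np.sqrt(0.7 * 0.3 / des.sum())
        assert abs(frac - 0.7) < 3 * se


class TestChromatidTransform:
    def test_empty_bivalent_gives_empty_chromatid(self):
        from gametoco.bf_sim import BivalentCOSet

        bset = BivalentCOSet([np.array([])], [np.array([], dtype=object)])
        ch = to_chromatid(bset, seed=0)
        assert len(ch.positions[0]) == 0

    def test_thinning_halves_mean(self, male_bivalents):
        ch = to_chromatid(male_bivalents, seed=9)
        biv_mean = male_bivalents.counts([CLASS_I_MATURE, CLASS_II]).mean()
        n = male_bivalents.n_bivalents
        se = np.sqrt(biv_mean * 0.25 / n) * 2
        assert abs(ch.counts().mean() - biv_mean / 2) < 3 * se + 0.02

    def test_positions_subset_of_source(self, female_bivalents):
        ch = to_chromatid(female_bivalents, seed=10)
        for cp, bp in zip(ch.positions, female_bivalents.positions):
            assert set(np.round(cp, 12)) <= set(np.round(bp, 12))

    def test_immature_never_transmitted(self):
        p = BFParams(Smax=2.6, L=0.25, M=0.0, T2prob=0.0)
        s = simulate_bivalents(p, 500, seed=11)
        ch = to_chromatid(s, seed=12)
        assert ch.counts().sum() == 0
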