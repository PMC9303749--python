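"""LiDAR transmission proxy, extinction fitting and profile comparison."""

import numpy as np
import pytest

from canopysphere import (
    PointCloud,
    SlabCanopy,
    als_pai_pad,
    compare_pad,
    cylinder_filter,
    fit_extinction,
    pad_profile,
    simulate_point_cloud,
    transmission_profile,
)


class TestCylinderFilter:
    def test_boundary_point_is_retained(self):
        pc = PointCloud(points=[[10.0, 0.0, 5.0]])
        kept = cylinder_filter(pc, center=(0.0, 0.0), radius=10.0)
        assert len(kept) == 1

    def test_empty_cylinder_raises(self):
        pc = PointCloud(points=[[20.0, 0.0, 5.0], [0.0, 25.0, 2.0]])
        with pytest.raises(ValueError, match="no points"):
            cylinder_filter(pc, center=(0.0, 0.0), radius=10.0)

    def test_counts_match_brute_force_distance_check(self):
        rng = np.random.default_rng(2)
        pts = rng.uniform(-20, 20, size=(500, 3))
        pc = PointCloud(points=pts)
        kept = cylinder_filter(pc, center=(1.0, -2.0), radius=10.0)
        n_expected = 0
        for x, y, z in pts:
            if ((x - 1.0) ** 2 + (y + 2.0) ** 2) ** 0.5 <= 10.0:
                n_expected += 1
        assert len(kept) == n_expected


class TestTransmissionProfile:
    def test_counting_arithmetic(self):
        # 100 points: 60 above 10 m, 40 below -> T(10) = 0.4
        z = np.concatenate([np.full(60, 15.0), np.full(40, 5.0)])
        pc = PointCloud(points=np.column_stack([np.zeros(100), np.zeros(100), z]))
        tp = transmission_profile(pc, n_levels=50)
        level_idx = np.argmin(np.abs(tp.levels - 10.0))
        assert tp.levels[level_idx] == pytest.approx(10.0, abs=tp.layer_width)
        T10 = 1.0 - (z > tp.levels[level_idx]).sum() / 100
        assert tp.T[level_idx] == pytest.approx(T10)

    def test_top_level_sees_full_transmission(self):
        rng = np.random.default_rng(0)
        z = rng.uniform(2.0, 20.0, 200)
        pc = PointCloud(points=np.column_stack([np.zeros(200), np.zeros(200), z]))
        tp = transmission_profile(pc)
        assert tp.T[-1] == 1.0
        assert np.all(np.diff(tp.T) >= 0)  # monotone in height
        assert np.all((tp.T >= 0) & (tp.T <= 1))

    def test_attenuated_cloud_matches_beer_lambert(self):
        """T at the canopy base of a simulated cloud lies within 3 binomial
        SEs of exp(-k * PAI) = exp(-1.5)."""
        canopy = SlabCanopy(layers=[(2.0, 8.0, 0.5)])  # PAI 3 above 2 m
        pc = simulate_point_cloud(canopy, k_true=0.5, n_pulses=20_000, seed=4)
        tp = transmission_profile(pc, n_levels=50, ground_cut=1.5)
        expected = np.exp(-0.5 * 3.0)
        se = np.sqrt(expected * (1 - expected) / 20_000)
        assert tp.T[0] == pytest.approx(expected, abs=3 * se)

    def test_all_ground_points_raise(self):
        pc = PointCloud(points=[[0, 0, 0.5], [1, 1, 1.0]])
        with pytest.raises(ValueError, match="no canopy returns"):
            transmission_profile(pc)


class TestFitExtinction:
    def test_noiseless_through_origin(self):
        heights = np.arange(10, dtype=float)
        pai = np.linspace(4.0, 0.5, 10)
        T = np.exp(-0.5 * pai)
        k, diag = fit_extinction(
            list(zip(heights, T)), list(zip(heights, pai))
        )
        assert k == pytest.approx(0.5, rel=1e-12)
        assert diag["rss"] == pytest.approx(0.0, abs=1e-20)

    def test_single_pair_is_insufficient(self):
        with pytest.raises(ValueError, match="fewer than 2"):
            fit_extinction([(0.0, 0.5)], [(0.0, 2.0)])

    def test_noisy_fit_equals_closed_form_ols(self):
        rng = np.random.default_rng(8)
        heights = np.arange(10, dtype=float)
        x = np.linspace(0.5, 4.0, 10)
        y = 0.4 * x + rng.normal(0, 0.05, 10)
        T = np.exp(-y)
        k, diag = fit_extinction(list(zip(heights, T)), list(zip(heights, x)))
        assert 0.3 <= k <= 0.5
        assert k == pytest.approx(float(np.sum(x * y) / np.sum(x * x)), rel=1e-12)

    def test_saturated_levels_are_dropped_with_warning(self):
        heights = [0.0, 1.0, 2.0, 3.0]
        T = [0.0, 0.5, 0.7, 0.9]
        pai = [6.0, 1.386, 0.713, 0.211]
        with pytest.warns(UserWarning, match="saturated"):
            k, diag = fit_extinction(
                list(zip(heights, T)), list(zip(heights, pai))
            )
        assert diag["n_pairs"] == 3

    def test_unmatched_heights_are_excluded(self):
        # ALS levels every 0.5 m up to 2 m; a PAI height at 10 m has no match
        T_pairs = [(z, 0.8) for z in np.arange(0.0, 2.5, 0.5)]
        pai_pairs = [(0.0, 1.0), (2.0, 0.5), (10.0, 0.1)]
        k, diag = fit_extinction(T_pairs, pai_pairs)
        assert diag["n_pairs"] == 2


class TestAlsPaiPad:
    def test_closed_form_inversion(self):
        tp_levels = np.array([0.0, 1.0])
        from canopysphere import TransmissionProfile

        tp = TransmissionProfile(
            levels=tp_levels,
            T=np.array([np.exp(-1.0), 1.0]),
            n_above=np.array([50, 0]),
            n_total=100,
        )
        prof = als_pai_pad(tp, k=0.5)
        assert prof.pai[0] == pytest.approx(2.0)
        assert prof.pai[1] == 0.0
        assert prof.pad[0] == pytest.approx(2.0)  # (2 - 0)/1

    def test_fitted_k_recovers_canopy_pai(self):
        """Full synthetic closure: cloud + true PAI profile -> fitted k ->
        Beer's-law PAI at the canopy base within 10% of the truth."""
        canopy = SlabCanopy(layers=[(2.0, 8.0, 0.5)])
        pc = simulate_point_cloud(canopy, k_true=0.5, n_pulses=50_000, seed=9)
        tp = transmission_profile(pc)
        pai_pairs = [(float(z), canopy.pai_above(float(z))) for z in tp.levels[::4]]
        k, _ = fit_extinction(list(zip(tp.levels, tp.T)), pai_pairs)
        assert k == pytest.approx(0.5, rel=0.1)
        prof = als_pai_pad(tp, k)
        assert prof.pai[0] == pytest.approx(3.0, rel=0.1)


class TestComparePad:
    def _uas(self):
        return pad_profile([0.0, 2.0, 4.0, 6.0], [4.0, 3.0, 1.5, 0.5])

    def test_identical_profiles_have_zero_rss(self):
        uas = self._uas()
        from canopysphere import ALSProfile

        als = ALSProfile(
            k=0.5,
            levels=uas.heights,
            pai=uas.pai,
            pad=uas.pad.copy(),
            layer_midpoints=uas.layer_midpoints.copy(),
        )
        rss, h = compare_pad(uas, als)
        assert rss == 0.0

    def test_constant_offset_rss(self):
        uas = self._uas()
        from canopysphere import ALSProfile

        als = ALSProfile(
            k=0.5,
            levels=uas.heights,
            pai=uas.pai,
            pad=uas.pad + 0.1,
            layer_midpoints=uas.layer_midpoints.copy(),
        )
        rss, h = compare_pad(uas, als)
        assert rss == pytest.approx(0.01 * len(uas.pad))

    def test_fine_layers_average_like_brute_force(self):
        uas = self._uas()
        rng = np.random.default_rng(12)
        fine_mid = np.arange(0.25, 6.0, 0.5)
        fine_pad = rng.uniform(0.0, 2.0, fine_mid.size)
        from canopysphere import ALSProfile

        als = ALSProfile(
            k=0.5, levels=None, pai=None, pad=fine_pad, layer_midpoints=fine_mid
        )
        rss, h_max = compare_pad(uas, als)
        # independent per-layer averaging loop
        rss_bf = 0.0
        best = (-1.0, None)
        for l in range(3):
            lo, hi = uas.heights[l], uas.heights[l + 1]
            sel = [p for m, p in zip(fine_mid, fine_pad) if lo <= m < hi]
            resid = uas.pad[l] - sum(sel) / len(sel)
            rss_bf += resid**2
            if abs(resid) > best[0]:
                best = (abs(resid), uas.layer_midpoints[l])
        assert rss == pytest.approx(rss_bf)
        assert h_max == pytest.approx(best[1])

    def test_disjoint_profiles_raise(self):
        uas = self._uas()
        from canopysphere import ALSProfile

        als = ALSProfile(
            k=0.5, levels=None, pai=None,
            pad=np.array([1.0]), layer_midpoints=np.array([50.0]),
        )
        with pytest.raises(ValueError, match="overlap"):
            compare_pad(uas, als)
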