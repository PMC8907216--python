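import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nanotopo.quantify import (AxialProfile, BiGaussianFit, Roi,
                               axial_profile, compute_axial_params,
                               fit_bigaussian, fit_population,
                               gaussian_range, render_colorcoded,
                               render_zstack, tile_rois)


def locs_df(x, y, z, frame=None):
    n = len(x)
    return pd.DataFrame({
        "frame": np.zeros(n, int) if frame is None else frame,
        "x": np.asarray(x, float), "y": np.asarray(y, float),
        "z": np.asarray(z, float)})


class TestRenderZstack:
    def test_single_localization_single_voxel(self):
        stack = render_zstack(locs_df([5.0], [5.0], [5.0]))
        assert stack.counts.sum() == 1
        assert stack.counts.max() == 1

    def test_count_conservation(self):
        rng = np.random.default_rng(0)
        n = 5000
        stack = render_zstack(locs_df(rng.uniform(0, 2000, n),
                                      rng.uniform(0, 2000, n),
                                      rng.uniform(-200, 200, n)))
        assert stack.counts.sum() == n

    def test_bin_edge_goes_to_upper_bin(self):
        # z = 20 sits exactly on the edge between [0, 20) and [20, 40)
        stack = render_zstack(locs_df([0.0, 0.0], [0.0, 0.0], [0.0, 20.0]))
        assert stack.counts.shape[0] == 2
        assert stack.counts[0].sum() == 1 and stack.counts[1].sum() == 1

    def test_out_of_range_dropped_and_counted(self):
        stack = render_zstack(locs_df([0, 0, 0], [0, 0, 0], [0.0, 50.0, 500.0]),
                              z_range=(-100, 100))
        assert stack.counts.sum() == 2
        assert stack.n_out_of_range == 1

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            render_zstack(locs_df([], [], []))


class TestRenderColorcoded:
    def test_flat_layer_uniform_hue_and_transparency(self):
        rng = np.random.default_rng(1)
        n = 2000
        df = locs_df(rng.uniform(0, 1000, n), rng.uniform(0, 1000, n),
                     np.full(n, 100.0))
        rgba, mean_z, count = render_colorcoded(df)
        occ = count > 0
        assert np.allclose(mean_z[occ], 100.0)
        # occupied pixels share one hue; empty pixels fully transparent
        hues = rgba[occ][:, :3] / np.maximum(
            rgba[occ][:, :3].max(axis=1, keepdims=True), 1e-12)
        assert np.allclose(hues, hues[0], atol=1e-6)
        assert np.all(rgba[~occ][:, 3] == 0.0)

    def test_two_level_surface_is_bimodal(self):
        rng = np.random.default_rng(2)
        n = 4000
        z = np.where(rng.random(n) < 0.5, 0.0, 200.0)
        df = locs_df(rng.uniform(0, 4000, n), rng.uniform(0, 4000, n), z)
        _, mean_z, count = render_colorcoded(df)
        vals = mean_z[count > 0]
        lo = (vals < 50).sum()
        hi = (vals > 150).sum()
        assert lo > 0.2 * len(vals) and hi > 0.2 * len(vals)


class TestTileRois:
    def test_full_square_mask_tiles_5x5(self):
        mask = np.ones((100, 100), bool)  # 10 x 10 um at 100 nm pixels
        rois = tile_rois(mask, (0.0, 0.0), 100.0, roi_side=2000.0)
        assert len(rois) == 25
        assert all(r.fraction == 1.0 for r in rois.rois)

    def test_partial_coverage_threshold(self):
        # interior notches keep the bounding box (and hence the ROI grid
        # anchor) fixed while removing area from the first candidate
        mask = np.ones((40, 20), bool)
        mask[4:12, 5:15] = False   # removes 80/400 = 20% of candidate 1
        rois = tile_rois(mask, (0.0, 0.0), 100.0, roi_side=2000.0)
        fractions = sorted(r.fraction for r in rois.rois)
        assert len(rois) == 2 and fractions[0] == pytest.approx(0.8)
        mask[4:16, 5:15] = False   # now 30% removed -> dropped
        rois = tile_rois(mask, (0.0, 0.0), 100.0, roi_side=2000.0)
        assert len(rois) == 1

    def test_empty_mask_raises(self):
        with pytest.raises(ValueError):
            tile_rois(np.zeros((10, 10), bool), (0.0, 0.0), 100.0)


class TestAxialProfile:
    def test_single_level_single_bin(self):
        df = locs_df(np.full(50, 500.0), np.full(50, 500.0), np.full(50, 70.0))
        stack = render_zstack(df)
        roi = Roi(0, 0.0, 0.0, 2000.0, 1.0)
        profile = axial_profile(stack, roi)
        assert (profile.counts > 0).sum() == 1
        assert profile.total == 50

    def test_disjoint_rois_partition_counts(self):
        rng = np.random.default_rng(3)
        n = 3000
        df = locs_df(rng.uniform(0, 4000, n), rng.uniform(0, 4000, n),
                     rng.uniform(0, 300, n))
        stack = render_zstack(df)
        total = 0
        for x0 in (0.0, 2000.0):
            for y0 in (0.0, 2000.0):
                total += axial_profile(stack, Roi(0, x0, y0, 2000.0, 1.0)).total
        assert total == n


class TestBiGaussianFit:
    TRUE = (300.0, 100.0, 20.0, 120.0, 250.0, 60.0)

    @staticmethod
    def model(x, a1, m1, s1, a2, m2, s2):
        return (a1 * np.exp(-0.5 * ((x - m1) / s1) ** 2)
                + a2 * np.exp(-0.5 * ((x - m2) / s2) ** 2))

    def profile(self, noisy=False, seed=0):
        z = np.arange(10.0, 400.0, 20.0)
        y = self.model(z, *self.TRUE)
        if noisy:
            y = np.random.default_rng(seed).poisson(y).astype(float)
        return AxialProfile(z_centers=z, counts=y)

    def test_noiseless_recovery_within_2_percent(self):
        f = fit_bigaussian(self.profile())
        for est, true in zip((f.a1, f.m1, f.s1, f.a2, f.m2, f.s2), self.TRUE):
            assert est == pytest.approx(true, rel=0.02)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_poisson_recovery_within_10_percent(self, seed):
        prof = self.profile(noisy=True, seed=seed)
        assert prof.total >= 1000
        f = fit_bigaussian(prof)
        for est, true in zip((f.a1, f.m1, f.s1, f.a2, f.m2, f.s2), self.TRUE):
            assert est == pytest.approx(true, rel=0.10)

    def test_single_gaussian_profile_degenerates_stably(self):
        z = np.arange(0.0, 400.0, 20.0)
        y = 200.0 * np.exp(-0.5 * ((z - 180.0) / 40.0) ** 2)
        zws = []
        for jitter in (0.0, 1e-6, -1e-6):
            f = fit_bigaussian(AxialProfile(z, y + jitter))
            zws.append(compute_axial_params(f).z_w)
        assert np.ptp(zws) / np.mean(zws) < 0.05

    def test_sparse_profile_rejected(self):
        z = np.arange(0.0, 100.0, 20.0)
        with pytest.raises(ValueError):
            fit_bigaussian(AxialProfile(z, np.ones_like(z)))

    def test_components_ordered_by_mean(self):
        f = fit_bigaussian(self.profile())
        assert f.m1 <= f.m2


class TestAxialParams:
    def test_degenerate_equal_components(self):
        f = BiGaussianFit(a1=1, m1=50.0, s1=10.0, a2=1, m2=50.0, s2=10.0,
                          goodness=0)
        p = compute_axial_params(f)
        assert p.z_w == pytest.approx(23.55)
        assert p.p_p == 0.0 and p.delta_fwhm == 0.0

    def test_direct_evaluation(self):
        f = BiGaussianFit(a1=1, m1=100.0, s1=20.0, a2=1, m2=180.0, s2=30.0,
                          goodness=0)
        p = compute_axial_params(f)
        assert p.z_w == pytest.approx(138.875)
        assert p.p_p == pytest.approx(80.0)
        assert p.delta_fwhm == pytest.approx(23.55)

    def test_homogeneous_scaling(self):
        f1 = BiGaussianFit(1, 100.0, 20.0, 1, 180.0, 30.0, 0)
        f2 = BiGaussianFit(1, 200.0, 40.0, 1, 360.0, 60.0, 0)
        p1, p2 = compute_axial_params(f1), compute_axial_params(f2)
        assert p2.z_w == pytest.approx(2 * p1.z_w)
        assert p2.p_p == pytest.approx(2 * p1.p_p)
        assert p2.delta_fwhm == pytest.approx(2 * p1.delta_fwhm)

    @settings(deadline=None, max_examples=200)
    @given(m1=st.floats(-500, 500), dm=st.floats(0, 500),
           s1=st.floats(10, 1000), s2=st.floats(10, 1000))
    def test_width_invariants(self, m1, dm, s1, s2):
        f = BiGaussianFit(1, m1, s1, 1, m1 + dm, s2, 0)
        p = compute_axial_params(f)
        assert p.z_w >= p.p_p - 1e-9
        assert p.z_w >= 2.355 * (s1 + s2) / 2 - 1e-9
        assert p.delta_fwhm >= 0


class TestPopulation:
    @pytest.mark.parametrize("mu,sigma,expected", [
        (247.0, 83.0, (149, 345)),
        (63.0, 22.0, (37, 89)),
        (57.0, 15.0, (39, 75)),
        (88.0, 28.0, (55, 121)),
        (120.0, 25.0, (91, 149)),
    ])
    def test_gaussian_range_rule(self, mu, sigma, expected):
        assert gaussian_range(mu, sigma) == expected

    def test_zero_sigma_range_collapses(self):
        assert gaussian_range(140.0, 0.0) == (140, 140)

    def test_mono_gaussian_population_recovery(self):
        rng = np.random.default_rng(5)
        values = rng.normal(120.0, 25.0, 2000)
        pop = fit_population(values, "mono_gaussian")
        assert pop.mu[0] == pytest.approx(120.0, abs=3.0)
        assert pop.sigma[0] == pytest.approx(25.0, rel=0.12)

    def test_bi_gaussian_population_recovery(self):
        rng = np.random.default_rng(6)
        values = np.concatenate([rng.normal(141.0, 27.0, 1500),
                                 rng.normal(247.0, 83.0, 700)])
        pop = fit_population(values, "bi_gaussian", bin_width=10.0)
        assert pop.mu[0] == pytest.approx(141.0, abs=8.0)
        assert pop.mu[1] == pytest.approx(247.0, abs=25.0)

    def test_exponential_tau_recovery(self):
        rng = np.random.default_rng(7)
        values = rng.exponential(23.0, 3000)
        pop = fit_population(values, "exponential", bin_width=5.0)
        assert pop.tau == pytest.approx(23.0, rel=0.15)

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError):
            fit_population(np.ones(10), "mono_gaussian")
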