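"""Landscape container, ratio/global inference, surfaces and geometry."""

import numpy as np
import pytest
from scipy.stats import norm

import invasionscape as iv
from invasionscape.landscape import (Landscape,
                                     expected_invasiveness, infer_global,
                                     infer_ratio, interpolate_2d, local_geometry,
                                     slope_sign_pattern)
from invasionscape.synthgen import (CloneSpec, DoseGrid, generate_benchmark_dataset,
                                    expected_log10_mean, up_down_up_truth,
                                    valley_truth)


class TestLandscapeContainer:
    def test_validation(self):
        with pytest.raises(ValueError):
            Landscape([0.0, 1.0], [0.5, 1.5])   # w out of range
        with pytest.raises(ValueError):
            Landscape([1.0, 0.0], [0.5, 0.5])   # decreasing grid
        with pytest.raises(ValueError):
            Landscape([0.0, 1.0], [0.5])        # shape mismatch

    def test_evaluation_holds_boundary_values(self):
        ls = Landscape([0.0, 1.0], [0.2, 0.8])
        assert ls(-5.0) == 0.2
        assert ls(5.0) == 0.8
        assert ls(0.5) == pytest.approx(0.5)


class TestInferRatio:
    def test_identical_samples_recover_flat_landscape(self):
        rng = np.random.default_rng(0)
        z = rng.normal(3.0, 0.3, size=20_000)
        ls = infer_ratio(z, z, v=0.4)
        np.testing.assert_allclose(ls.w[ls.support_mask], 0.4, atol=0.01)

    def test_step_truth_recovered_from_truncated_sample(self):
        # seeded N(0,1), truth 0.5 above 0: invaded is the upper truncation
        rng = np.random.default_rng(1)
        z = rng.normal(0.0, 1.0, size=100_000)
        invade = rng.uniform(size=z.size) < np.where(z >= 0, 0.5, 0.0)
        ls = infer_ratio(z, z[invade], v=invade.mean())
        sup = ls.support_mask
        below = sup & (ls.z_grid < -0.15)
        above = sup & (ls.z_grid > 0.15)
        assert np.max(ls.w[below]) < 0.05
        np.testing.assert_allclose(ls.w[above], 0.5, atol=0.05)

    def test_valley_truth_recovered_on_support(self, valley_benchmark):
        ds = valley_benchmark
        ls = infer_ratio(ds.seeded[0], ds.invaded[0], ds.records[0].v)
        sup = ls.support_mask
        err = np.max(np.abs(ls.w[sup] - ds.truth(ls.z_grid[sup])))
        assert err < 0.05

    def test_inconsistent_zero_invasiveness(self):
        rng = np.random.default_rng(2)
        z = rng.normal(size=100)
        with pytest.raises(ValueError):
            infer_ratio(z, z[:10], v=0.0)


class TestInferGlobal:
    def _sweep(self, truth, doses, sigma=0.2, n=20_000, seed=0):
        ds = generate_benchmark_dataset(CloneSpec(sigma_log10=sigma),
                                        DoseGrid(doses), truth,
                                        n_per_dose=n, seed=seed)
        return ds

    def test_flat_truth_recovered(self):
        truth = Landscape.flat(0.3, 0.5, 5.0)
        ds = self._sweep(truth, (0.0, 0.2, 1.0, 10.0), n=10_000)
        ls = infer_global(ds.dose_sweep())
        np.testing.assert_allclose(ls.w[ls.support_mask], 0.3, atol=0.03)
        assert np.abs(np.asarray(ls.meta["residuals"])).max() < 0.02

    def test_nonmonotone_shape_recovered(self):
        spec = CloneSpec(sigma_log10=0.2)
        doses = (0.0, 0.05, 0.1, 0.2, 0.35, 0.5, 1.0, 2.0, 5.0, 10.0)
        zm = [expected_log10_mean(spec, d) for d in doses]
        truth = up_down_up_truth(min(zm) - 0.8, max(zm) + 0.8)
        ds = generate_benchmark_dataset(spec, DoseGrid(doses), truth,
                                        n_per_dose=20_000, seed=5)
        ls = infer_global(ds.dose_sweep())
        nodes = np.asarray(ls.meta["nodes"])
        coef = np.asarray(ls.meta["coef"])
        supz = ls.z_grid[ls.support_mask]
        inside = (nodes >= supz.min()) & (nodes <= supz.max())
        assert (slope_sign_pattern(coef[inside], tol=0.03)
                == slope_sign_pattern(truth(nodes[inside]), tol=0.03)
                == (1, -1, 1))

    def test_single_dose_is_underdetermined(self):
        truth = Landscape.flat(0.3, 0.5, 5.0)
        ds = self._sweep(truth, (1.0,), n=1000)
        with pytest.raises(ValueError):
            infer_global(ds.dose_sweep())

    def test_agrees_with_ratio_estimator_where_identifiable(self):
        # dense knots, vanishing ridge, one informative dose per region:
        # both estimators see the same flat truth
        truth = Landscape.flat(0.4, 0.5, 5.5)
        ds = self._sweep(truth, (0.0, 0.5, 5.0), n=20_000, seed=9)
        global_ls = infer_global(ds.dose_sweep(), knots=6, ridge=1e-6)
        ratio_ls = infer_ratio(ds.seeded[1], ds.invaded[1], ds.records[1].v)
        sup = ratio_ls.support_mask
        diff = global_ls(ratio_ls.z_grid[sup]) - ratio_ls.w[sup]
        assert np.max(np.abs(diff)) < 0.05


class TestExpectedInvasiveness:
    def test_certain_invasion(self):
        ls = Landscape.flat(1.0, -3, 3)
        rng = np.random.default_rng(0)
        assert expected_invasiveness(ls, rng.normal(size=1000)) == 1.0

    def test_step_landscape_half_mass(self):
        ls = Landscape.from_callable(lambda z: np.where(z >= 0, 0.5, 0.0), -6, 6, 1024)
        rng = np.random.default_rng(1)
        z = rng.normal(size=500_000)
        # analytic: 0.5 * P(z >= 0) = 0.25
        assert expected_invasiveness(ls, z) == pytest.approx(0.25, abs=0.005)

    def test_monotone_in_pointwise_landscape_order(self):
        rng = np.random.default_rng(2)
        z = rng.normal(size=5000)
        grid = np.linspace(-4, 4, 64)
        w_a = 0.3 + 0.2 * np.sin(grid)
        w_b = w_a + 0.1
        v_a = expected_invasiveness(Landscape(grid, np.clip(w_a, 0, 1)), z)
        v_b = expected_invasiveness(Landscape(grid, np.clip(w_b, 0, 1)), z)
        assert v_a <= v_b

    def test_matches_monte_carlo_oracle(self, valley_benchmark):
        ds = valley_benchmark
        z = ds.seeded[0].log10_values()
        v_exp = expected_invasiveness(ds.truth, ds.seeded[0])
        sims = [iv.invasionmc.simulate_invasion(z, ds.truth, seed=s).v_sim
                for s in range(50)]
        se = np.sqrt(v_exp * (1 - v_exp) / z.size)
        assert abs(np.mean(sims) - v_exp) < 3 * se


class TestSurface2D:
    def test_interpolates_input_points_exactly(self):
        pts = [(0.0, 0.1, 0.2), (1.0, 0.1, 0.5), (0.0, 0.4, 0.3), (1.0, 0.5, 0.9)]
        surf = interpolate_2d(pts)
        for m, c, v in pts:
            val, extrap = surf.query(m, c)
            assert val == pytest.approx(v, abs=1e-8)
            assert not extrap

    def test_reproduces_plane(self):
        # thin-plate splines with linear polynomial tail reproduce planes
        plane = lambda m, c: 0.2 + 0.3 * m - 0.1 * c
        pts = [(m, c, plane(m, c)) for m in (0.0, 1.0) for c in (0.0, 1.0)]
        surf = interpolate_2d(pts)
        val, extrap = surf.query(0.37, 0.61)
        assert val == pytest.approx(plane(0.37, 0.61), abs=1e-6)
        assert not extrap

    def test_extrapolation_flagged(self):
        pts = [(0.0, 0.0, 0.1), (1.0, 0.0, 0.2), (0.0, 1.0, 0.3), (1.0, 1.0, 0.4)]
        _, extrap = interpolate_2d(pts).query(5.0, 5.0)
        assert extrap

    def test_collinear_points_rejected(self):
        pts = [(x, 2 * x, 0.1 * x) for x in range(4)]
        with pytest.raises(ValueError):
            interpolate_2d(pts)

    def test_conflicting_duplicates_rejected(self):
        pts = [(0.0, 0.0, 0.1), (0.0, 0.0, 0.9), (1.0, 0.0, 0.2), (0.0, 1.0, 0.3)]
        with pytest.raises(ValueError):
            interpolate_2d(pts)


class TestLocalGeometry:
    def test_linear_landscape_is_upslope(self):
        grid = np.linspace(0, 2, 128)
        ls = Landscape(grid, np.clip(0.1 + 0.4 * grid, 0, 1))
        rep = local_geometry(ls, 1.0, 0.3)
        assert rep.kind == "upslope"
        assert rep.curvature == pytest.approx(0.0, abs=1e-6)

    def test_quadratic_dip_is_valley(self):
        grid = np.linspace(-1, 1, 256)
        ls = Landscape(grid, 0.2 + 0.5 * grid**2)
        rep = local_geometry(ls, 0.0, 0.5)
        assert rep.kind == "valley"
        assert rep.slope == pytest.approx(0.0, abs=1e-6)
        assert rep.curvature > 0

    def test_peak_detected(self):
        grid = np.linspace(-1, 1, 256)
        ls = Landscape(grid, np.clip(0.8 - 0.5 * grid**2, 0, 1))
        assert local_geometry(ls, 0.0, 0.5).kind == "peak"

    def test_window_outside_support_is_error(self):
        grid = np.linspace(0, 1, 64)
        mask = grid < 0.5
        ls = Landscape(grid, np.full(64, 0.3), support_mask=mask)
        with pytest.raises(ValueError):
            local_geometry(ls, 0.6, 0.2)

    def test_noisy_flat_inference_classified_flat(self):
        # inferred landscapes from a flat truth read as flat at the
        # default tolerance in >= 95% of replicates
        spec = CloneSpec(sigma_log10=0.25)
        truth = Landscape.flat(0.35, 0.5, 6.0)
        z0 = expected_log10_mean(spec, 0.5)
        hits = 0
        n_reps = 50
        for s in range(n_reps):
            ds = generate_benchmark_dataset(spec, DoseGrid((0.5,)), truth,
                                            n_per_dose=50_000, seed=1000 + s)
            ls = infer_ratio(ds.seeded[0], ds.invaded[0], ds.records[0].v)
            hits += local_geometry(ls, z0, 0.3).kind == "flat"
        assert hits >= 0.95 * n_reps


class TestSlopeSignPattern:
    def test_collapses_and_thresholds(self):
        assert slope_sign_pattern([0.1, 0.4, 0.41, 0.2, 0.5], tol=0.05) == (1, -1, 1)
        assert slope_sign_pattern([0.3, 0.3, 0.3]) == ()
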