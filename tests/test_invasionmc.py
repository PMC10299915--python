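"""Monte Carlo invasion: thinning law, OU coupling, selection directions."""

import numpy as np
import pytest
from scipy.stats import norm, ttest_1samp

from invasionscape.invasionmc import simulate_invasion, simulate_invasion_ou
from invasionscape.landscape import Landscape, infer_ratio
from invasionscape.ouproc import OUParams, stationary_sample


def _step_landscape():
    return Landscape.from_callable(lambda z: np.where(z >= 0, 0.5, 0.0), -6, 6, 1024)


class TestSimulateInvasion:
    def test_certain_invasion(self):
        rng = np.random.default_rng(0)
        z = rng.normal(size=1000)
        res = simulate_invasion(z, Landscape.flat(1.0, -6, 6), seed=1)
        assert res.v_sim == 1.0
        np.testing.assert_array_equal(res.invaded_values, z)

    def test_flat_landscape_binomial_rate(self):
        rng = np.random.default_rng(1)
        z = rng.normal(size=100_000)
        res = simulate_invasion(z, Landscape.flat(0.3, -6, 6), seed=2)
        se = np.sqrt(0.3 * 0.7 / 100_000)
        assert res.v_sim == pytest.approx(0.3, abs=3 * se)

    def test_step_landscape_truncated_normal_mean(self):
        rng = np.random.default_rng(2)
        z = rng.normal(size=100_000)
        res = simulate_invasion(z, _step_landscape(), seed=3)
        assert res.v_sim == pytest.approx(0.25, abs=0.01)
        # mean of upper half-normal: phi(0)/(1 - Phi(0)) = 0.7979
        assert res.invaded_values.mean() == pytest.approx(
            norm.pdf(0) / norm.sf(0), abs=0.02)

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(3)
        z = rng.normal(size=1000)
        a = simulate_invasion(z, Landscape.flat(0.5, -6, 6), seed=7)
        b = simulate_invasion(z, Landscape.flat(0.5, -6, 6), seed=7)
        np.testing.assert_array_equal(a.invaded_values, b.invaded_values)

    def test_empty_population_rejected(self):
        with pytest.raises(ValueError):
            simulate_invasion(np.array([]), Landscape.flat(0.5, -6, 6), seed=0)

    def test_histograms_share_bins(self):
        rng = np.random.default_rng(4)
        z = rng.normal(size=10_000)
        res = simulate_invasion(z, _step_landscape(), seed=5)
        assert res.histograms["seeded"].size == res.histograms["invaded"].size == 64

    def test_thinning_identity_roundtrip(self):
        # feeding simulation output back to the ratio estimator recovers w
        rng = np.random.default_rng(5)
        z = rng.normal(3.0, 0.3, size=50_000)
        truth = Landscape.from_callable(
            lambda x: np.clip(0.2 + 0.5 * (x - 3.0), 0.05, 0.95), 1.5, 4.5)
        res = simulate_invasion(z, truth, seed=6)
        ls = infer_ratio(z, res.invaded_values, res.v_sim)
        sup = ls.support_mask
        assert np.max(np.abs(ls.w[sup] - truth(ls.z_grid[sup]))) < 0.05


class TestSelectionDirections:
    """Slopes shift the invaded mean; curvature shifts its spread."""

    MU, SIGMA = 3.0, 0.2

    def _landscape(self, kind):
        mu = self.MU
        shapes = {
            "upslope": lambda z: 0.4 + 1.0 * (z - mu),
            "downslope": lambda z: 0.4 - 1.0 * (z - mu),
            "valley": lambda z: 0.15 + 3.5 * (z - mu) ** 2,
            "peak": lambda z: 0.75 - 3.5 * (z - mu) ** 2,
        }
        return Landscape.from_callable(
            lambda z: np.clip(shapes[kind](z), 0.05, 0.95), mu - 1.5, mu + 1.5)

    def _replicate_shifts(self, kind, n_reps=20, n=10_000):
        ls = self._landscape(kind)
        d_mean, d_sd = [], []
        for s in range(n_reps):
            rng = np.random.default_rng(100 + s)
            z = rng.normal(self.MU, self.SIGMA, size=n)
            res = simulate_invasion(z, ls, seed=200 + s)
            d_mean.append(res.invaded_values.mean() - z.mean())
            d_sd.append(res.invaded_values.std() - z.std())
        return np.array(d_mean), np.array(d_sd)

    @pytest.mark.parametrize("kind,stat,sign", [
        ("upslope", "mean", +1), ("downslope", "mean", -1),
        ("valley", "sd", +1), ("peak", "sd", -1),
    ])
    def test_shift_direction_significant(self, kind, stat, sign):
        d_mean, d_sd = self._replicate_shifts(kind)
        shifts = d_mean if stat == "mean" else d_sd
        t = ttest_1samp(sign * shifts, 0.0, alternative="greater")
        assert t.pvalue < 0.01


class TestSimulateInvasionOU:
    PARAMS = OUParams(mu=3.0, sigma=0.25, tau=24.0)

    def test_frozen_limit_matches_static_assay(self):
        # tau >> assay: endpoint levels are the stationary draw itself
        frozen = OUParams(mu=3.0, sigma=0.25, tau=1e9)
        ls = Landscape.from_callable(
            lambda z: np.clip(0.2 + 0.6 * (z - 3.0), 0, 1), 1.5, 4.5)
        v_ou, v_static = [], []
        for s in range(20):
            res = simulate_invasion_ou(frozen, ls, 20_000, assay_hours=20.0,
                                       seed=s)
            v_ou.append(res.v_sim)
            z = stationary_sample(frozen, 20_000, rng=1000 + s)
            v_static.append(simulate_invasion(z, ls, seed=2000 + s).v_sim)
        se = np.sqrt(0.25 / 20_000) / np.sqrt(20)
        assert np.mean(v_ou) == pytest.approx(np.mean(v_static), abs=3 * 2 * se)

    def test_flat_landscape_insensitive_to_tau(self):
        ls = Landscape.flat(0.4, 0.0, 6.0)
        vs = []
        for tau in (1.0, 24.0, 1000.0):
            res = simulate_invasion_ou(self.PARAMS.with_tau(tau), ls, 50_000,
                                       assay_hours=20.0, seed=3)
            vs.append(res.v_sim)
        se = np.sqrt(0.4 * 0.6 / 50_000)
        assert max(vs) - min(vs) < 6 * se

    def test_fast_fluctuations_blunt_disruptive_selection(self):
        # a fitness valley widens the invaded distribution of seeding-time
        # levels only if levels persist through the assay: fast OU mixing
        # decorrelates the seeding level from the invasion decision
        mu = 3.0
        ls = Landscape.from_callable(
            lambda z: np.clip(0.15 + 3.5 * (z - mu) ** 2, 0.05, 0.95),
            mu - 1.5, mu + 1.5)
        gaps = {}
        for tau in (0.5, 1e6):
            g = []
            for s in range(10):
                res = simulate_invasion_ou(self.PARAMS.with_tau(tau), ls, 20_000,
                                           assay_hours=20.0, seed=500 + s,
                                           record="seeding")
                g.append(res.invaded_values.std() - res.seeded_values.std())
            gaps[tau] = np.mean(g)
        assert gaps[1e6] > 0
        assert gaps[0.5] < 0.5 * gaps[1e6]

    def test_hazard_mode_runs_and_bounds(self):
        ls = Landscape.flat(0.5, 0.0, 6.0)
        res = simulate_invasion_ou(self.PARAMS, ls, 5_000, assay_hours=20.0,
                                   eval_mode="hazard", seed=9)
        assert 0.0 <= res.v_sim <= 1.0
        assert res.n_invaded == len(res.invaded_values)

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError):
            simulate_invasion_ou(self.PARAMS, Landscape.flat(0.5, 0, 6), 10,
                                 assay_hours=1.0, eval_mode="bogus", seed=0)
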