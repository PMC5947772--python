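"""Global geometry refinement and post-integration cell refinement."""

import numpy as np
import pandas as pd
import pytest

from sweepint.geometry import predict_reflections
from sweepint.refine import (
    Parameterization,
    RefinementError,
    levenberg_marquardt,
    refine_cell_from_two_theta,
    refine_geometry,
    residuals_and_weights,
)
from sweepint.simulate import default_experiment


def synthetic_observations(exp, n=400, seed=0, noise_px=0.0, noise_phi=0.0):
    """Noise-free (or noisy) centroid observations generated from the model."""
    pred = predict_reflections(exp, 3.5)
    pred = pred[np.abs(pred.zeta) > 0.15].reset_index(drop=True)
    rng = np.random.default_rng(seed)
    pred = pred.iloc[np.sort(rng.choice(len(pred), n, replace=False))]
    obs = pred[["h", "k", "l", "x", "y", "phi"]].copy().reset_index(drop=True)
    if noise_px:
        obs["x"] += rng.normal(0, noise_px, n)
        obs["y"] += rng.normal(0, noise_px, n)
    if noise_phi:
        obs["phi"] += rng.normal(0, noise_phi, n)
    obs["var_x"] = obs["var_y"] = max(noise_px**2, 1 / 12)
    obs["var_phi"] = max(noise_phi**2, exp.scan.oscillation**2 / 12)
    obs["indexed"] = True
    return obs


@pytest.fixture(scope="module")
def exp():
    return default_experiment()


class TestParameterization:
    def test_zero_vector_reproduces_models(self, exp):
        par = Parameterization(exp)
        out = par.apply(par.x0())
        assert np.allclose(out.crystal.ub, exp.crystal.ub, atol=1e-15)
        assert np.allclose(out.detector[0].origin, exp.detector[0].origin)
        assert np.allclose(out.beam.s0_direction, exp.beam.s0_direction)

    def test_perturb_then_invert_roundtrip(self, exp):
        par = Parameterization(exp)
        rng = np.random.default_rng(1)
        x = rng.uniform(-0.1, 0.1, par.n_parameters)
        pert = par.apply(x)
        back = Parameterization(pert, par.free_blocks).apply(-x)
        assert np.abs(back.beam.s0_direction - exp.beam.s0_direction).max() < 1e-10
        assert np.abs(back.detector[0].origin - exp.detector[0].origin).max() < 1e-9
        assert np.abs(back.crystal.u - exp.crystal.u).max() < 1e-10

    def test_unknown_block_rejected(self, exp):
        with pytest.raises(RefinementError):
            Parameterization(exp, ("detector", "nonsense"))


class TestResiduals:
    def test_zero_for_self_consistent_observations(self, exp):
        obs = synthetic_observations(exp)
        resid, weights, valid = residuals_and_weights(obs, exp)
        assert valid.all()
        assert np.abs(resid).max() < 1e-9
        assert (weights > 0).all()

    def test_detector_shift_appears_in_x_residuals(self, exp):
        obs = synthetic_observations(exp)
        par = Parameterization(exp, ("detector",))
        x = par.x0()
        x[0] = 0.5  # +0.5 mm along the fast axis
        shifted = par.apply(x)
        resid, _, valid = residuals_and_weights(obs, shifted)
        assert abs(abs(resid[valid, 0].mean()) - 0.5) < 0.05
        assert abs(resid[valid, 1].mean()) < 0.05


class TestLevenbergMarquardt:
    def test_quadratic_bowl_converges(self):
        target = np.array([3.0, -2.0])

        def fun(x):
            return x - target

        x, hist, n_iter, conv, null = levenberg_marquardt(fun, np.zeros(2))
        assert np.allclose(x, target, atol=1e-8)
        assert all(b <= a + 1e-15 for a, b in zip(hist, hist[1:]))

    def test_null_space_reported(self):
        def fun(x):
            return np.array([x[0] - 1.0, x[0] + 1.0])  # x[1] unconstrained

        x, hist, n_iter, conv, null = levenberg_marquardt(fun, np.zeros(2))
        assert null == [1]


class TestRefineGeometry:
    def test_start_at_truth_is_stationary(self, exp):
        obs = synthetic_observations(exp)
        refined, stats = refine_geometry(obs, exp)
        assert stats.rmsd_x_mm < 1e-6 and stats.rmsd_phi_deg < 1e-6
        assert np.abs(refined.crystal.u - exp.crystal.u).max() < 1e-7
        assert np.abs(refined.detector[0].origin - exp.detector[0].origin).max() < 1e-6

    def test_cost_non_increasing_and_order_invariant(self, exp):
        obs = synthetic_observations(exp, noise_px=0.3, noise_phi=0.1, seed=5)
        refined, stats = refine_geometry(
            obs, exp, free_blocks=("crystal_orientation", "detector")
        )
        hist = np.asarray(stats.cost_history)
        assert (np.diff(hist) <= 1e-9 * hist[0]).all()
        shuffled = obs.sample(frac=1.0, random_state=7).reset_index(drop=True)
        refined2, stats2 = refine_geometry(
            shuffled, exp, free_blocks=("crystal_orientation", "detector")
        )
        assert stats2.rmsd_x_mm == pytest.approx(stats.rmsd_x_mm, rel=1e-6)

    def test_cell_recovery_under_centroid_noise(self, exp):
        """0.3 px centroid noise over a 90 deg scan leaves the refined cell
        lengths within 0.1 % of truth."""
        obs = synthetic_observations(exp, n=500, noise_px=0.3, seed=9)
        par = Parameterization(exp, ("crystal_cell",))
        x = par.x0()
        x[:3] = [0.02, -0.02, 0.01]  # start slightly off the true cell
        start = par.apply(x)
        refined, stats = refine_geometry(
            obs, start, free_blocks=("crystal_orientation", "crystal_cell")
        )
        got = np.asarray(refined.crystal.cell[:3])
        true = np.asarray(exp.crystal.cell[:3])
        assert np.abs(got / true - 1.0).max() < 1e-3

    def test_too_few_reflections_raise(self, exp):
        obs = synthetic_observations(exp, n=4)
        with pytest.raises(RefinementError):
            refine_geometry(obs, exp)


class TestCellFromTwoTheta:
    def make_table(self, exp, n=200, noise_deg=0.0, seed=0):
        from sweepint.geometry import two_theta

        pred = predict_reflections(exp, 3.5)
        rng = np.random.default_rng(seed)
        pred = pred.iloc[np.sort(rng.choice(len(pred), n, replace=False))]
        tt = two_theta(exp.beam, r=pred[["h", "k", "l"]].to_numpy(float)
                       @ exp.crystal.ub.T)
        return pd.DataFrame(
            {"h": pred.h.to_numpy(), "k": pred.k.to_numpy(), "l": pred.l.to_numpy(),
             "two_theta_obs": tt + rng.normal(0, noise_deg, n)}
        )

    def test_exact_recovery(self, exp):
        table = self.make_table(exp)
        cell, esds, stats = refine_cell_from_two_theta(table, exp.crystal, exp)
        assert np.allclose(cell, exp.crystal.cell, rtol=1e-6)
        assert np.all(esds < 1e-4)

    def test_esds_positive_with_noise(self, exp):
        table = self.make_table(exp, noise_deg=0.01, seed=1)
        cell, esds, stats = refine_cell_from_two_theta(table, exp.crystal, exp)
        assert (esds > 0).all()

    def test_esd_coverage(self, exp):
        """With 0.01 deg noise on 2-theta the true cell lies within 3 esds in
        at least 95 % of seeded trials."""
        true = np.asarray(exp.crystal.cell)
        hits = 0
        trials = 100
        for s in range(trials):
            table = self.make_table(exp, noise_deg=0.01, seed=100 + s)
            cell, esds, _ = refine_cell_from_two_theta(table, exp.crystal, exp)
            if np.all(np.abs(np.asarray(cell) - true) <= 3.0 * esds + 1e-12):
                hits += 1
        assert hits >= 95

    def test_too_few_reflections_raise(self, exp):
        table = self.make_table(exp, n=4)
        with pytest.raises(RefinementError):
            refine_cell_from_two_theta(table, exp.crystal, exp)
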