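"""Laboratory-frame ray computation, reciprocal-space mapping and
rotation-method reflection prediction."""

import numpy as np
import pytest

from sweepint.geometry import (
    Beam,
    Crystal,
    Experiment,
    GeometryError,
    Panel,
    map_to_rlp,
    pixel_to_ray,
    predict_reflections,
    rotation_about_axis,
    two_theta,
)
from sweepint.simulate import default_experiment


@pytest.fixture()
def beam():
    return Beam(s0_direction=[0.0, 0.0, 1.0], wavelength=1.0)


@pytest.fixture()
def panel():
    # beam-normal panel, 100 mm away, 250 x 250 pixels of 0.1 mm; the beam
    # axis passes through the centre of pixel (100, 100)
    return Panel(
        origin=np.array([-10.05, -10.05, 100.0]),
        fast_axis=[1.0, 0.0, 0.0],
        slow_axis=[0.0, 1.0, 0.0],
        pixel_size=(0.1, 0.1),
        image_size=(250, 250),
    )


class TestModelInvariants:
    def test_beam_rejects_non_unit_direction(self):
        with pytest.raises(GeometryError):
            Beam(s0_direction=[0, 0, 2.0], wavelength=1.0)

    def test_beam_rejects_non_orthogonal_polarization(self):
        with pytest.raises(GeometryError):
            Beam(s0_direction=[0, 0, 1.0], wavelength=1.0,
                 polarization_normal=[0, 0.6, 0.8])

    def test_panel_rejects_skew_axes(self):
        with pytest.raises(GeometryError):
            Panel(origin=[0, 0, 100], fast_axis=[1, 0, 0],
                  slow_axis=[0.1, 0.995, 0], pixel_size=(0.1, 0.1),
                  image_size=(10, 10))

    def test_crystal_ub_roundtrip(self):
        cell = (23.0, 31.0, 47.0, 88.0, 95.0, 103.0)
        c = Crystal(cell=cell)
        c2 = Crystal.from_ub(c.ub)
        assert np.allclose(c2.cell, cell, rtol=1e-8)
        assert np.allclose(c2.ub, c.ub, atol=1e-10)

    def test_crystal_rejects_improper_u(self):
        with pytest.raises(GeometryError):
            Crystal(cell=(10, 10, 10, 90, 90, 90), u=-np.eye(3))

    def test_experiment_json_roundtrip(self, tmp_path):
        exp = default_experiment()
        path = tmp_path / "exp.json"
        exp.to_json(path)
        exp2 = Experiment.from_json(path)
        assert np.allclose(exp2.crystal.ub, exp.crystal.ub, atol=1e-12)
        assert np.allclose(exp2.detector[0].origin, exp.detector[0].origin)
        assert exp2.scan.image_range == exp.scan.image_range


class TestPixelToRay:
    def test_on_axis_pixel_gives_beam_direction(self, beam, panel):
        ray, s1 = pixel_to_ray(panel, (100, 100), beam)
        lab = panel.pixel_to_lab(np.asarray(100.5), np.asarray(100.5))
        assert np.allclose(lab[:2], 0.0, atol=1e-12)
        assert np.allclose(ray, [0, 0, 1], atol=1e-12)
        assert two_theta(beam, s1=s1) == pytest.approx(0.0, abs=1e-10)

    def test_s1_normalization_exact(self, beam, panel):
        for px in [(0, 0), (37, 158), (199, 199)]:
            _, s1 = pixel_to_ray(panel, px, beam)
            assert np.linalg.norm(s1) * beam.wavelength == pytest.approx(1.0, abs=1e-12)

    def test_off_axis_two_theta_closed_form(self, beam, panel):
        # 10 mm off axis at 100 mm distance: 2theta = atan(0.1) = 5.7106 deg
        ray, s1 = pixel_to_ray(panel, (200, 100), beam)
        assert two_theta(beam, s1=s1) == pytest.approx(
            np.degrees(np.arctan(10.0 / 100.0)), abs=1e-6
        )

    def test_outside_panel_raises(self, beam, panel):
        with pytest.raises(GeometryError):
            pixel_to_ray(panel, (250, 10), beam)


class TestMapToRlp:
    def test_direct_beam_maps_to_origin(self):
        exp = default_experiment()
        panel = exp.detector[0]
        # pixel centre on the beam axis: lab x = y = 0
        x = -panel.origin[0] / panel.pixel_size[0]
        y = -panel.origin[1] / panel.pixel_size[1]
        r = map_to_rlp(np.array([x, y, 17.0]), exp)
        assert np.allclose(r, 0.0, atol=1e-12)

    def test_ewald_sphere_identity(self):
        exp = default_experiment()
        rng = np.random.default_rng(0)
        cents = np.column_stack(
            [rng.uniform(0, 450, 50), rng.uniform(0, 450, 50), rng.uniform(0, 90, 50)]
        )
        r = map_to_rlp(cents, exp)
        tt = np.radians(
            two_theta(exp.beam, s1=exp.detector[0].pixel_to_lab(cents[:, 0], cents[:, 1]))
        )
        expected = 2.0 * np.sin(tt / 2.0) / exp.beam.wavelength
        assert np.allclose(np.linalg.norm(r, axis=1), expected, atol=1e-10)

    def test_roundtrip_through_prediction(self):
        exp = default_experiment()
        pred = predict_reflections(exp, 4.0)
        rlp = map_to_rlp(pred[["x", "y", "phi"]].to_numpy(float), exp)
        r0 = pred[["h", "k", "l"]].to_numpy(float) @ exp.crystal.ub.T
        assert np.abs(rlp - r0).max() < 1e-6


class TestTwoTheta:
    def test_reference_values(self, beam):
        assert two_theta(beam, r=np.zeros(3)) == pytest.approx(0.0)
        assert two_theta(beam, r=np.array([2.0, 0, 0])) == pytest.approx(180.0)
        assert two_theta(beam, r=np.array([0, 1.0, 0])) == pytest.approx(60.0)

    def test_beyond_backscattering_raises(self, beam):
        with pytest.raises(GeometryError):
            two_theta(beam, r=np.array([2.1, 0, 0]))


class TestPrediction:
    def test_blind_region_excluded(self):
        # crystal aligned with the rotation axis: (h, 0, 0) rlps are parallel
        # to the axis and can never cross the Ewald sphere
        exp = default_experiment(misset_deg=0.0)
        pred = predict_reflections(exp, 3.5)
        axis_rows = pred[(pred.k == 0) & (pred.l == 0)]
        assert len(axis_rows) == 0

    def test_outside_ewald_reach_excluded(self):
        exp = default_experiment()
        pred = predict_reflections(exp, 0.49)  # includes |r| > 2/lambda shells
        d = pred["d"].to_numpy(float)
        assert (d >= 0.5).all()

    def test_on_sphere_and_at_most_two_per_turn(self):
        exp = default_experiment()
        pred = predict_reflections(exp, 3.5)
        r0 = pred[["h", "k", "l"]].to_numpy(float) @ exp.crystal.ub.T
        m = exp.goniometer.rotation_axis
        R = rotation_about_axis(m, np.radians(pred["phi"].to_numpy(float)))
        s = np.einsum("nij,nj->ni", R, r0) + exp.beam.s0
        mag = np.linalg.norm(s, axis=1) * exp.beam.wavelength
        assert np.abs(mag - 1.0).max() < 1e-10
        counts = pred.groupby(["h", "k", "l"]).size()
        assert counts.max() <= 2  # 90 deg scan: at most the two crossings

    def test_phi_solutions_match_brute_force_scan(self):
        # 10 A cubic cell, lambda = 1, 90 deg scan: closed-form crossings vs
        # sign changes of |R(phi) r + s0| - 1/lambda on a 0.001 deg grid
        exp = default_experiment(cell=(10, 10, 10, 90, 90, 90), distance=40.0)
        pred = predict_reflections(exp, 2.0)
        sub = pred.iloc[:: max(len(pred) // 40, 1)]
        phis = np.radians(np.arange(0.0, 90.0, 0.001))
        m = exp.goniometer.rotation_axis
        s0 = exp.beam.s0
        for row in sub.itertuples(index=False):
            r0 = np.array([row.h, row.k, row.l], float) @ exp.crystal.ub.T
            Rall = rotation_about_axis(m, phis)
            f = np.linalg.norm(np.einsum("nij,j->ni", Rall, r0) + s0, axis=1) - 1.0
            sign_changes = np.nonzero(np.diff(np.sign(f)) != 0)[0]
            brute = np.degrees(phis[sign_changes])
            assert np.min(np.abs(brute - row.phi)) < 0.002

    def test_requires_crystal(self):
        exp = default_experiment()
        exp = Experiment(exp.beam, exp.detector, exp.goniometer, exp.scan, None)
        with pytest.raises(GeometryError):
            predict_reflections(exp, 3.0)
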