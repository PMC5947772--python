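"""Profile model estimation, background, summation, Kabsch transform and
profile fitting."""

import copy

import numpy as np
import pandas as pd
import pytest

from sweepint.geometry import predict_reflections
from sweepint.integrate import (
    MASK_BACKGROUND,
    MASK_FOREGROUND,
    MASK_VALID,
    ProfileModel,
    ReferenceLocator,
    Shoebox,
    block_schedule,
    build_reference_profiles,
    estimate_background,
    estimate_profile_params,
    extract_shoeboxes,
    fit_profile,
    integrate_summation,
    kabsch_transform,
    polygon_area,
    polygon_clip,
)
from sweepint.simulate import default_experiment, simulate_rotation_series


def bg_shoebox(values):
    values = np.asarray(values, float).reshape(1, 1, -1)
    mask = np.full(values.shape, MASK_VALID | MASK_BACKGROUND, np.uint8)
    return Shoebox(bbox=(0, values.shape[2], 0, 1, 0, 1), data=values, mask=mask)


# ---- profile parameters -----------------------------------------------------


@pytest.fixture(scope="module")
def fine_sliced():
    """Two fine-sliced simulations differing only in sigma_d."""
    out = {}
    exp = default_experiment(n_images=200, oscillation=0.05)
    from sweepint.spotfind import find_spots

    for sd in (0.05, 0.10):
        profile = ProfileModel(sigma_d=sd, sigma_m=0.10)
        images, truth, _ = simulate_rotation_series(
            exp, profile, intensity_law=("constant", 2e5), background=0.5,
            seed=11, n_spots=60,
        )
        table, groups = find_spots(images, exp)
        table["indexed"] = True
        out[sd] = estimate_profile_params(table, groups, exp, images=images)
    return out


class TestProfileParams:
    def test_sigma_m_recovered(self, fine_sliced):
        for est in fine_sliced.values():
            assert 0.08 <= est.sigma_m <= 0.12

    def test_sigma_d_scales_with_truth(self, fine_sliced):
        ratio = fine_sliced[0.10].sigma_d / fine_sliced[0.05].sigma_d
        assert 1.8 <= ratio <= 2.2

    def test_single_pixel_spots_bounded_by_quantization(self):
        """Delta-function spots: the estimate cannot exceed the one-pixel /
        one-frame quantization width."""
        exp = default_experiment()
        panel = exp.detector[0]
        rng = np.random.default_rng(0)
        rows, groups = [], []
        for _ in range(25):
            x, y, z = rng.integers(50, 400), rng.integers(50, 400), rng.integers(5, 85)
            rows.append({"x": x + 0.5, "y": y + 0.5, "z": z + 0.5,
                         "phi": exp.scan.frame_to_phi(np.asarray(z + 0.5)),
                         "indexed": True})
            groups.append(np.array([[z, y, x, 1000.0]]))
        est = estimate_profile_params(pd.DataFrame(rows), groups, exp, min_spots=20)
        px_subtense = np.degrees(panel.pixel_size[0] / 120.0)
        assert est.sigma_d <= px_subtense
        assert est.sigma_m <= exp.scan.oscillation

    def test_too_few_spots_raise(self):
        exp = default_experiment()
        with pytest.raises(Exception, match="[Ss]pot"):
            estimate_profile_params(pd.DataFrame({"x": [1.0]}), [np.zeros((1, 4))],
                                    exp)


# ---- shoeboxes --------------------------------------------------------------


@pytest.fixture(scope="module")
def shoebox_setup():
    exp = default_experiment()
    profile = ProfileModel(sigma_d=0.05, sigma_m=0.1)
    images, truth, _ = simulate_rotation_series(
        exp, profile, intensity_law=("constant", 20000.0), background=1.0,
        seed=21, n_spots=60,
    )
    pred = predict_reflections(exp, 3.5)
    merged = pred.merge(truth[["h", "k", "l", "z"]], on=["h", "k", "l"],
                        suffixes=("", "_t"))
    merged = merged[np.abs(merged.z - merged.z_t) < 1].reset_index(drop=True)
    boxes, dropped = extract_shoeboxes(merged, images, exp, profile)
    return exp, profile, merged, boxes


class TestExtractShoeboxes:
    def test_predicted_centroid_inside_bbox(self, shoebox_setup):
        _, _, _, boxes = shoebox_setup
        for box in boxes:
            x0, x1, y0, y1, z0, z1 = box.bbox
            assert x0 <= box.xcal < x1 and y0 <= box.ycal < y1
            assert z0 <= box.zcal < z1

    def test_foreground_background_disjoint(self, shoebox_setup):
        _, _, _, boxes = shoebox_setup
        for box in boxes:
            assert not np.any((box.mask & MASK_FOREGROUND) & (box.mask & MASK_BACKGROUND))

    def test_bbox_extent_matches_projection_formula(self):
        # sigma_d = 0.05 deg, n_sigma 3, beam-normal detector at 200 mm with
        # 0.1 mm pixels: foreground side ~ 2 tan(0.15 deg) * 200 / 0.1 =
        # 10.5 px.  The foreground square lives in the (eps1, eps2) frame,
        # which is rotated relative to the raster, so test its (rotation-
        # invariant) area per frame instead of an axis-aligned width.
        exp = default_experiment(distance=200.0, pixel_size=(0.1, 0.1),
                                 image_size=(600, 600))
        profile = ProfileModel(sigma_d=0.05, sigma_m=0.1)
        pred = predict_reflections(exp, 3.5)
        pred = pred[(np.abs(pred.zeta) > 0.3) & (pred.z > 3) & (pred.z < 85)]
        row = pred.iloc[[0]]
        images = np.zeros((90, 600, 600), dtype=np.uint32)
        boxes, _ = extract_shoeboxes(row.reset_index(drop=True), images, exp, profile)
        box = boxes[0]
        fg = (box.mask & MASK_FOREGROUND) > 0
        central = int(np.argmax(fg.sum(axis=(1, 2))))
        area = fg[central].sum()
        assert abs(area - 10.5**2) <= 0.3 * 10.5**2

    def test_partial_flag_at_scan_edge(self):
        exp = default_experiment()
        profile = ProfileModel(sigma_d=0.05, sigma_m=0.1)
        pred = predict_reflections(exp, 3.5)
        pred = pred[np.abs(pred.zeta) > 0.3]
        edge = pred[(pred.z < 0.7) | (pred.z > 89.3)]
        assert len(edge) > 0
        images = np.zeros((90, 450, 450), dtype=np.uint32)
        boxes, _ = extract_shoeboxes(edge.reset_index(drop=True), images, exp, profile)
        assert any(b.partial for b in boxes)

    def test_shared_foreground_masked_out_of_both(self):
        exp = default_experiment()
        profile = ProfileModel(sigma_d=0.05, sigma_m=0.1)
        pred = predict_reflections(exp, 3.5)
        pred = pred[(np.abs(pred.zeta) > 0.3) & (pred.z > 5) & (pred.z < 80)]
        row = pred.iloc[[10]].reset_index(drop=True)
        dup = pd.concat([row, row], ignore_index=True)  # same position twice
        images = np.ones((90, 450, 450), dtype=np.uint32)
        boxes, _ = extract_shoeboxes(dup, images, exp, profile)
        for box in boxes:
            assert box.counts(MASK_FOREGROUND) == 0  # fully overlapped


# ---- background -------------------------------------------------------------


class TestBackground:
    @pytest.mark.parametrize("method", ["glm", "mean", "plane"])
    def test_constant_background_exact(self, method):
        levels, var, info = estimate_background(bg_shoebox(np.full(100, 5.0)), method)
        assert np.allclose(levels, 5.0, atol=1e-9)

    def test_glm_unbiased_below_one_count(self):
        """Poisson(0.5) over 2000 pixels, 200 seeds: |bias| < 0.02."""
        est = []
        for s in range(200):
            rng = np.random.default_rng(s)
            levels, _, _ = estimate_background(
                bg_shoebox(rng.poisson(0.5, 2000)), "glm")
            est.append(levels.flat[0])
        assert abs(np.mean(est) - 0.5) < 0.02

    def test_glm_robust_to_zingers_where_mean_fails(self):
        rng = np.random.default_rng(77)
        c = rng.poisson(0.5, 2000).astype(float)
        c[rng.choice(2000, 40, replace=False)] = 1e4
        glm_level = estimate_background(bg_shoebox(c), "glm")[0].flat[0]
        assert abs(glm_level - 0.5) / 0.5 < 0.05
        assert c.mean() / 0.5 > 10.0  # plain mean is off by > an order of magnitude

    def test_plane_recovers_inclined_background(self):
        ny, nx = 12, 12
        gx, gy = np.meshgrid(np.arange(nx, dtype=float), np.arange(ny, dtype=float))
        plane = 5.0 + 0.3 * gx - 0.2 * gy
        data = plane[None, :, :]
        mask = np.full(data.shape, MASK_VALID | MASK_BACKGROUND, np.uint8)
        box = Shoebox(bbox=(0, nx, 0, ny, 0, 1), data=data, mask=mask)
        levels, var, _ = estimate_background(box, "plane")
        assert np.allclose(levels[0], plane, atol=1e-8)

    def test_too_few_background_pixels_raise(self):
        with pytest.raises(Exception, match="background"):
            estimate_background(bg_shoebox(np.ones(4)), "glm")


# ---- summation --------------------------------------------------------------


class TestSummation:
    def make_box(self, fg_counts, bg_level, n_bg=50):
        m = len(fg_counts)
        data = np.concatenate([np.asarray(fg_counts, float),
                               np.full(n_bg, bg_level)]).reshape(1, 1, -1)
        mask = np.full(data.shape, MASK_VALID, np.uint8)
        mask[0, 0, :m] |= MASK_FOREGROUND
        mask[0, 0, m:] |= MASK_BACKGROUND
        return Shoebox(bbox=(0, data.shape[2], 0, 1, 0, 1), data=data, mask=mask)

    def test_pure_signal(self):
        box = self.make_box([100.0], 0.0)
        out = integrate_summation(box, np.zeros(box.data.shape))
        assert out["intensity"] == 100.0
        assert out["variance"] == 100.0

    def test_background_equals_model_gives_zero(self):
        box = self.make_box([3.0, 3.0], 3.0)
        out = integrate_summation(box, np.full(box.data.shape, 3.0))
        assert out["intensity"] == 0.0

    def test_linearity(self):
        box1 = self.make_box([10.0, 20.0, 30.0], 2.0)
        out1 = integrate_summation(box1, np.full(box1.data.shape, 2.0))
        box2 = self.make_box([20.0, 40.0, 60.0], 4.0)
        out2 = integrate_summation(box2, np.full(box2.data.shape, 4.0))
        assert out2["intensity"] == pytest.approx(2.0 * out1["intensity"], abs=1e-12)

    def test_variance_follows_leslie_error_model(self):
        fg = [5.0, 7.0, 6.0]
        box = self.make_box(fg, 2.0, n_bg=40)
        out = integrate_summation(box, np.full(box.data.shape, 2.0))
        m, n, b = 3, 40, 2.0
        assert out["variance"] == pytest.approx(sum(fg) + m * m / n * b)

    def test_no_foreground_flagged(self):
        box = bg_shoebox(np.ones(30))
        out = integrate_summation(box, np.ones(box.data.shape))
        assert out["flag"] == "no_foreground" and np.isnan(out["intensity"])

    def test_partials_sum_to_total(self):
        data = np.ones((4, 3, 3))
        mask = np.full(data.shape, MASK_VALID | MASK_FOREGROUND, np.uint8)
        mask[:, 0, :] = MASK_VALID | MASK_BACKGROUND
        box = Shoebox(bbox=(0, 3, 0, 3, 2, 6), data=data, mask=mask)
        out = integrate_summation(box, np.zeros(data.shape))
        assert sum(out["partials"].values()) == pytest.approx(out["intensity"])
        assert set(out["partials"]) == {2, 3, 4, 5}


# ---- polygon clipping -------------------------------------------------------


class TestPolygonClip:
    unit = np.array([(0, 0), (1, 0), (1, 1), (0, 1)], float)

    def test_self_clip(self):
        assert polygon_area(polygon_clip(self.unit, self.unit)) == pytest.approx(1.0)

    def test_half_overlap(self):
        shifted = self.unit + [0.5, 0.0]
        assert polygon_area(polygon_clip(self.unit, shifted)) == pytest.approx(0.5)

    def test_disjoint_is_empty(self):
        far = self.unit + [5.0, 5.0]
        assert polygon_area(polygon_clip(self.unit, far)) == 0.0

    def test_degenerate_clip_area_zero(self):
        line = np.array([(0, 0), (1, 0), (2, 0)], float)
        assert polygon_area(polygon_clip(self.unit, line)) == 0.0

    def test_random_quads_match_shapely(self):
        shapely = pytest.importorskip("shapely")
        from shapely.geometry import Polygon

        from scipy.spatial import ConvexHull

        rng = np.random.default_rng(17)
        n_done = 0
        while n_done < 200:
            def convex_poly():
                pts = rng.uniform(-1, 1, (5, 2))
                hull = ConvexHull(pts)
                return pts[hull.vertices]

            a, b = convex_poly(), convex_poly()
            expected = Polygon(a).intersection(Polygon(b)).area
            got = polygon_area(polygon_clip(a, b))
            assert got == pytest.approx(expected, abs=1e-9)
            n_done += 1


# ---- Kabsch transform -------------------------------------------------------


@pytest.fixture(scope="module")
def spot_box():
    exp = default_experiment()
    profile = ProfileModel(sigma_d=0.05, sigma_m=0.1)
    images, truth, _ = simulate_rotation_series(
        exp, profile, intensity_law=("constant", 50000.0), background=0.0,
        seed=31, n_spots=30,
    )
    pred = predict_reflections(exp, 3.5)
    merged = pred.merge(truth[["h", "k", "l", "z"]], on=["h", "k", "l"],
                        suffixes=("", "_t"))
    merged = merged[np.abs(merged.z - merged.z_t) < 1].reset_index(drop=True)
    boxes, _ = extract_shoeboxes(merged, images, exp, profile)
    return exp, profile, boxes


class TestKabschTransform:
    def test_count_conservation(self, spot_box):
        exp, profile, boxes = spot_box
        for box in boxes:
            fg_sum = box.data[(box.mask & MASK_FOREGROUND) > 0].sum()
            grid = kabsch_transform(box, exp, profile, np.zeros(box.data.shape))
            total = grid.values.sum() + grid.clipped
            assert total == pytest.approx(fg_sum, rel=1e-9)

    def test_profile_centred_on_grid(self, spot_box):
        exp, profile, boxes = spot_box
        offs = []
        for box in boxes:
            grid = kabsch_transform(box, exp, profile, np.zeros(box.data.shape))
            g = grid.values
            if g.sum() <= 0:
                continue
            idx = np.arange(9)
            com = np.array([
                g.sum(axis=(1, 2)) @ idx, g.sum(axis=(0, 2)) @ idx,
                g.sum(axis=(0, 1)) @ idx,
            ]) / g.sum()
            offs.append(np.abs(com - 4.0))
        assert np.mean(offs) < 0.2

    def test_pixel_inside_single_cell(self):
        # a very wide profile makes grid cells much larger than one pixel, so
        # a single bright pixel lands in exactly one (eps1, eps2) cell
        exp = default_experiment()
        profile = ProfileModel(sigma_d=0.5, sigma_m=0.5)
        pred = predict_reflections(exp, 3.5)
        pred = pred[(np.abs(pred.zeta) > 0.3) & (pred.z > 10) & (pred.z < 80)]
        row = pred.iloc[[0]].reset_index(drop=True)
        images = np.zeros((90, 450, 450), dtype=np.uint32)
        images[int(row.z[0]), int(row.y[0]), int(row.x[0])] = 7
        boxes, _ = extract_shoeboxes(row, images, exp, profile)
        grid = kabsch_transform(boxes[0], exp, profile, np.zeros(boxes[0].data.shape))
        plane = grid.values.sum(axis=0)
        assert (plane > 0).sum() == 1
        assert grid.values.sum() + grid.clipped == pytest.approx(7.0, rel=1e-9)


# ---- reference profiles and fitting -----------------------------------------

class TestReferences:
    def test_halfway_spot_contributes_equal_half_weight(self):
        loc = ReferenceLocator((450, 450), 3)
        x = 0.5 * (loc.positions[0, 0] + loc.positions[1, 0])
        y = loc.positions[0, 1]
        w = loc.weights(x, y)
        on_site = loc.weights(*loc.positions[0])[0]
        assert w[0] / on_site == pytest.approx(0.5, abs=1e-12)
        assert w[1] / on_site == pytest.approx(0.5, abs=1e-12)

    def test_reference_profiles_normalized(self):
        rng = np.random.default_rng(3)
        profiles = [rng.uniform(0, 1, (9, 9, 9)) for _ in range(12)]
        positions = rng.uniform(0, 450, (12, 2))
        loc = ReferenceLocator((450, 450), 3)
        refs, usable = build_reference_profiles(profiles, positions, loc)
        for i in np.nonzero(usable)[0]:
            assert refs[i].sum() == pytest.approx(1.0, abs=1e-12)

    def test_identical_spots_give_identical_references(self):
        prof = np.zeros((9, 9, 9))
        prof[4, 4, 4] = 2.0
        prof[4, 4, 5] = 1.0
        positions = np.array([[100.0, 100.0], [300.0, 220.0], [50.0, 400.0]])
        loc = ReferenceLocator((450, 450), 3)
        refs, usable = build_reference_profiles([prof] * 3, positions, loc)
        expected = prof / prof.sum()
        for i in np.nonzero(usable)[0]:
            assert np.allclose(refs[i], expected, atol=1e-12)


class TestFitProfile:
    def make_ref(self):
        g = np.zeros((9, 9, 9))
        x = np.arange(9) - 4.0
        gx = np.exp(-x**2 / 4.0)
        g = gx[:, None, None] * gx[None, :, None] * gx[None, None, :]
        return g / g.sum()

    def test_exact_model_recovered(self):
        ref = self.make_ref()
        fit = fit_profile(1000.0 * ref, np.zeros_like(ref), ref)
        assert fit["intensity"] == pytest.approx(1000.0, rel=1e-6)
        assert fit["correlation"] == pytest.approx(1.0, abs=1e-12)

    def test_background_only_fits_to_zero(self):
        ref = self.make_ref()
        bg = np.full_like(ref, 2.0)
        fit = fit_profile(bg.copy(), bg, ref)
        assert abs(fit["intensity"]) < 1e-6

    def test_constant_variance_limit_closed_form(self):
        # dominant flat background makes all v_j equal, so the iteration
        # reduces to the plain least-squares ratio sum(p (d-b)) / sum(p^2)
        ref = self.make_ref()
        rng = np.random.default_rng(5)
        signal = 40.0 * ref + rng.normal(0, 0.01, ref.shape)
        b = np.full_like(ref, 1e6)
        fit = fit_profile(signal + b, b, ref)
        closed = float((ref * signal).sum() / (ref**2).sum())
        assert fit["intensity"] == pytest.approx(closed, rel=1e-4)

    def test_null_reference_flagged(self):
        ref = np.zeros((9, 9, 9))
        out = fit_profile(np.ones_like(ref), np.zeros_like(ref), ref)
        assert out["flag"] == "null_reference"


# ---- blocks -----------------------------------------------------------------


class TestBlockSchedule:
    def test_half_overlap_starts(self):
        from sweepint.geometry import Scan

        scan = Scan(image_range=(0, 99), phi_start=0.0, oscillation=1.0)
        blocks = block_schedule(scan, 20)
        assert [b[0] for b in blocks] == [0, 10, 20, 30, 40, 50, 60, 70, 80]

    def test_oversized_block_collapses_to_one(self):
        from sweepint.geometry import Scan

        scan = Scan(image_range=(0, 49), phi_start=0.0, oscillation=1.0)
        assert block_schedule(scan, 100) == [(0, 50)]

    def test_full_coverage(self):
        from sweepint.geometry import Scan

        scan = Scan(image_range=(3, 89), phi_start=0.0, oscillation=0.5)
        blocks = block_schedule(scan, 16)
        covered = np.zeros(87, bool)
        for a, b in blocks:
            covered[a - 3 : b - 3] = True
        assert covered.all()
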