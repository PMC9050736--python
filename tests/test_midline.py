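"""Midline extraction, width profiling, somite calling, first-somite geometry."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import integrate
from skimage import draw

from somitometry import midline as ml
from somitometry import segmentation as seg
from somitometry import synthgen
from somitometry.grids import LabeledMask, MidlineCurve


def rect_mask(length=400, width=100, pad=20):
    m = np.zeros((width + 2 * pad, length + 2 * pad), dtype=bool)
    m[pad:pad + width, pad:pad + length] = True
    return LabeledMask(m, (1.0, 1.0))


def straight_curve(x0, x1, y, step=1.0):
    s = np.arange(0.0, x1 - x0 + step / 2, step)
    pts = np.stack([x0 + s, np.full_like(s, y)], axis=1)
    return MidlineCurve(pts, s, smoothing=0.0, step=step)


class TestRidgePoints:
    def test_rectangle_matches_per_column_argmax_oracle(self):
        mask = rect_mask(length=300, width=80, pad=10)
        pts = ml.midline_ridge_points(mask)
        # oracle: exact EDT argmax per column
        from scipy import ndimage
        edt = ndimage.distance_transform_edt(mask.mask)
        interior_cols = range(60, 260)
        oracle_y = {c: np.argmax(edt[:, c]) for c in interior_cols}
        ys = {}
        for x, y in pts:
            ys.setdefault(int(round(x)), []).append(y)
        for c in interior_cols:
            assert c in ys, f"no ridge point in column {c}"
            assert min(abs(y - oracle_y[c]) for y in ys[c]) <= 1.5

    def test_disc_concentrates_at_center(self):
        m = np.zeros((101, 101), dtype=bool)
        rr, cc = draw.disk((50, 50), 40)
        m[rr, cc] = True
        pts = ml.midline_ridge_points(LabeledMask(m, (1.0, 1.0)))
        d = np.linalg.norm(pts - [50, 50], axis=1)
        assert d.max() <= 3.0

    def test_bent_tube_points_near_true_centerline(self, sinusoidal_somitoid):
        img, truth = sinusoidal_somitoid
        mask = seg.segment(img, method="yen")
        pts = ml.midline_ridge_points(mask)
        from scipy.spatial import cKDTree
        d, _ = cKDTree(truth.centerline_points).query(pts)
        assert (d <= 3.0).mean() >= 0.9

    def test_empty_mask_raises(self):
        with pytest.raises(ValueError, match="empty"):
            ml.midline_ridge_points(
                LabeledMask(np.zeros((10, 10), dtype=bool), (1, 1)))

    def test_one_pixel_wide_mask_degenerate(self):
        m = np.zeros((20, 50), dtype=bool)
        m[10, 5:45] = True
        with pytest.warns(UserWarning, match="no interior"):
            pts = ml.midline_ridge_points(LabeledMask(m, (1, 1)))
        assert len(pts) == 1


class TestOrdering:
    def test_straight_line_sorted_and_reversible(self):
        rng = np.random.default_rng(0)
        x = rng.permutation(np.arange(0.0, 100.0, 2.0))
        pts = np.stack([x, np.zeros_like(x)], axis=1)
        fwd = ml.order_midline_points(pts, (0, 0), (100, 0),
                                      include_anchors=False)
        assert np.all(np.diff(fwd[:, 0]) > 0)
        rev = ml.order_midline_points(pts, (100, 0), (0, 0),
                                      include_anchors=False)
        np.testing.assert_allclose(rev, fwd[::-1])

    def test_u_shape_matches_brute_force_shortest_path(self):
        # 10 points on a U; oracle = exact shortest Hamiltonian path with
        # fixed endpoints, by enumeration of the 8 interior points
        theta = np.linspace(np.pi, 2 * np.pi, 10)
        pts = np.stack([50 * np.cos(theta), 50 * np.sin(theta)], axis=1)
        shuffled = pts[np.random.default_rng(1).permutation(10)]
        got = ml.order_midline_points(shuffled, pts[0], pts[-1],
                                      include_anchors=False,
                                      anchor_capture=10.0)

        start = np.argmin(np.linalg.norm(shuffled - pts[0], axis=1))
        end = np.argmin(np.linalg.norm(shuffled - pts[-1], axis=1))
        interior = [i for i in range(10) if i not in (start, end)]
        best, best_len = None, np.inf
        for perm in itertools.permutations(interior):
            order = [start, *perm, end]
            length = sum(np.linalg.norm(shuffled[a] - shuffled[b])
                         for a, b in zip(order, order[1:]))
            if length < best_len:
                best, best_len = order, length
        np.testing.assert_allclose(got, shuffled[list(best)])

    def test_far_anchor_raises(self):
        pts = np.stack([np.arange(10.0), np.zeros(10)], axis=1)
        with pytest.raises(ValueError, match="capture"):
            ml.order_midline_points(pts, (0, 500.0), (9, 0))


class TestSpline:
    def test_collinear_points_give_straight_segment(self):
        x = np.arange(0.0, 200.0, 5.0)
        pts = np.stack([x, np.zeros_like(x)], axis=1)
        curve = ml.fit_midline_spline(pts)
        assert curve.total_length == pytest.approx(195.0, rel=1e-3)
        assert np.abs(curve.points[:, 1]).max() < 0.1

    def test_noisy_line_smoothed_close_to_truth(self):
        rng = np.random.default_rng(2)
        x = np.arange(0.0, 500.0, 1.0)
        pts = np.stack([x, rng.normal(0.0, 2.0, x.size)], axis=1)
        curve = ml.fit_midline_spline(pts)
        assert np.abs(curve.points[:, 1]).max() < 2.0

    def test_sinusoid_arc_length_matches_quadrature(self):
        amp, lam = 30.0, 500.0
        x = np.arange(0.0, 1000.0, 1.0)
        pts = np.stack([x, amp * np.sin(2 * np.pi * x / lam)], axis=1)
        curve = ml.fit_midline_spline(pts)
        true_len, _ = integrate.quad(
            lambda t: np.hypot(1.0, amp * 2 * np.pi / lam
                               * np.cos(2 * np.pi * t / lam)), 0.0, 999.0)
        assert curve.total_length == pytest.approx(true_len, rel=0.02)

    def test_few_points_falls_back_to_polyline(self):
        pts = np.array([[0.0, 0.0], [50.0, 10.0], [100.0, 0.0]])
        with pytest.warns(UserWarning, match="polyline"):
            curve = ml.fit_midline_spline(pts)
        assert curve.total_length > 100.0


class TestWidthProfile:
    def test_rectangle_width_constant(self):
        mask = rect_mask(length=400, width=100, pad=20)
        curve = straight_curve(40.0, 440.0, 70.0)
        prof = ml.compute_width_profile(mask, curve)
        interior = (prof.s > 30) & (prof.s < 370)
        np.testing.assert_allclose(prof.w[interior], 100.0, atol=1.0)

    def test_disc_width_at_center_equals_diameter(self):
        m = np.zeros((201, 201), dtype=bool)
        rr, cc = draw.disk((100, 100), 55)
        m[rr, cc] = True
        mask = LabeledMask(m, (1.0, 1.0))
        curve = straight_curve(40.0, 160.0, 100.0)
        prof = ml.compute_width_profile(mask, curve)
        w_center = np.interp(60.0, prof.s, prof.w)
        assert w_center == pytest.approx(110.0, abs=2.0)

    def test_tangent_disc_chain_extrema_positions(self):
        # 5 tangent discs, d = 110: maxima ~110 at centres, minima ~0 at
        # tangency points (exact union-of-circles geometry as oracle)
        d = 110.0
        m = np.zeros((160, 700), dtype=bool)
        centers = 70 + d * np.arange(5)
        for cx in centers:
            rr, cc = draw.disk((80, cx), d / 2, shape=m.shape)
            m[rr, cc] = True
        mask = LabeledMask(m, (1.0, 1.0))
        curve = straight_curve(centers[0] - d / 2, centers[-1] + d / 2, 80.0)
        prof = ml.compute_width_profile(mask, curve)
        for k, cx in enumerate(centers):
            s_c = d / 2 + k * d
            assert np.interp(s_c, prof.s, prof.w) == pytest.approx(d, abs=2.0)
        for k in range(4):
            s_t = d * (k + 1)
            assert np.interp(s_t, prof.s, prof.w) <= 4.0

    @pytest.mark.parametrize("sd", range(5))
    def test_agrees_with_bruteforce_oracle(self, sd):
        spec = synthgen.SomitoidSpec(seed=sd, n_somites=3,
                                     body_length=200.0)
        img, truth = synthgen.generate_somitoid(spec)
        mask = seg.segment(img, method="yen")
        curve = ml.extract_midline(mask, truth.posterior_anchor,
                                   truth.anterior_anchor)
        fast = ml.compute_width_profile(mask, curve, step=2.0)
        slow = ml.width_profile_bruteforce(mask, curve, step=2.0)
        assert np.abs(fast.w - slow.w).max() <= 1.0  # within 1 px everywhere


class TestExtrema:
    def test_monotone_profile_has_no_interior_extrema(self):
        from somitometry.grids import WidthProfile
        s = np.arange(0.0, 300.0)
        prof = WidthProfile(s=s, w=50 + 0.3 * s, step=1.0)
        minima, maxima = ml.find_profile_extrema(prof)
        assert len(minima) == 0 and len(maxima) == 0

    def test_cosine_extrema_match_analytic_positions(self):
        # w = 100 + 20 cos(2*pi*s/120) on [0, 600]: analytic maxima at
        # multiples of 120, minima at odd multiples of 60; the end-discard
        # rule (40 µm) removes the extrema at s = 0 and s = 600
        from somitometry.grids import WidthProfile
        s = np.arange(0.0, 601.0)
        prof = WidthProfile(s=s, w=100 + 20 * np.cos(2 * np.pi * s / 120),
                            step=1.0)
        minima, maxima = ml.find_profile_extrema(prof, min_prominence=10,
                                                 min_separation=40)
        np.testing.assert_allclose(maxima, [120, 240, 360, 480], atol=1.5)
        np.testing.assert_allclose(minima, [60, 180, 300, 420, 540], atol=1.5)

    @pytest.mark.parametrize("sd", range(10))
    def test_noise_below_prominence_ignored(self, sd):
        from somitometry.grids import WidthProfile
        rng = np.random.default_rng(sd)
        s = np.arange(0.0, 601.0)
        w = 100 + 20 * np.cos(2 * np.pi * s / 120) + rng.uniform(-2, 2, s.size)
        prof = WidthProfile(s=s, w=w, step=1.0)
        minima, maxima = ml.find_profile_extrema(prof, min_prominence=10,
                                                 min_separation=40)
        assert len(maxima) == 4 and len(minima) == 5


class TestSomiteCalls:
    def test_single_bracketed_maximum_gives_one_call(self):
        from somitometry.grids import WidthProfile
        s = np.arange(0.0, 421.0)
        # interior minima at 60 and 360, single maximum at 210
        w = 60 - 40 * np.cos(2 * np.pi * (s - 60) / 300)
        prof = WidthProfile(s=s, w=w, step=1.0)
        extrema = ml.find_profile_extrema(prof, min_separation=40)
        calls = ml.call_somites(prof, extrema, end_cap=False)
        assert len(calls) == 1
        assert calls[0].index == 1

    def test_default_somitoid_recovery(self, default_somitoid, default_calls):
        _, truth = default_somitoid
        assert len(default_calls) == len(truth.somites) == 8
        w_err = [abs(c.width - t["width"])
                 for c, t in zip(default_calls, truth.somites)]
        l_err = [abs(c.length - t["length"])
                 for c, t in zip(default_calls, truth.somites)]
        assert np.mean(w_err) <= 5.0
        assert np.mean(l_err) <= 5.0

    def test_posterior_body_never_called(self, default_somitoid,
                                         default_calls):
        _, truth = default_somitoid
        body_len = truth.spec["body_length"]
        assert all(c.s_start >= body_len - 20 for c in default_calls)

    def test_anterior_end_cap_recovers_last_somite(self, default_calls):
        assert default_calls[-1].end_capped
        assert not any(c.end_capped for c in default_calls[:-1])

    def test_monotone_fixture_monotone_calls(self):
        spec = synthgen.SomitoidSpec(
            seed=11, somite_diameters=(80, 100, 120, 140, 160),
            noise_sigma=10.0)
        img, truth = synthgen.generate_somitoid(spec)
        mask = seg.segment(img, method="yen")
        curve = ml.extract_midline(mask, truth.posterior_anchor,
                                   truth.anterior_anchor)
        prof = ml.compute_width_profile(mask, curve)
        calls = ml.call_somites(prof, ml.find_profile_extrema(prof))
        widths = [c.width for c in calls]
        lengths = [c.length for c in calls]
        assert len(calls) == 5
        assert np.all(np.diff(widths) > 0)
        assert np.all(np.diff(lengths) > 0)

    def test_rigid_motion_leaves_scalars_unchanged(self, default_somitoid,
                                                   default_calls):
        img, truth = default_somitoid
        # exact rigid motion: rotate image 90 degrees, map the anchors along
        rot = np.rot90(img.data)
        h = img.data.shape[1]  # original n_cols = new n_rows
        from somitometry.grids import ImageGrid

        def map_pt(p):
            return np.array([p[1], (h - 1) - p[0]])

        mask = seg.segment(ImageGrid(rot, (1.0, 1.0)), method="yen")
        curve = ml.extract_midline(mask, map_pt(truth.posterior_anchor),
                                   map_pt(truth.anterior_anchor))
        prof = ml.compute_width_profile(mask, curve)
        calls = ml.call_somites(prof, ml.find_profile_extrema(prof))
        assert len(calls) == len(default_calls)
        for a, b in zip(calls, default_calls):
            assert a.width == pytest.approx(b.width, rel=0.01)
            assert a.length == pytest.approx(b.length, rel=0.01)


class TestShapeStats:
    def test_circle_is_exact(self):
        area, circ = ml.somite_shape_stats(100.0, 100.0)
        assert area == pytest.approx(np.pi * 100 ** 2 / 4, rel=1e-12)
        assert circ == pytest.approx(1.0, abs=1e-9)

    def test_printed_somite_dimensions(self):
        # paired-somite scale: 110 µm length, 104 µm width
        area, circ = ml.somite_shape_stats(110.0, 104.0)
        assert area == pytest.approx(np.pi * 110 * 104 / 4, rel=1e-12)
        assert area == pytest.approx(8985.0, abs=1.0)
        assert 0.99 < circ < 1.0

    def test_circularity_matches_quadrature_perimeter(self):
        L, W = 2.0, 1.0
        a, b = L / 2, W / 2
        _, circ = ml.somite_shape_stats(L, W)
        # oracle: numerically integrated ellipse perimeter
        per, _ = integrate.quad(
            lambda t: np.hypot(a * np.sin(t), b * np.cos(t)), 0, 2 * np.pi)
        expected = 4 * np.pi * (np.pi * a * b) / per ** 2
        assert circ == pytest.approx(expected, abs=5e-5)

    @given(L=st.floats(10.0, 300.0), W=st.floats(10.0, 300.0))
    @settings(max_examples=50, deadline=None)
    def test_symmetric_and_maximised_on_diagonal(self, L, W):
        _, c_lw = ml.somite_shape_stats(L, W)
        _, c_wl = ml.somite_shape_stats(W, L)
        _, c_diag = ml.somite_shape_stats(L, L)
        assert c_lw == pytest.approx(c_wl, rel=1e-9)
        assert c_lw <= c_diag + 1e-9

    def test_nonpositive_raises(self):
        with pytest.raises(ValueError):
            ml.somite_shape_stats(0.0, 10.0)


class TestCountRows:
    def test_empty_and_truth_counts(self, default_calls):
        assert ml.count_somite_rows([]) == 0
        assert ml.count_somite_rows(default_calls) == 8

    def test_three_somite_fixture(self):
        spec = synthgen.SomitoidSpec(seed=2, n_somites=3)
        img, truth = synthgen.generate_somitoid(spec)
        mask = seg.segment(img, method="yen")
        curve = ml.extract_midline(mask, truth.posterior_anchor,
                                   truth.anterior_anchor)
        prof = ml.compute_width_profile(mask, curve)
        calls = ml.call_somites(prof, ml.find_profile_extrema(prof))
        assert ml.count_somite_rows(calls) == 3

    def test_paired_rows_counted_once(self):
        # profile along the true centerline: one width maximum per pair
        spec = synthgen.SomitoidSpec(seed=6, paired=True, n_somites=6)
        img, truth = synthgen.generate_somitoid(spec)
        mask = seg.segment(img, method="yen")
        curve = ml.fit_midline_spline(truth.centerline_points[::10])
        prof = ml.compute_width_profile(mask, curve)
        calls = ml.call_somites(prof, ml.find_profile_extrema(prof))
        assert ml.count_somite_rows(calls) == 6
        for c, t in zip(calls, truth.somites):
            assert c.width == pytest.approx(t["width"], abs=5.0)


class TestFirstSomite:
    def test_orthogonal_crossing_at_20_percent(self):
        curve = straight_curve(0.0, 1000.0, 50.0)
        res = ml.first_somite_metrics(
            curve, np.array([[200.0, 0.0], [200.0, 100.0]]))
        assert res.relative_position == pytest.approx(0.20, abs=1e-6)
        assert res.angle == pytest.approx(0.0, abs=1e-6)
        assert res.exact_crossing

    def test_tilted_segment_angle(self):
        curve = straight_curve(0.0, 1000.0, 0.0)
        t = np.radians(30.0)
        d = np.array([np.sin(t), np.cos(t)]) * 80.0
        p = np.array([300.0, 0.0])
        res = ml.first_somite_metrics(curve, np.stack([p - d, p + d]))
        assert res.angle == pytest.approx(30.0, abs=1e-6)

    def test_sinusoidal_fixture_recovers_arc_fraction(self,
                                                      sinusoidal_somitoid):
        img, truth = sinusoidal_somitoid
        mask = seg.segment(img, method="yen")
        curve = ml.extract_midline(mask, truth.posterior_anchor,
                                   truth.anterior_anchor)
        lr = synthgen.lr_segment_at_fraction(truth, 0.35)
        res = ml.first_somite_metrics(curve, lr)
        assert res.relative_position == pytest.approx(0.35, abs=0.01)

    def test_no_crossing_reports_distance(self):
        curve = straight_curve(0.0, 100.0, 0.0)
        with pytest.raises(ValueError, match="closest approach"):
            ml.first_somite_metrics(
                curve, np.array([[50.0, 50.0], [50.0, 150.0]]))


class TestRegionMorphometrics:
    def test_square_area(self):
        m = np.zeros((140, 140), dtype=bool)
        m[20:120, 20:120] = True
        out = ml.region_morphometrics(LabeledMask(m, (1.0, 1.0)))
        assert out["area_um2"] == pytest.approx(10000.0)

    def test_disc_circularity(self):
        m = np.zeros((240, 240), dtype=bool)
        rr, cc = draw.disk((120, 120), 100)         # r = 50 µm at 0.5 µm/px
        m[rr, cc] = True
        out = ml.region_morphometrics(LabeledMask(m, (0.5, 0.5)))
        assert out["circularity"] >= 0.98

    def test_ellipse_axis_ratio(self):
        yy, xx = np.mgrid[0:200, 0:300]
        m = ((xx - 150) / 100.0) ** 2 + ((yy - 100) / 50.0) ** 2 <= 1.0
        out = ml.region_morphometrics(LabeledMask(m, (1.0, 1.0)))
        ratio = out["major_axis_um"] / out["minor_axis_um"]
        assert ratio == pytest.approx(2.0, abs=0.05)

    def test_empty_raises(self):
        with pytest.raises(ValueError, match="empty"):
            ml.region_morphometrics(
                LabeledMask(np.zeros((5, 5), dtype=bool), (1, 1)))
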