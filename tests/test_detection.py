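"""Unit and property tests for the per-frame detection pipeline."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pupilfit.detection import (
    DegenerateSegmentError,
    DetectorConfig,
    EllipseFit,
    HullBorder,
    Segment,
    angle_profile,
    detect_pupil,
    filter_segments,
    fit_sinusoidal_ellipse,
    hull_border,
    hull_perimeter,
    label_segments,
    parametric_angle,
    select_pupil,
    taylor_cos,
    taylor_sin,
    threshold_image,
)

from oracles import (
    coordinate_descent_fit,
    flood_fill_labels,
    halfplane_hull,
    point_in_convex_polygon,
)


# --- thresholding ------------------------------------------------------------


class TestThreshold:
    def test_uniform_bright_image_yields_empty_mask(self):
        img = np.full((20, 30), 200, dtype=np.uint8)
        assert not threshold_image(img, 30).any()

    def test_boundary_intensity_is_excluded(self):
        """The dark-pixel predicate is strict: intensity == cut stays out."""
        img = np.full((10, 10), 30, dtype=np.uint8)
        assert not threshold_image(img, 30).any()
        assert threshold_image(img, 31).all()

    def test_disc_mask_matches_direct_inequality(self, disc_image):
        img, disc = disc_image
        mask = threshold_image(img, 30)
        assert np.array_equal(mask, disc)
        assert mask.sum() == disc.sum()

    def test_threshold_zero_always_empty(self, rng):
        img = rng.integers(0, 256, size=(30, 40))
        assert not threshold_image(img, 0).any()

    def test_mask_is_monotone_in_threshold(self, rng):
        img = rng.integers(0, 256, size=(40, 60))
        prev = threshold_image(img, 0)
        for t in range(0, 256, 17):
            cur = threshold_image(img, t)
            assert (prev <= cur).all()  # set inclusion
            prev = cur

    def test_color_input_uses_luminance(self):
        rgb = np.zeros((5, 5, 3), dtype=np.uint8)
        rgb[..., 2] = 255  # pure blue: Rec.601 luminance ~29 < 30
        assert threshold_image(rgb, 30).all()
        assert not threshold_image(rgb, 29).any()


# --- labeling ----------------------------------------------------------------


class TestLabeling:
    def test_empty_mask_gives_no_segments(self):
        assert label_segments(np.zeros((10, 10), dtype=bool)) == []

    def test_two_separated_discs_give_two_segments(self, rng):
        mask = np.zeros((60, 120), dtype=bool)
        ys, xs = np.mgrid[0:60, 0:120]
        d1 = (xs - 25) ** 2 + (ys - 30) ** 2 <= 100
        d2 = (xs - 90) ** 2 + (ys - 30) ** 2 <= 64
        mask |= d1 | d2
        segs = label_segments(mask)
        assert sorted(s.size for s in segs) == sorted([d1.sum(), d2.sum()])

    def test_diagonal_touch_is_one_component(self):
        mask = np.zeros((4, 4), dtype=bool)
        mask[1, 1] = mask[2, 2] = True
        segs = label_segments(mask)
        assert len(segs) == 1 and segs[0].size == 2

    def test_partition_matches_flood_fill(self, rng):
        mask = rng.random((25, 35)) < 0.35
        segs = label_segments(mask)
        assert sum(s.size for s in segs) == int(mask.sum())
        ours = {frozenset(map(tuple, s.pixels)) for s in segs}
        theirs = {frozenset(c) for c in flood_fill_labels(mask)}
        assert ours == theirs

    def test_labels_are_unique_and_start_at_one(self, rng):
        mask = rng.random((20, 20)) < 0.2
        segs = label_segments(mask)
        labels = [s.label for s in segs]
        assert labels == list(range(1, len(segs) + 1))


# --- size filter -------------------------------------------------------------


class TestFilter:
    def test_strictly_bigger_than_survives(self):
        segs = [Segment(i + 1, np.zeros((n, 2), dtype=int))
                for i, n in enumerate([599, 600, 601])]
        kept = filter_segments(segs, 600)
        assert [s.size for s in kept] == [601]

    def test_empty_input(self):
        assert filter_segments([], 600) == []

    def test_matches_brute_force_scan(self, rng):
        sizes = rng.integers(1, 1200, size=200)
        segs = [Segment(i + 1, np.zeros((n, 2), dtype=int))
                for i, n in enumerate(sizes)]
        kept = filter_segments(segs, 600)
        expected = [s for s in segs if s.size > 600]
        assert [s.label for s in kept] == [s.label for s in expected]


# --- convex hull -------------------------------------------------------------


class TestHull:
    def test_triangle_kept_verbatim(self):
        pts = np.array([[0, 0], [4, 1], [1, 5]])
        hull = hull_border(Segment(1, pts))
        assert set(map(tuple, hull.vertices)) == set(map(tuple, pts))

    def test_filled_square_reduces_to_corners(self):
        ys, xs = np.mgrid[0:10, 0:10]
        pts = np.column_stack([xs.ravel(), ys.ravel()])
        hull = hull_border(Segment(1, pts))
        assert set(map(tuple, hull.vertices)) == {(0, 0), (9, 0), (9, 9), (0, 9)}

    def test_starts_at_lexicographically_smallest_vertex(self):
        pts = np.array([[5, 5], [9, 2], [3, 8], [1, 1], [7, 9]])
        hull = hull_border(Segment(1, pts))
        assert tuple(hull.vertices[0]) == (1, 1)

    def test_collinear_segment_is_degenerate(self):
        pts = np.array([[i, 2 * i] for i in range(10)])
        with pytest.raises(DegenerateSegmentError):
            hull_border(Segment(1, pts))

    @pytest.mark.parametrize("seed", range(5))
    def test_vertex_set_matches_halfplane_oracle(self, seed):
        rng = np.random.default_rng(seed)
        pts = rng.random((50, 2)) * 100
        hull = hull_border(Segment(1, pts))
        assert set(map(tuple, hull.vertices)) == halfplane_hull(pts)

    def test_invariant_to_input_ordering(self, rng):
        pts = rng.random((40, 2)) * 50
        h1 = hull_border(Segment(1, pts))
        h2 = hull_border(Segment(1, pts[rng.permutation(40)]))
        assert np.array_equal(h1.vertices, h2.vertices)

    def test_every_pixel_inside_hull(self, rng):
        pts = np.column_stack([rng.integers(0, 60, 300), rng.integers(0, 40, 300)])
        hull = hull_border(Segment(1, pts))
        for p in pts[rng.choice(300, 50, replace=False)]:
            assert point_in_convex_polygon(p, hull.vertices)


# --- angle profile -----------------------------------------------------------


class TestAngleProfile:
    def test_point_on_horizontal_has_angle_zero(self):
        verts = np.array([[10, 5], [0, 5], [5, 0], [5, 10]], dtype=float)
        prof = angle_profile(HullBorder(verts))
        assert prof.reference == (5.0, 5.0)
        assert prof.angles[0] == 0.0

    def test_point_above_reference_is_plus_half_pi(self):
        """y-up sign convention despite y-down image storage."""
        verts = np.array([[10, 5], [0, 5], [5, 0], [5, 10]], dtype=float)
        prof = angle_profile(HullBorder(verts))
        assert prof.angles[2] == pytest.approx(math.pi / 2)
        assert prof.angles[3] == pytest.approx(-math.pi / 2)

    def test_regular_hexagon_angles(self):
        expected = np.array([0, math.pi / 3, 2 * math.pi / 3, math.pi,
                             -2 * math.pi / 3, -math.pi / 3])
        verts = np.column_stack([5 + 3 * np.cos(expected), 5 - 3 * np.sin(expected)])
        prof = angle_profile(HullBorder(verts))
        np.testing.assert_allclose(prof.angles, expected, atol=1e-12)

    def test_angles_in_half_open_interval(self, rng):
        verts = rng.random((30, 2)) * 100
        prof = angle_profile(HullBorder(verts))
        assert np.all(prof.angles > -math.pi) and np.all(prof.angles <= math.pi)


# --- ellipse fit -------------------------------------------------------------


def truncated_model_points(h, k, a, b, w):
    """Points lying exactly on the truncated sinusoidal model."""
    return np.column_stack([h - b * taylor_sin(w), k + a * taylor_cos(w)])


class TestEllipseFit:
    def test_truncated_bases_at_zero(self):
        assert taylor_sin(0.0) == 0.0
        assert taylor_cos(0.0) == 1.0

    def test_parametric_angle_is_involution(self, rng):
        phi = rng.uniform(-math.pi, math.pi, 200)
        np.testing.assert_allclose(parametric_angle(parametric_angle(phi)), phi,
                                   atol=1e-12)

    def test_exact_recovery_from_truncated_model(self):
        w = np.linspace(-3.0, 3.0, 32)
        pts = truncated_model_points(320, 240, 50, 48, w)
        geo = parametric_angle(w)  # involution: geometric angles mapping back to w
        from pupilfit.detection import AngleProfile
        prof = AngleProfile(reference=(0.0, 0.0), angles=geo)
        fit = fit_sinusoidal_ellipse(pts, prof)
        assert fit.h == pytest.approx(320, abs=1e-6)
        assert fit.k == pytest.approx(240, abs=1e-6)
        assert fit.a == pytest.approx(50, abs=1e-6)
        assert fit.b == pytest.approx(48, abs=1e-6)
        assert fit.sse == pytest.approx(0, abs=1e-9)

    def test_fitted_curve_at_zero_passes_through_center_plus_a(self):
        """At w = 0 the model constrains x toward h and y toward k + a."""
        from pupilfit.detection import AngleProfile
        w = np.linspace(-2.5, 2.5, 40)
        pts = truncated_model_points(100, 80, 30, 28, w)
        prof = AngleProfile(reference=(0.0, 0.0), angles=parametric_angle(w))
        fit = fit_sinusoidal_ellipse(pts, prof)
        # noiseless: fitted x(0) = h, y(0) = k + a
        assert fit.h == pytest.approx(100, abs=1e-6)
        assert fit.k + fit.a == pytest.approx(80 + 30, abs=1e-6)

    @pytest.mark.parametrize("seed", range(20))
    def test_agrees_with_coordinate_descent_oracle(self, seed):
        rng = np.random.default_rng(seed)
        a, b = rng.uniform(20, 50, 2)
        h, k = rng.uniform(100, 300, 2)
        phi = np.sort(rng.uniform(-math.pi, math.pi, 60))
        pts = np.column_stack([h + b * np.cos(phi), k - a * np.sin(phi)])
        pts += rng.normal(0, 0.3, pts.shape)
        fit = fit_sinusoidal_ellipse(pts)
        oh, ok, oa, ob = coordinate_descent_fit(pts, parametric_angle(
            angle_profile(HullBorder(pts)).angles))
        assert fit.h == pytest.approx(oh, abs=0.1)
        assert fit.k == pytest.approx(ok, abs=0.1)
        assert fit.a == pytest.approx(oa, abs=0.1)
        assert fit.b == pytest.approx(ob, abs=0.1)

    def test_center_bias_on_dense_circle_is_bounded(self):
        """Truncation bias on a full circular border stays below 0.2 r."""
        for r in (20, 40, 60):
            phi = np.linspace(-math.pi, math.pi, 720, endpoint=False)
            pts = np.column_stack([300 + r * np.cos(phi), 240 - r * np.sin(phi)])
            fit = fit_sinusoidal_ellipse(pts)
            assert abs(fit.k - 240) <= 0.2 * r
            assert abs(fit.h - 300) <= 0.2 * r

    def test_too_few_distinct_angles_is_degenerate(self):
        pts = np.array([[0, 0], [10, 0], [0, 10], [10, 10]], dtype=float)
        from pupilfit.detection import AngleProfile
        prof = AngleProfile(reference=(5.0, 5.0),
                            angles=np.array([0.1, 0.1, 0.1, 0.1]))
        with pytest.raises(DegenerateSegmentError):
            fit_sinusoidal_ellipse(pts, prof)

    def test_negative_amplitude_flagged_invalid(self):
        fit = EllipseFit(h=10, k=10, a=-5, b=20, sse=0)
        assert not fit.valid


# --- selection ---------------------------------------------------------------


class TestSelection:
    def fit(self, a, b, size=700, label=1):
        return EllipseFit(h=0, k=0, a=a, b=b, sse=0,
                          source_label=label, source_size=size)

    def test_most_circular_wins(self):
        win = select_pupil([self.fit(21, 20), self.fit(30, 20)])
        assert win.circularity == pytest.approx(1.05)

    def test_empty_list_gives_none(self):
        assert select_pupil([]) is None

    def test_tie_broken_by_larger_segment(self):
        f1 = self.fit(24, 20, size=700, label=1)
        f2 = self.fit(24, 20, size=900, label=2)
        assert select_pupil([f1, f2]).source_size == 900

    def test_tie_broken_then_by_smaller_label(self):
        f1 = self.fit(24, 20, size=700, label=2)
        f2 = self.fit(24, 20, size=700, label=1)
        assert select_pupil([f1, f2]).source_label == 1

    def test_invalid_fits_never_selected(self):
        assert select_pupil([self.fit(-5, 20), self.fit(0, 20)]) is None


# --- full pipeline -----------------------------------------------------------


class TestDetectPupil:
    def test_blank_bright_frame_has_no_pupil(self):
        img = np.full((480, 640), 200, dtype=np.uint8)
        result = detect_pupil(img)
        assert result.status == "no_pupil" and result.pcp is None

    def test_clean_disc_recovered_within_quarter_radius(self, disc_image):
        img, _ = disc_image
        result = detect_pupil(img)
        assert result.detected
        err = math.hypot(result.pcp[0] - 300, result.pcp[1] - 200)
        assert err <= 0.25 * 40

    def test_matches_stagewise_oracle_composition(self):
        """Independent per-stage oracles, composed, give the same center."""
        img = np.full((150, 200), 200, dtype=np.uint8)
        ys, xs = np.mgrid[0:150, 0:200]
        disc = (xs - 90) ** 2 + (ys - 70) ** 2 <= 25**2
        img[disc] = 10
        result = detect_pupil(img, DetectorConfig(threshold=30, min_segment_size=600))

        # oracle pipeline: inequality mask -> BFS labels -> size filter ->
        # monotone-chain hull -> dense border -> coordinate-descent fit
        from oracles import monotone_chain_hull
        mask = np.asarray(img) < 30
        comps = [c for c in flood_fill_labels(mask) if len(c) > 600]
        assert len(comps) == 1
        hull_pts = monotone_chain_hull(np.array(sorted(comps[0])))
        dense = hull_perimeter(HullBorder(hull_pts))
        w = parametric_angle(angle_profile(HullBorder(dense)).angles)
        oh, ok, _, _ = coordinate_descent_fit(dense, w)
        assert result.pcp[0] == pytest.approx(oh, abs=0.05)
        assert result.pcp[1] == pytest.approx(ok, abs=0.05)

    def test_pupil_beats_elongated_eyelash_bar(self, disc_image):
        img, _ = disc_image
        img[20:45, 100:200] = 12  # aspect-4 bar, 2500 px > 600
        result = detect_pupil(img)
        assert result.detected and result.n_candidates == 2
        assert math.hypot(result.pcp[0] - 300, result.pcp[1] - 200) < 20
        assert result.ellipse.circularity < 1.3

    def test_deterministic_across_runs(self, disc_image):
        img, _ = disc_image
        r1, r2 = detect_pupil(img), detect_pupil(img)
        assert r1.pcp == r2.pcp and r1.ellipse == r2.ellipse


# --- scalar properties via hypothesis ---------------------------------------


@settings(derandomize=True, max_examples=50)
@given(st.floats(-math.pi, math.pi))
def test_truncated_bases_track_trig_near_zero(w):
    """Within |w| <= 2 the truncated bases stay close to sin/cos."""
    if abs(w) <= 2.0:
        assert abs(taylor_sin(w) - math.sin(w)) < 0.03
        assert abs(taylor_cos(w) - math.cos(w)) < 0.09
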