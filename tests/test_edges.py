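"""Contour extraction, trimming/filtering, Hough fitting, edge recovery."""

import numpy as np
import pytest

from wscas import (
    EdgeLine,
    SceneSpec,
    detect_uncut_edge,
    extract_boundary_pixels,
    filter_small_components,
    fit_edge_line,
    generate_scene,
    trim_and_filter_rightmost,
)
from wscas.errors import DegenerateContourError, EmptyMaskError, NoLineError


class TestEdgeLine:
    def test_rho_theta_bottom_x_consistency(self):
        line = EdgeLine.from_vertical_angle(bottom_x=120.0, angle_deg=10.0, height=200)
        assert line.bottom_x == pytest.approx(120.0, abs=1e-9)
        assert line.vertical_angle_deg == pytest.approx(10.0, abs=1e-9)
        # the bottom point satisfies x cos(t) + y sin(t) = rho
        assert line.distance_to(line.bottom_x, 199) == pytest.approx(0.0, abs=1e-9)

    def test_negative_angle_canonicalised(self):
        line = EdgeLine.from_vertical_angle(bottom_x=80.0, angle_deg=-15.0, height=100)
        assert 0 <= line.theta_deg < 180
        assert line.vertical_angle_deg == pytest.approx(-15.0, abs=1e-9)
        assert line.bottom_x == pytest.approx(80.0, abs=1e-9)


class TestBoundary:
    def test_full_frame_mask_boundary_is_border(self):
        mask = np.ones((30, 40), dtype=bool)
        pts = extract_boundary_pixels(mask)
        assert len(pts) == 2 * 30 + 2 * 40 - 4
        xs, ys = pts[:, 0], pts[:, 1]
        assert np.all((xs == 0) | (xs == 39) | (ys == 0) | (ys == 29))

    def test_rectangle_perimeter_count(self):
        mask = np.zeros((100, 100), dtype=bool)
        mask[10:60, 20:80] = True  # 50 x 60 rectangle
        pts = extract_boundary_pixels(mask)
        assert abs(len(pts) - (2 * 60 + 2 * 50 - 4)) <= 4

    def test_empty_mask_rejected(self):
        with pytest.raises(EmptyMaskError):
            extract_boundary_pixels(np.zeros((10, 10), dtype=bool))

    def test_agrees_with_canny_on_interior_blob(self):
        """On a binary mask the morphological contour and the Canny contour
        coincide up to one pixel (Hausdorff distance)."""
        from scipy.spatial import cKDTree
        from skimage.feature import canny

        mask = np.zeros((120, 120), dtype=bool)
        yy, xx = np.mgrid[:120, :120]
        mask[(yy - 60) ** 2 + (xx - 55) ** 2 < 35**2] = True
        ours = extract_boundary_pixels(mask)
        edges = canny(mask.astype(float) * 255, low_threshold=64, high_threshold=192)
        cy, cx = np.nonzero(edges)
        theirs = np.column_stack([cx, cy])
        d1 = cKDTree(theirs).query(ours)[0].max()
        d2 = cKDTree(ours).query(theirs)[0].max()
        assert max(d1, d2) <= 1.5  # diagonal neighbour


class TestTrimFilter:
    def rectangle_boundary(self, rows=100, x_right=200):
        pts = []
        for y in range(rows):
            pts.append((100, y))
            pts.append((x_right, y))
        for x in range(100, x_right + 1):
            pts.append((x, 0))
            pts.append((x, rows - 1))
        return np.unique(np.array(pts), axis=0)

    def test_ten_percent_trim_keeps_inner_rows(self):
        out = trim_and_filter_rightmost(self.rectangle_boundary(), 0.10)
        assert len(out) == 80
        assert np.all(out[:, 0] == 200)
        assert out[:, 1].min() == 10 and out[:, 1].max() == 89

    def test_zero_trim_keeps_one_pixel_per_row(self):
        out = trim_and_filter_rightmost(self.rectangle_boundary(), 0.0)
        assert len(out) == 100
        assert np.all(out[:, 0] == 200)

    def test_single_row_degenerate(self):
        with pytest.raises(DegenerateContourError):
            trim_and_filter_rightmost(np.array([[5, 7], [9, 7]]))

    def test_output_subset_of_input(self):
        b = self.rectangle_boundary()
        out = trim_and_filter_rightmost(b, 0.10)
        bset = {tuple(p) for p in b}
        assert all(tuple(p) in bset for p in out)


class TestHoughFit:
    def test_perfect_vertical_consensus(self):
        pts = np.array([(120, y) for y in range(50)])
        line = fit_edge_line(pts, height=50)
        assert line.bottom_x == pytest.approx(120, abs=1.0)
        assert abs(line.vertical_angle_deg) <= 1.0

    def test_diagonal_line_angle_recovered(self):
        pts = np.array([(v, v) for v in range(60)])  # y = x
        line = fit_edge_line(pts, height=60)
        # y = x has vertical-axis angle -45 deg in screen coordinates
        assert line.vertical_angle_deg == pytest.approx(-45.0, abs=1.0)

    def test_scattered_pixels_below_threshold(self):
        rng = np.random.default_rng(0)
        pts = np.column_stack([rng.integers(0, 200, 10), rng.integers(0, 200, 10)])
        with pytest.raises(NoLineError):
            fit_edge_line(pts, vote_threshold=0.3 * 50)

    def test_no_consensus_on_random_scatter(self):
        rng = np.random.default_rng(1)
        pts = np.column_stack([rng.integers(0, 300, 60), rng.integers(0, 300, 60)])
        with pytest.raises(NoLineError):
            fit_edge_line(pts)


class TestDetectUncutEdge:
    @pytest.mark.parametrize("angle,xb", [(0.0, 180.0), (5.0, 200.0),
                                          (-10.0, 150.0), (25.0, 240.0)])
    def test_recovers_generator_line_from_gt_mask(self, angle, xb):
        s = generate_scene(SceneSpec(noise_sigma=0.0, edge_angle_deg=angle,
                                     edge_bottom_x=xb, seed=7))
        line = detect_uncut_edge(s.mask == 1)
        assert abs(line.bottom_x - xb) <= 2.0
        assert abs(line.vertical_angle_deg - angle) <= 1.0

    def test_border_clamped_mask(self):
        mask = np.zeros((100, 120), dtype=bool)
        mask[40:, :] = True  # crop fills the band to the right border
        line = detect_uncut_edge(mask)
        assert line.bottom_x == pytest.approx(119, abs=1.0)

    def test_translation_equivariance(self):
        base = generate_scene(SceneSpec(noise_sigma=0.0, edge_angle_deg=0.0,
                                        edge_bottom_x=150.0, seed=3))
        mask = base.mask == 1
        shifted = np.zeros_like(mask)
        shifted[:, 30:] = mask[:, :-30]
        d = detect_uncut_edge(shifted).bottom_x - detect_uncut_edge(mask).bottom_x
        assert d == pytest.approx(30.0, abs=1.5)

    def test_rotation_consistency(self):
        """Rotating the boundary pixels changes the fitted angle by the
        rotation, within quantisation."""
        pts = np.array([(150, y) for y in range(60, 300)], dtype=float)
        base = fit_edge_line(pts.astype(int), height=360)
        for alpha in (5.0, -8.0):
            a = np.radians(alpha)
            c, s = np.cos(a), np.sin(a)
            ctr = np.array([180.0, 180.0])
            rot = (pts - ctr) @ np.array([[c, s], [-s, c]]) + ctr
            line = fit_edge_line(np.round(rot).astype(int), height=360)
            # in screen coordinates (y down) this rotation tilts the top of
            # a vertical line to the right for positive alpha
            assert line.vertical_angle_deg - base.vertical_angle_deg == pytest.approx(
                alpha, abs=1.0
            )

    def test_multi_component_flagged(self):
        mask = np.zeros((100, 100), dtype=bool)
        mask[20:90, 10:50] = True
        mask[20:40, 70:90] = True
        seg = filter_small_components(mask, min_area=10)
        assert seg.n_components == 2
        line = detect_uncut_edge(seg)
        assert line.meta["multi_component"] is True

    def test_empty_mask_propagates(self):
        with pytest.raises(EmptyMaskError):
            detect_uncut_edge(np.zeros((20, 20), dtype=bool))
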