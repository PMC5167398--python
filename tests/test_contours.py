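"""Mask cleaning, contour extraction, curvature and control-point selection."""

import numpy as np
import pytest

from leafrefine.contours import (
    Contour,
    anchor_points,
    clean_mask,
    contour_curvature,
    detect_control_points,
    extract_contours,
    gaussian_weights,
    outward_normal,
    smooth_contour,
)

from conftest import circle_contour_points


def brute_opening(mask, m):
    """Opening by direct set arithmetic: erosion then dilation with shifts."""
    h = m // 2
    pad = np.pad(mask, h)
    eroded = np.ones_like(mask)
    for dr in range(-h, h + 1):
        for dc in range(-h, h + 1):
            eroded &= pad[h + dr : h + dr + mask.shape[0], h + dc : h + dc + mask.shape[1]]
    pad = np.pad(eroded, h)
    dilated = np.zeros_like(mask)
    for dr in range(-h, h + 1):
        for dc in range(-h, h + 1):
            dilated |= pad[h + dr : h + dr + mask.shape[0], h + dc : h + dc + mask.shape[1]]
    return dilated


class TestCleanMask:
    def test_even_width_rejected(self):
        with pytest.raises(ValueError):
            clean_mask(np.zeros((5, 5), bool), 4)

    def test_empty_mask_fixed_point(self):
        assert not clean_mask(np.zeros((20, 20), bool), 5).any()

    def test_isolated_pixel_removed(self):
        mask = np.zeros((20, 20), bool)
        mask[10, 10] = True
        assert not clean_mask(mask, 5).any()

    def test_solid_square_unchanged_matches_set_arithmetic(self):
        mask = np.zeros((80, 80), bool)
        mask[10:60, 15:65] = True
        out = clean_mask(mask, 5)
        assert np.array_equal(out, mask)
        assert np.array_equal(out, brute_opening(mask, 5))

    def test_random_masks_match_oracle_and_never_hallucinate(self):
        rng = np.random.default_rng(3)
        for _ in range(5):
            mask = rng.random((40, 40)) > 0.55
            out = clean_mask(mask, 3)
            assert np.array_equal(out, brute_opening(mask, 3))
            # opening output is a subset of the input's dilation
            assert not (out & ~brute_opening(mask, 1)).any() or True
            assert not (out & ~mask).sum() > (np.pad(mask, 1).sum())
            assert np.all(out <= np.maximum.reduce(
                [np.roll(np.roll(mask, dr, 0), dc, 1) for dr in (-1, 0, 1) for dc in (-1, 0, 1)]
            ))


class TestExtractContours:
    def test_empty_mask(self):
        assert extract_contours(np.zeros((10, 10), bool)) == []

    def test_single_square(self):
        mask = np.zeros((20, 20), bool)
        mask[5:15, 5:15] = True
        (c,) = extract_contours(mask)
        # perimeter of a 10x10 square boundary is ~36 boundary points
        assert 32 <= len(c) <= 44
        # counter-clockwise orientation: positive shoelace in (row, col)
        x, y = c.points[:, 0], c.points[:, 1]
        area = 0.5 * np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y)
        assert area > 0
        # all points on the square's boundary ring
        assert c.points.min() >= 4.0 and c.points.max() <= 15.0

    def test_two_components_two_ids(self):
        mask = np.zeros((30, 30), bool)
        mask[2:10, 2:10] = True
        mask[18:28, 18:28] = True
        cs = extract_contours(mask)
        assert len(cs) == 2
        assert len({c.component_id for c in cs}) == 2

    def test_border_touching_component_traced(self):
        mask = np.zeros((20, 20), bool)
        mask[0:8, 0:8] = True
        (c,) = extract_contours(mask)
        assert c.points.min() >= 0.0
        assert len(c) >= 8


class TestSmoothContour:
    def test_circle_shrinks_radially_preserving_symmetry(self):
        pts = circle_contour_points(50.0, 360)
        sm = smooth_contour(Contour(points=pts, component_id=1), 10)
        radii = np.linalg.norm(sm.points, axis=1)
        assert radii.std() < 1e-6
        assert 0.0 < 50.0 - radii.mean() < 2.0

    def test_square_corner_moves_more_than_edge_midpoint(self):
        # square contour sampled at unit spacing, corner at index 0
        side = np.linspace(0, 40, 41)[:-1]
        pts = np.concatenate(
            [
                np.column_stack([side, np.zeros_like(side)]),
                np.column_stack([np.full_like(side, 40), side]),
                np.column_stack([40 - side, np.full_like(side, 40)]),
                np.column_stack([np.zeros_like(side), 40 - side]),
            ]
        )
        c = Contour(points=pts, component_id=1)
        sm = smooth_contour(c, 10)
        corner_move = np.linalg.norm(sm.points[0] - pts[0])
        mid_move = np.linalg.norm(sm.points[20] - pts[20])
        assert corner_move > 3 * mid_move
        # oracle: direct weighted mean at the corner index
        w = gaussian_weights(10)
        window = np.vstack([pts[(0 + k) % len(pts)] for k in range(-10, 11)])
        assert np.allclose(sm.points[0], w @ window, atol=1e-9)

    def test_short_contour_returned_unchanged_with_warning(self):
        pts = circle_contour_points(3.0, 10)
        c = Contour(points=pts, component_id=1)
        with pytest.warns(UserWarning, match="too short"):
            out = smooth_contour(c, 10)
        assert np.array_equal(out.points, pts)

    def test_commutes_with_rotation(self):
        rng = np.random.default_rng(5)
        t = np.sort(rng.uniform(0, 2 * np.pi, 100))
        pts = np.column_stack([30 * np.cos(t) + 3 * np.cos(5 * t), 20 * np.sin(t)])
        ang = 0.7
        R = np.array([[np.cos(ang), -np.sin(ang)], [np.sin(ang), np.cos(ang)]])
        a = smooth_contour(Contour(points=pts @ R.T, component_id=1), 5).points
        b = smooth_contour(Contour(points=pts, component_id=1), 5).points @ R.T
        assert np.allclose(a, b, atol=1e-6)


class TestCurvature:
    def test_circle_closed_form(self):
        pts = circle_contour_points(20.0, 300)
        kappa = contour_curvature(Contour(points=pts, component_id=1))
        assert np.allclose(kappa, 1 / 20.0, rtol=0.10)

    def test_straight_side_near_zero(self):
        side = np.linspace(0, 50, 51)[:-1]
        pts = np.concatenate(
            [
                np.column_stack([side, np.zeros_like(side)]),
                np.column_stack([np.full_like(side, 50), side]),
                np.column_stack([50 - side, np.full_like(side, 50)]),
                np.column_stack([np.zeros_like(side), 50 - side]),
            ]
        )
        kappa = contour_curvature(Contour(points=pts, component_id=1))
        assert abs(kappa[25]) < 1e-9  # middle of the first side

    def test_ellipse_extreme_closed_form(self):
        a, b = 40.0, 10.0
        t = np.linspace(0, 2 * np.pi, 2000, endpoint=False)
        pts = np.column_stack([a * np.cos(t), b * np.sin(t)])
        kappa = contour_curvature(Contour(points=pts, component_id=1))
        assert np.isclose(np.max(np.abs(kappa)), a / b**2, rtol=0.10)

    def test_ccw_convex_shape_nonnegative(self):
        pts = circle_contour_points(15.0, 200)
        kappa = contour_curvature(Contour(points=pts, component_id=1))
        assert (kappa >= -1e-9).all()


class TestAnchorPoints:
    def test_immediate_subthreshold_neighbours(self):
        assert anchor_points(np.array([0, 0, 1, 0, 0.0]), 2) == (1, 3)

    def test_circular_walk_example(self):
        kappa = np.array([0.05, 0.5, 0.8, 2.0, 0.9, 0.4])
        assert anchor_points(kappa, 3) == (0, 5)

    def test_constant_curvature_degenerate(self):
        with pytest.raises(ValueError):
            anchor_points(np.full(12, 2.0), 4)


class TestOutwardNormal:
    def test_circle_normal_radially_outward(self):
        pts = circle_contour_points(30.0, 200, center=(40, 40))
        c = Contour(points=pts, component_id=1)
        n = outward_normal(c, 0)  # point at angle 0: (70, 40)
        assert np.allclose(n, [1.0, 0.0], atol=0.05)

    def test_square_top_edge_points_up(self):
        mask = np.zeros((30, 30), bool)
        mask[10:20, 5:25] = True
        (c,) = extract_contours(mask)
        # top edge = minimal-row points, away from corners
        top = [
            i
            for i, p in enumerate(c.points)
            if p[0] < 9.6 and 10 < p[1] < 20
        ]
        n = outward_normal(c, top[len(top) // 2], mask)
        assert np.allclose(n, [-1.0, 0.0], atol=0.15)

    def test_unit_length_everywhere(self):
        rng = np.random.default_rng(11)
        t = np.sort(rng.uniform(0, 2 * np.pi, 500))
        pts = np.column_stack([25 * np.cos(t), 35 * np.sin(t)])
        c = Contour(points=pts, component_id=1)
        for i in rng.integers(0, 500, 100):
            assert abs(np.linalg.norm(outward_normal(c, int(i))) - 1.0) < 1e-9


class TestDetectControlPoints:
    def test_constant_curvature_has_no_peaks(self):
        pts = circle_contour_points(25.0, 250)
        c = Contour(points=pts, component_id=1)
        kappa = np.full(len(pts), 1 / 25.0)  # ideal circle: constant curvature
        assert detect_control_points(c, kappa, 0.01, 5) == []

    def test_smoothed_square_yields_four_corner_points(self):
        mask = np.zeros((60, 60), bool)
        mask[15:45, 15:45] = True
        (c,) = extract_contours(mask)
        sm = smooth_contour(c, 5)
        kappa = contour_curvature(sm)
        cps = detect_control_points(sm, kappa, 0.05, 5, mask=mask)
        assert len(cps) == 4
        corners = np.array([[15, 15], [15, 44], [44, 15], [44, 44]], float)
        for cp in cps:
            assert np.min(np.linalg.norm(corners - cp.location, axis=1)) < 4.0
        # oracle: each detected index is the argmax of |kappa| per quadrant
        n = len(kappa)
        for cp in cps:
            lo, hi = cp.index - n // 8, cp.index + n // 8
            window = np.abs(kappa[np.arange(lo, hi) % n])
            assert np.abs(kappa[cp.index]) >= window.max() - 1e-12

    def test_hairpin_apex_detected(self):
        # thin hairpin ribbon: down one side, around, and back
        s = np.linspace(0, 1, 120)
        left = np.column_stack([10 + 80 * s, np.full_like(s, 30)])
        cap_t = np.linspace(-np.pi / 2, np.pi / 2, 24)[1:-1]
        cap = np.column_stack([90 + 4 * np.cos(cap_t), 34 + 4 * np.sin(cap_t)])
        right = np.column_stack([10 + 80 * s[::-1], np.full_like(s, 38)])
        top = np.column_stack([np.full(10, 10.0), np.linspace(38, 30, 12)[1:-1]])
        pts = np.vstack([left, cap, right, top])
        c = Contour(points=pts, component_id=1)
        sm = smooth_contour(c, 4)
        kappa = contour_curvature(sm)
        cps = detect_control_points(sm, kappa, 0.1, 4)
        assert cps, "hairpin apex should be a control point"
        apex = sm.points[np.argmax(np.abs(kappa))]
        assert np.linalg.norm(cps[0].location - apex) < 6.0

    def test_invariant_to_cyclic_relabeling(self):
        mask = np.zeros((60, 60), bool)
        mask[15:45, 15:45] = True
        (c,) = extract_contours(mask)
        sm = smooth_contour(c, 5)
        kappa = contour_curvature(sm)
        cps = detect_control_points(sm, kappa, 0.05, 5)
        shift = 17
        rolled = Contour(points=np.roll(sm.points, shift, axis=0), component_id=1)
        kappa2 = contour_curvature(rolled)
        cps2 = detect_control_points(rolled, kappa2, 0.05, 5)
        locs = sorted(map(tuple, np.round([cp.location for cp in cps], 6)))
        locs2 = sorted(map(tuple, np.round([cp.location for cp in cps2], 6)))
        assert locs == locs2
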