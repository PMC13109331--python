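"""Pin color reference, weighted HSV distance, iterative isolation, disk fit."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pinreg3d import (ColoredCloud, PinNotFoundError, PinReference,
                      color_distance, fit_pin_frame, radius_outlier_filter,
                      reference_from_swatch, segment_pin_iterative)
from pinreg3d.pin_segmentation import convex_hull_volume

unit = st.floats(0.0, 1.0, allow_nan=False)


def swatch(rgb, n=8, alpha=255):
    img = np.zeros((n, n, 4), dtype=np.uint8)
    img[..., :3] = rgb
    img[..., 3] = alpha
    return img


class TestReferenceFromSwatch:
    def test_uniform_red_swatch(self):
        ref = reference_from_swatch(swatch((255, 0, 0)))
        assert ref.hsv == pytest.approx((0.0, 1.0, 1.0))

    def test_median_takes_majority_color(self):
        img = swatch((255, 0, 0), n=10)
        img[:4, :, :3] = (0, 0, 255)  # 40% blue, 60% red
        ref = reference_from_swatch(img)
        assert ref.hsv[0] == pytest.approx(0.0)  # red hue wins

    def test_matches_sort_based_median(self, rng):
        from skimage.color import rgb2hsv

        img = (rng.random((12, 12, 3)) * 255).astype(np.uint8)
        rgba = np.dstack([img, np.full((12, 12), 255, np.uint8)])
        ref = reference_from_swatch(rgba)
        hsv = rgb2hsv(img.reshape(-1, 3)[None] / 255.0)[0]
        expected = np.median(np.sort(hsv, axis=0), axis=0)
        assert ref.hsv == pytest.approx(tuple(expected), abs=1e-12)

    def test_fully_transparent_rejected(self):
        with pytest.raises(ValueError):
            reference_from_swatch(swatch((255, 0, 0), alpha=0))


class TestColorDistance:
    def test_identity_is_zero(self):
        ref = PinReference((0.4, 0.6, 0.8))
        assert color_distance(np.array([0.4, 0.6, 0.8]), ref) == 0.0

    def test_maximal_case_is_one(self):
        # Δh = 0.5 (wrap max), Δs = 1, Δv = 1 → normalized to exactly 1
        ref = PinReference((0.0, 0.0, 0.0))
        assert color_distance(np.array([0.5, 1.0, 1.0]), ref) == pytest.approx(1.0)

    def test_hue_wrap_hand_value(self):
        # h 0.9 vs 0.1: wrapped Δh = 0.2 → 0.5·0.2 / 0.65 ≈ 0.1538
        ref = PinReference((0.1, 0.5, 0.5))
        d = color_distance(np.array([0.9, 0.5, 0.5]), ref)
        assert d == pytest.approx(0.10 / 0.65, abs=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            color_distance(np.array([1.2, 0.0, 0.0]), PinReference((0, 0, 0)))

    @settings(derandomize=True, max_examples=100)
    @given(h1=unit, s1=unit, v1=unit, h2=unit, s2=unit, v2=unit)
    def test_symmetric_and_bounded(self, h1, s1, v1, h2, s2, v2):
        d12 = color_distance(np.array([h1, s1, v1]), PinReference((h2, s2, v2)))
        d21 = color_distance(np.array([h2, s2, v2]), PinReference((h1, s1, v1)))
        assert d12 == pytest.approx(d21, abs=1e-12)
        assert 0.0 <= d12 <= 1.0 + 1e-12

    @settings(derandomize=True, max_examples=50)
    @given(h=unit, dh=st.floats(0.0, 0.999), s=unit, v=unit)
    def test_hue_term_periodic(self, h, dh, s, v):
        ref = PinReference((h, s, v))
        a = color_distance(np.array([(h + dh) % 1.0, s, v]), ref)
        b = color_distance(np.array([(h + dh + 1.0) % 1.0, s, v]), ref)
        assert a == pytest.approx(b, abs=1e-9)


class TestRadiusOutlierFilter:
    def test_isolated_point_removed(self, rng):
        ball = rng.uniform(-1.5, 1.5, size=(500, 3))  # dense 3 mm cube
        pts = np.vstack([ball, [[50.0, 0.0, 0.0]]])
        keep = radius_outlier_filter(pts, min_points=40, radius=5.0)
        assert not keep[-1] and keep[:-1].all()

    def test_dense_cluster_unchanged(self, rng):
        pts = rng.normal(scale=1.0, size=(60, 3))  # all mutually within 5 mm
        assert radius_outlier_filter(pts, min_points=40, radius=10.0).all()

    def test_matches_quadratic_oracle(self, rng):
        pts = rng.uniform(-10, 10, size=(80, 3))
        keep = radius_outlier_filter(pts, min_points=5, radius=4.0)
        d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        expected = (d <= 4.0).sum(axis=1) - 1 >= 5  # exclude self
        np.testing.assert_array_equal(keep, expected)


def make_segmentation_fixture():
    """Pin at the origin plus two color-bleed clumps engineered so the
    hull-volume check fails at thresholds 0.35 and 0.30 but passes at 0.25."""
    rng = np.random.default_rng(99)
    ref = PinReference((0.66, 0.90, 0.85))

    def disk(n, radius, center, thickness):
        r = radius * np.sqrt(rng.uniform(size=n))
        a = rng.uniform(0, 2 * np.pi, size=n)
        z = rng.uniform(-thickness / 2, thickness / 2, size=n)
        return np.column_stack([r * np.cos(a), r * np.sin(a), z]) + center

    def ball(n, radius, center):
        p = rng.normal(size=(n, 3))
        p *= (radius * rng.uniform(size=n) ** (1 / 3) /
              np.linalg.norm(p, axis=1))[:, None]
        return p + center

    from skimage.color import hsv2rgb

    def colored(points, hsv):
        rgb = np.tile(hsv2rgb(np.asarray(hsv)[None, None])[0, 0], (len(points), 1))
        return points, rgb

    # pin: true color, flat disk → hull well under 60 mm³
    pin_pts, pin_rgb = colored(disk(300, 5.5, (0, 0, 0), 0.4), (0.66, 0.90, 0.85))
    # clump at d ≈ 0.33 (value offset only): selected at t=0.35 only
    d33_v = 0.85 - 0.33 * 0.65 / 0.3
    a_pts, a_rgb = colored(ball(120, 2.0, (20, 0, 0)), (0.66, 0.90, d33_v))
    # clump at d ≈ 0.28: selected at t = 0.35 and 0.30
    d28_v = 0.85 - 0.28 * 0.65 / 0.3
    b_pts, b_rgb = colored(ball(120, 2.0, (-20, 5, 0)), (0.66, 0.90, d28_v))
    # body: hue-opposite, far outside every threshold
    body_pts, body_rgb = colored(ball(500, 30.0, (0, 0, -40)), (0.12, 0.5, 0.5))

    cloud = ColoredCloud(np.vstack([pin_pts, a_pts, b_pts, body_pts]),
                         np.vstack([pin_rgb, a_rgb, b_rgb, body_rgb]))
    return cloud, ref, np.arange(len(pin_pts))


class TestSegmentPinIterative:
    def test_separable_colors_single_pass(self, rng):
        from skimage.color import hsv2rgb

        pin = rng.normal(scale=2.0, size=(200, 3)) * [1, 1, 0.05]
        body = rng.normal(scale=25.0, size=(2000, 3)) + [0, 0, -60]
        pin_rgb = np.tile(hsv2rgb(np.array([[[0.66, 0.9, 0.85]]]))[0, 0], (200, 1))
        body_rgb = np.tile(hsv2rgb(np.array([[[0.12, 0.5, 0.5]]]))[0, 0], (2000, 1))
        cloud = ColoredCloud(np.vstack([pin, body]), np.vstack([pin_rgb, body_rgb]))
        seg = segment_pin_iterative(cloud, PinReference((0.66, 0.9, 0.85)))
        assert seg.final_threshold == pytest.approx(0.35)
        assert set(seg.pin_indices) <= set(range(200))
        assert len(seg.pin_indices) > 150

    def test_two_decrement_stopping_point(self):
        cloud, ref, _ = make_segmentation_fixture()
        seg = segment_pin_iterative(cloud, ref)
        assert seg.final_threshold == pytest.approx(0.25)
        assert seg.hull_volume <= 60.0
        # trace shows strictly decreasing thresholds with oversized hulls
        ts = [t for t, _, _ in seg.threshold_trace]
        assert ts == sorted(ts, reverse=True)
        assert all(v > 60.0 for _, _, v in seg.threshold_trace[:-1])

    def test_hull_volume_matches_independent_oracle(self):
        import trimesh

        cloud, ref, _ = make_segmentation_fixture()
        seg = segment_pin_iterative(cloud, ref)
        pts = cloud.points[seg.pin_indices]
        oracle = trimesh.PointCloud(pts).convex_hull.volume
        assert seg.hull_volume == pytest.approx(oracle, rel=1e-9)
        assert convex_hull_volume(pts) == pytest.approx(oracle, rel=1e-9)

    def test_pin_not_found_names_tuber(self, rng):
        # achromatic gray sits at d ≈ 0.46 from the saturated reference
        cloud = ColoredCloud(rng.normal(size=(100, 3)),
                             np.tile([0.5, 0.5, 0.5], (100, 1)))
        with pytest.raises(PinNotFoundError, match="R9-9"):
            segment_pin_iterative(cloud, PinReference((0.9, 1.0, 1.0)),
                                  tuber_id="R9-9")


class TestFitPinFrame:
    def test_planar_circle_recovered(self, rng):
        t = np.linspace(0, 2 * np.pi, 100, endpoint=False)
        pts = np.column_stack([np.cos(t), np.sin(t),
                               rng.normal(scale=0.01, size=100)])
        frame = fit_pin_frame(pts, tuber_centroid=[0, 0, -50])
        assert np.linalg.norm(frame.center) < 1e-2
        assert frame.radius == pytest.approx(1.0, abs=1e-3)
        assert abs(frame.normal @ [0, 0, 1]) > 0.999

    def test_three_point_circumcircle(self):
        pts = np.array([[0.0, 0, 0], [2.0, 0, 0], [1.0, 1, 0]])
        frame = fit_pin_frame(pts, tuber_centroid=[1, 0, -10])
        np.testing.assert_allclose(frame.center, [1.0, 0.0, 0.0], atol=1e-9)
        assert frame.radius == pytest.approx(1.0, abs=1e-9)

    def test_normal_points_away_from_tuber(self, rng):
        # pin disk on top of a sphere centered at the origin
        t = np.linspace(0, 2 * np.pi, 80, endpoint=False)
        disk = np.column_stack([5.5 * np.cos(t), 5.5 * np.sin(t),
                                np.full(80, 40.0)])
        disk += rng.normal(scale=0.05, size=disk.shape)
        frame = fit_pin_frame(disk, tuber_centroid=[0, 0, 0])
        assert frame.normal @ [0, 0, 1] > 0.99
        assert frame.normal @ (frame.center - np.array([0, 0, 0.0])) > 0

    def test_frame_is_right_handed_orthonormal(self, rng):
        t = np.linspace(0, 2 * np.pi, 60, endpoint=False)
        axis = rng.normal(size=3)
        axis /= np.linalg.norm(axis)
        # arbitrary tilted disk
        u = np.cross([0.3, 0.7, 0.2], axis)
        u /= np.linalg.norm(u)
        w = np.cross(axis, u)
        disk = 4.0 * (np.outer(np.cos(t), u) + np.outer(np.sin(t), w)) + axis * 30
        frame = fit_pin_frame(disk, tuber_centroid=[0, 0, 0])
        B = frame.basis
        np.testing.assert_allclose(B.T @ B, np.eye(3), atol=1e-9)
        np.testing.assert_allclose(np.cross(frame.u, frame.v), frame.normal,
                                   atol=1e-9)

    def test_rank_deficient_rejected(self):
        with pytest.raises(ValueError):
            fit_pin_frame(np.zeros((5, 3)), tuber_centroid=[0, 0, -1])
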