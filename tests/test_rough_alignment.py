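"""Pin-frame initialization and the cross-strip rotation search."""

import numpy as np
import pytest

from pinreg3d import (ColoredCloud, PinFrame, RigidTransform, apply_transform,
                      crop_neighborhood, extract_strip, init_by_pin,
                      optimal_strip_rotation, scan_N_rotations,
                      select_candidate, rmsd_one_way)
from pinreg3d.rough_alignment import circular_local_minima
from conftest import random_rigid_transform


def make_frame(center=(0, 0, 0), normal=(0, 0, 1), radius=5.5):
    normal = np.asarray(normal, dtype=float)
    normal /= np.linalg.norm(normal)
    ref = np.array([1.0, 0, 0]) if abs(normal[0]) <= 0.9 else np.array([0.0, 1, 0])
    u = np.cross(ref, normal)
    u /= np.linalg.norm(u)
    return PinFrame(center=center, normal=normal, u=u,
                    v=np.cross(normal, u), radius=radius)


def bumpy_patch(n=2000, seed=0):
    """An asymmetric wavy surface patch around the origin (the 'tuber top')."""
    g = np.random.default_rng(seed)
    xy = g.uniform(-30, 30, size=(n, 2))
    z = (0.02 * xy[:, 0] ** 2 / 10 + 2.0 * np.sin(0.2 * xy[:, 0])
         + 1.5 * np.cos(0.17 * xy[:, 1] + 0.8) + 0.05 * xy[:, 1])
    return np.column_stack([xy, z])


class TestInitByPin:
    def test_identical_frames_identity(self):
        f = make_frame(center=(3, 4, 5), normal=(0.2, 0.3, 0.9))
        T = init_by_pin(f, f)
        np.testing.assert_allclose(T.matrix, np.eye(4), atol=1e-12)

    def test_pure_translation(self):
        a = make_frame(center=(0, 0, 0))
        b = make_frame(center=(5, -2, 7))
        T = init_by_pin(a, b)
        np.testing.assert_allclose(T.rotation, np.eye(3), atol=1e-12)
        np.testing.assert_allclose(T.translation_vector, [5, -2, 7], atol=1e-12)

    def test_random_frame_pairs_align_center_and_normal(self):
        g = np.random.default_rng(17)
        for _ in range(100):
            a = make_frame(center=g.uniform(-50, 50, 3), normal=g.normal(size=3))
            b = make_frame(center=g.uniform(-50, 50, 3), normal=g.normal(size=3))
            T = init_by_pin(a, b)
            assert np.linalg.norm(T.apply(a.center) - b.center) < 1e-9
            assert (T.rotation @ a.normal) @ b.normal > 1 - 1e-9
            assert (T.rotation @ a.u) @ b.u > 1 - 1e-9  # zero residual N-twist


class TestCropAndStrips:
    def test_all_beyond_radius_empty(self):
        cloud = ColoredCloud(np.full((10, 3), 100.0))
        assert len(crop_neighborhood(cloud, make_frame(), radius=30)) == 0

    def test_infinite_radius_identity(self, random_cloud):
        cloud = random_cloud(n=40)
        assert len(crop_neighborhood(cloud, make_frame(), radius=np.inf)) == 40

    def test_crop_count_matches_scan(self, random_cloud):
        cloud = random_cloud(n=200, scale=25.0, seed=3)
        frame = make_frame(center=(5, 5, 5))
        got = crop_neighborhood(cloud, frame, radius=30.0)
        expected = sum(np.linalg.norm(p - frame.center) <= 30.0
                       for p in cloud.points)
        assert len(got) == expected

    def test_axis_points_strip_membership(self):
        frame = make_frame()
        on_u = np.outer(np.linspace(-20, 20, 9), frame.u)
        assert len(extract_strip(on_u, frame, "u", width=1.0)) == 9
        # in the v-strip only the origin-adjacent point survives |u| <= 0.5
        assert len(extract_strip(on_u, frame, "v", width=1.0)) == 1

    def test_infinite_width_whole_neighborhood(self, random_cloud):
        cloud = random_cloud(n=100, scale=10.0, seed=5)
        frame = make_frame()
        strip = extract_strip(cloud, frame, "u", width=np.inf, radius=30.0)
        nbhd = crop_neighborhood(cloud, frame, radius=30.0)
        assert len(strip) == len(nbhd)

    def test_membership_matches_predicate_oracle(self, random_cloud):
        cloud = random_cloud(n=300, scale=15.0, seed=6)
        frame = make_frame(normal=(0.3, 0.1, 0.9))
        strip = extract_strip(cloud, frame, "v", width=2.0, radius=25.0)
        expect = [p for p in cloud.points
                  if abs((p - frame.center) @ frame.u) <= 1.0
                  and np.linalg.norm(p - frame.center) <= 25.0]
        assert len(strip) == len(expect)


class TestOptimalStripRotation:
    def test_identical_strips_zero_angle(self):
        frame = make_frame()
        strip = bumpy_patch(300, seed=1)
        angle, rmsd = optimal_strip_rotation(strip, strip, frame, "u")
        assert angle == 0.0
        assert rmsd == pytest.approx(0.0, abs=1e-12)

    def test_constructed_rotation_recovered(self):
        frame = make_frame()
        target = extract_strip(bumpy_patch(4000, seed=2), frame, "u", width=2.0)
        # tilt the u-strip by -10° about v; the search must undo it with +10°
        T = RigidTransform.about_axis(frame.v, -10.0, center=frame.center)
        source = T.apply(target)
        angle, rmsd = optimal_strip_rotation(source, target, frame, "u")
        assert angle == pytest.approx(10.0)
        assert rmsd < 0.05

    def test_grid_matches_second_implementation(self):
        frame = make_frame()
        target = extract_strip(bumpy_patch(3000, seed=3), frame, "v", width=2.0)
        source = RigidTransform.about_axis(frame.u, 7.0,
                                           center=frame.center).apply(target)
        angle, rmsd = optimal_strip_rotation(source, target, frame, "v",
                                             step=5.0, search_range=45.0)
        # independent exhaustive evaluation
        best = min(
            ((a, rmsd_one_way(
                RigidTransform.about_axis(frame.u, a, center=frame.center)
                .apply(source), ColoredCloud(target)))
             for a in np.arange(-45.0, 50.0, 5.0)),
            key=lambda t: (t[1], abs(t[0])))
        assert (angle, rmsd) == pytest.approx(best)

    def test_empty_strip_rejected(self):
        with pytest.raises(ValueError):
            optimal_strip_rotation(np.empty((0, 3)), np.zeros((5, 3)),
                                   make_frame(), "u")


class TestCircularLocalMinima:
    @pytest.mark.parametrize("profile,expected", [
        ([3, 1, 2, 4, 2, 3], [1, 4]),
        ([1, 2, 3, 4, 5, 2], [0]),             # 2 wraps onto smaller 1
        ([2, 1, 1, 3, 0, 5], [1, 4]),          # plateau counted at left edge
        ([1, 1, 1, 1], [0]),                   # flat profile
    ])
    def test_minima_detection(self, profile, expected):
        assert circular_local_minima(np.asarray(profile, float)) == expected


@pytest.fixture(scope="module")
def scan_setup():
    surface = bumpy_patch(6000, seed=8)
    frame = make_frame()
    cloud = ColoredCloud(surface)
    nbhd = crop_neighborhood(cloud, frame, 30.0)
    return nbhd, frame


class TestScanAndSelect:
    def test_identical_clouds_rank1_at_zero(self, scan_setup):
        nbhd, frame = scan_setup
        profile = scan_N_rotations(nbhd, nbhd, frame)
        best = profile.candidates[0]
        assert best.theta_N == 0.0
        assert best.rmsd == pytest.approx(0.0, abs=1e-9)

    def test_prerotated_source_recovered_at_inverse_angle(self, scan_setup):
        nbhd, frame = scan_setup
        T = RigidTransform.about_axis(frame.normal, 40.0, center=frame.center)
        rotated = apply_transform(nbhd, T)
        profile = scan_N_rotations(rotated, nbhd, frame)
        assert profile.candidates[0].theta_N == pytest.approx(320.0)

    def test_search_never_worse_than_init(self, scan_setup):
        nbhd, frame = scan_setup
        T = RigidTransform.about_axis(frame.normal, 73.0, center=frame.center)
        rotated = apply_transform(nbhd, T)
        profile = scan_N_rotations(rotated, nbhd, frame)
        assert profile.candidates[0].rmsd <= profile.rmsd_init + 1e-12

    def test_gauge_invariance_under_u_flip(self, scan_setup):
        """Relabeling u → −u (and v → −v, keeping right-handedness) must
        leave the RMSD profile unchanged."""
        nbhd, frame = scan_setup
        T = RigidTransform.about_axis(frame.normal, 50.0, center=frame.center)
        rotated = apply_transform(nbhd, T)
        flipped = PinFrame(center=frame.center, normal=frame.normal,
                           u=-frame.u, v=-frame.v, radius=frame.radius)
        p1 = scan_N_rotations(rotated, nbhd, frame)
        p2 = scan_N_rotations(rotated, nbhd, flipped)
        np.testing.assert_allclose(p1.rmsd, p2.rmsd, atol=1e-9)
        assert ([c.theta_N for c in p1.candidates]
                == [c.theta_N for c in p2.candidates])

    def test_select_candidate_ranks(self, scan_setup):
        nbhd, frame = scan_setup
        T = RigidTransform.about_axis(frame.normal, 40.0, center=frame.center)
        profile = scan_N_rotations(apply_transform(nbhd, T), nbhd, frame)
        ranks = [c.rank for c in profile.candidates]
        assert ranks == list(range(1, len(ranks) + 1))
        assert select_candidate(profile.candidates, 1) is profile.candidates[0]
        with pytest.raises(ValueError, match="ranks"):
            select_candidate(profile.candidates, len(ranks) + 1)

    def test_empty_neighborhood_rejected(self, scan_setup):
        _, frame = scan_setup
        with pytest.raises(ValueError, match="sparse"):
            scan_N_rotations(np.empty((0, 3)), np.zeros((10, 3)), frame)
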