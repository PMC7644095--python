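"""Skeleton I/O, ring-crossing geometry, and the defasciculation index."""

import numpy as np
import pytest

from flysleep import (
    DIUndefinedError,
    ParseError,
    Skeleton,
    ShollConfig,
    ValidationError,
    best_cone,
    defasciculation_index,
    di_batch,
    read_skeleton,
    ring_intersections,
    write_skeleton,
)
from conftest import random_arbor
from oracles import anchored_cone_max, dense_crossings


def ray(angle_deg, length=170.0, root=(0.0, 0.0)):
    a = np.radians(angle_deg)
    root = np.asarray(root, dtype=float)
    return np.vstack([root, root + length * np.array([np.cos(a), np.sin(a)])])


class TestSkeletonIO:
    def test_linear_swc_is_one_polyline(self, tmp_path):
        p = tmp_path / "lin.swc"
        p.write_text(
            "1 1 0 0 0 1.0 -1\n2 3 0 10 0 1.0 1\n3 3 0 20 0 1.0 2\n"
        )
        skel = read_skeleton(p, dialect="swc")
        assert len(skel.branches) == 1
        np.testing.assert_allclose(skel.branches[0], [[0, 0], [0, 10], [0, 20]])
        np.testing.assert_allclose(skel.root, [0, 0])

    def test_branch_point_splits_into_two_polylines(self, tmp_path):
        p = tmp_path / "y.swc"
        p.write_text(
            "1 1 0 0 0 1.0 -1\n"
            "2 3 0 10 0 1.0 1\n"
            "3 3 -5 20 0 1.0 2\n"
            "4 3 5 20 0 1.0 2\n"
        )
        skel = read_skeleton(p, dialect="swc")
        # one polyline root->branch node, two from the branch node on
        assert len(skel.branches) == 3
        shared = [b for b in skel.branches if np.allclose(b[0], [0, 10])]
        assert len(shared) == 2

    def test_orphan_parent_reference_errors(self, tmp_path):
        p = tmp_path / "bad.swc"
        p.write_text("1 1 0 0 0 1.0 -1\n2 3 0 10 0 1.0 9\n")
        with pytest.raises(ParseError, match="parent"):
            read_skeleton(p, dialect="swc")

    def test_csv_round_trip_preserves_coordinates_exactly(self, tmp_path, rng):
        skel = Skeleton(root=rng.normal(size=2),
                        branches=[rng.normal(size=(7, 2)), rng.normal(size=(4, 2))])
        p = tmp_path / "arbor.csv"
        write_skeleton(skel, p, dialect="csv_polyline")
        back = read_skeleton(p, dialect="csv_polyline")
        np.testing.assert_array_equal(back.root, skel.root)
        for a, b in zip(back.branches, skel.branches):
            np.testing.assert_array_equal(a, b)

    def test_swc_round_trip_for_rooted_arbor(self, tmp_path):
        skel = random_arbor(seed=3)
        p = tmp_path / "arbor.swc"
        write_skeleton(skel, p, dialect="swc")
        back = read_skeleton(p, dialect="swc")
        assert len(back.branches) == len(skel.branches)
        for a, b in zip(back.branches, skel.branches):
            np.testing.assert_array_equal(a, b)

    def test_csv_needs_a_root(self, tmp_path):
        p = tmp_path / "arbor.csv"
        write_skeleton(random_arbor(seed=1), p, dialect="csv_polyline")
        p.with_suffix(".csv.root").unlink()
        with pytest.raises(ValidationError, match="root"):
            read_skeleton(p, dialect="csv_polyline")

    def test_3d_input_rejected_when_projection_disabled(self, tmp_path):
        p = tmp_path / "z.swc"
        p.write_text("1 1 0 0 4.5 1.0 -1\n2 3 0 10 4.5 1.0 1\n")
        with pytest.raises(ValidationError, match="3-D"):
            read_skeleton(p, dialect="swc", project_3d=False)
        assert len(read_skeleton(p, dialect="swc").branches) == 1


class TestRingIntersections:
    def test_radial_segment_crosses_rings_one_and_two(self):
        skel = Skeleton(root=[0, 0], branches=[np.array([[5.0, 0.0], [25.0, 0.0]])])
        inter = ring_intersections(skel)
        assert sorted(c.ring for c in inter.crossings) == [1, 2]
        for c in inter.crossings:
            assert abs(np.linalg.norm(c.point) - c.ring * 10) < 1e-9
            assert c.angle_deg == pytest.approx(0.0, abs=1e-9)

    def test_segment_inside_first_ring_is_empty(self):
        skel = Skeleton(root=[0, 0], branches=[np.array([[1.0, 1.0], [3.0, 2.0]])])
        assert len(ring_intersections(skel)) == 0

    def test_vertex_on_ring_counts_once(self):
        # two consecutive segments share a vertex exactly on ring 1
        branch = np.array([[5.0, 0.0], [10.0, 0.0], [15.0, 5.0]])
        inter = ring_intersections(Skeleton(root=[0, 0], branches=[branch]),
                                   ShollConfig(n_rings=1))
        assert len(inter) == 1

    def test_chord_crosses_twice(self):
        branch = np.array([[-15.0, 5.0], [15.0, 5.0]])
        inter = ring_intersections(Skeleton(root=[0, 0], branches=[branch]),
                                   ShollConfig(n_rings=1))
        assert len(inter) == 2

    def test_out_and_back_counts_two_crossings(self):
        branch = np.array([[5.0, 0.0], [12.0, 0.0], [5.0, 1.0]])
        inter = ring_intersections(Skeleton(root=[0, 0], branches=[branch]),
                                   ShollConfig(n_rings=1))
        assert len(inter) == 2

    @pytest.mark.parametrize("seed", range(12))
    def test_counts_match_dense_resampling_oracle(self, seed):
        skel = random_arbor(seed=seed)
        cfg = ShollConfig()
        inter = ring_intersections(skel, cfg)
        oracle_counts, oracle_angles = dense_crossings(skel, cfg.radii)
        got = np.bincount([c.ring for c in inter.crossings], minlength=cfg.n_rings + 1)[1:]
        np.testing.assert_array_equal(got, oracle_counts)
        np.testing.assert_allclose(np.sort(inter.angles_deg), np.sort(oracle_angles),
                                   atol=1e-7)


class TestBestCone:
    def test_all_angles_equal(self):
        center, count = best_cone(np.full(9, 137.0))
        assert count == 9
        assert abs((center - 137.0 + 180) % 360 - 180) <= 7.5

    def test_opposite_angles_capture_half(self):
        center, count = best_cone(np.array([10.0, 190.0]))
        assert count == 1
        assert center == pytest.approx(2.5)  # smallest candidate centre tie-break

    def test_empty_errors(self):
        with pytest.raises(DIUndefinedError):
            best_cone(np.array([]))

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_exhaustive_anchor_oracle(self, seed):
        rng = np.random.default_rng(seed)
        angles = rng.uniform(0, 360, size=int(rng.integers(1, 60)))
        _, count = best_cone(angles)
        assert count == anchored_cone_max(angles, 15.0)


class TestDefasciculationIndex:
    def test_single_ray_has_zero_di(self):
        res = defasciculation_index(Skeleton(root=[0, 0], branches=[ray(40.0)]))
        assert (res.total, res.in_cone, res.di) == (15, 15, 0.0)

    def test_opposite_rays_split_evenly(self):
        skel = Skeleton(root=[0, 0], branches=[ray(90.0), ray(270.0)])
        res = defasciculation_index(skel)
        assert (res.total, res.in_cone, res.di) == (30, 15, 0.5)

    def test_no_crossings_is_undefined_not_zero(self):
        tiny = Skeleton(root=[0, 0], branches=[np.array([[0.0, 0.0], [2.0, 2.0]])])
        with pytest.raises(DIUndefinedError):
            defasciculation_index(tiny)

    def test_conservation_on_random_arbors(self):
        for seed in range(30):
            res = defasciculation_index(random_arbor(seed=seed))
            assert res.in_cone + round(res.di * res.total) == res.total
            assert 0.0 <= res.di <= 1.0

    def test_rotation_invariance(self):
        cfg = ShollConfig()
        for seed in range(10):
            skel = random_arbor(seed=seed)
            base = defasciculation_index(skel, cfg)
            theta = np.radians(123.4)
            R = np.array([[np.cos(theta), -np.sin(theta)],
                          [np.sin(theta), np.cos(theta)]])
            rot = skel.transformed(lambda p: (np.atleast_2d(p) - skel.root) @ R.T
                                   + skel.root)
            rot = Skeleton(root=skel.root, branches=rot.branches)
            res = defasciculation_index(rot, cfg)
            assert res.total == base.total
            assert res.in_cone == base.in_cone
            assert abs(res.di - base.di) < 1e-12

    def test_scale_covariance(self):
        skel = random_arbor(seed=4)
        base = defasciculation_index(skel, ShollConfig(ring_spacing_um=10.0))
        k = 2.7
        scaled = Skeleton(root=skel.root * k, branches=[b * k for b in skel.branches])
        res = defasciculation_index(scaled, ShollConfig(ring_spacing_um=10.0 * k))
        assert (res.total, res.in_cone) == (base.total, base.in_cone)
        assert res.di == pytest.approx(base.di, abs=1e-12)

    def test_di_non_increasing_in_cone_width(self):
        widths = [5.0, 15.0, 45.0, 90.0, 180.0]
        for seed in range(10):
            skel = random_arbor(seed=seed)
            dis = [defasciculation_index(skel, ShollConfig(cone_full_angle_deg=w)).di
                   for w in widths]
            assert all(a >= b - 1e-12 for a, b in zip(dis, dis[1:]))


class TestDIBatch:
    def test_single_skeleton_single_row(self):
        res = di_batch([("h1", random_arbor(seed=0))])
        assert len(res.per_skeleton) == 1
        assert res.per_skeleton.loc[0, "error"] == ""

    def test_empty_skeleton_is_flagged_not_fatal(self):
        tiny = Skeleton(root=[0, 0], branches=[np.array([[0.0, 0.0], [1.0, 1.0]])])
        res = di_batch([("ok", random_arbor(seed=1)), ("empty", tiny)])
        flagged = res.per_skeleton.set_index("label")
        assert flagged.loc["empty", "error"] != ""
        assert flagged.loc["ok", "error"] == ""

    def test_group_mean_equals_mean_of_rows(self):
        items = [(f"h{i}", random_arbor(seed=i)) for i in range(6)]
        res = di_batch(items)
        assert res.summary.loc[0, "di_mean"] == pytest.approx(
            res.per_skeleton["di"].mean())
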