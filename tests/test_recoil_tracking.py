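import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import brute_force_matching
from tensionfret.recoil_tracking import (
    acute_angle_deg,
    build_tracks,
    classify_orientation,
    compute_recoil,
    filter_tracks,
    fit_projective_map,
    junction_slope,
    link_to_pre,
    match_puncta,
    recoil_angle,
    recoil_angle_from_vector,
)
from tensionfret.synthetic_scenes import (
    PullSimSpec,
    make_junction_scene,
    simulate_pull_sequence,
)


class TestProjectiveMap:
    def test_identity_pairs(self):
        pts = np.array([[0.0, 0], [10, 0], [0, 10], [10, 10], [5, 3], [2, 8]])
        h = fit_projective_map(pts, pts)
        assert np.allclose(h.matrix, np.eye(3), atol=1e-9)
        assert h.reprojection_rms < 1e-9

    def test_known_homography_recovered(self):
        true = np.array([[1.1, 0.05, 2.0], [-0.03, 0.95, 1.0], [0.001, 0.0005, 1.0]])
        src = np.array([[0.0, 0], [30, 0], [0, 30], [30, 30], [10, 18], [22, 7]])
        hom = np.column_stack([src, np.ones(6)]) @ true.T
        dst = hom[:, :2] / hom[:, 2:3]
        h = fit_projective_map(src, dst)
        assert np.max(np.abs(h.matrix - true)) / np.max(np.abs(true)) < 1e-8

    def test_jittered_points_rms(self):
        rng = np.random.default_rng(0)
        src = rng.uniform(0, 50, size=(8, 2))
        dst = src + np.array([3.0, -2.0]) + rng.normal(0, 0.1, size=(8, 2))
        h = fit_projective_map(src, dst)
        assert h.reprojection_rms <= 0.2

    def test_too_few_points(self):
        pts = np.zeros((3, 2))
        with pytest.raises(ValueError, match="at least 4"):
            fit_projective_map(pts, pts)

    def test_degenerate_configuration(self):
        src = np.array([[0.0, 0], [1, 1], [2, 2], [3, 3]])  # collinear
        with pytest.raises(ValueError, match="degenerate"):
            fit_projective_map(src, src + 1.0)


class TestMatching:
    def test_identity_sets(self):
        pts = np.array([[0.0, 0], [5, 5], [9, 1]])
        m = match_puncta(pts, pts, 10)
        assert sorted(m.pairs) == [(0, 0), (1, 1), (2, 2)]
        assert m.total_displacement == 0.0

    def test_translation_pythagorean(self):
        rng = np.random.default_rng(2)
        a = rng.uniform(0, 30, size=(5, 2))
        b = a + np.array([3.0, 4.0])
        m = match_puncta(a, b, 10)
        assert len(m.pairs) == 5
        assert m.total_displacement == pytest.approx(25.0)

    @pytest.mark.parametrize("seed", [7, 0, 1])
    def test_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.uniform(0, 20, size=(6, 2))
        b = rng.uniform(0, 20, size=(6, 2))
        m = match_puncta(a, b, 12.0)
        pairs, cost = brute_force_matching(a, b, 12.0)
        assert len(m.pairs) == len(pairs)
        assert m.total_displacement == pytest.approx(cost, abs=1e-9)

    def test_unmatched_beyond_gate(self):
        a = np.array([[0.0, 0.0], [100.0, 100.0]])
        b = np.array([[1.0, 0.0]])
        m = match_puncta(a, b, 5.0)
        assert m.pairs == [(0, 0)]
        assert m.unmatched_a == [1]

    def test_empty_sets(self):
        m = match_puncta(np.empty((0, 2)), np.array([[1.0, 2.0]]), 5.0)
        assert m.pairs == [] and m.unmatched_b == [0]


class TestRecoilVectors:
    def test_zero_displacement(self):
        pts = np.array([[1.0, 1.0]])
        m = match_puncta(pts, pts, 5)
        tr = compute_recoil(m, pts, pts)
        assert tr["d_r_um"].iloc[0] == 0.0

    def test_six_eight_ten(self):
        a = np.array([[0.0, 0.0]])
        b = np.array([[6.0, 8.0]])
        m = match_puncta(a, b, 15)
        tr = compute_recoil(m, a, b)
        assert tr["d_r_um"].iloc[0] == pytest.approx(10.0)

    def test_simulator_ground_truth(self):
        base, poly = make_junction_scene(n_puncta=10)
        h = np.array([[1.0, 0.0, 3.0], [0.0, 1.0, 4.0], [0.0, 0.0, 1.0]])
        seq = simulate_pull_sequence(
            PullSimSpec(base_scene=base, homography=h, recoil_fraction=1.0,
                        junction_polyline=poly)
        )
        pull = seq.tables["pull"][["x_um", "y_um"]].to_numpy()
        post = seq.tables["post"][["x_um", "y_um"]].to_numpy()
        m = match_puncta(pull, post, 15)
        tr = compute_recoil(m, pull, post)
        assert np.max(np.abs(tr["d_r_um"] - 5.0)) < 0.05


class TestLinkToPre:
    def _tracks_and_tables(self, drop_pre=None):
        pre = pd.DataFrame(
            {"x_um": [1.0, 5.0, 9.0], "y_um": [1.0, 1.0, 1.0],
             "fret_index": [50.0, 51.0, 52.0]}
        )
        if drop_pre is not None:
            pre = pre.drop(index=drop_pre).reset_index(drop=True)
        post = pd.DataFrame(
            {"x_um": [1.0, 5.0, 9.0], "y_um": [1.0, 1.0, 1.0],
             "fret_index": [48.0, 49.0, 50.0]}
        )
        m1 = match_puncta(post[["x_um", "y_um"]].to_numpy(),
                          post[["x_um", "y_um"]].to_numpy(), 5)
        tracks = compute_recoil(m1, post[["x_um", "y_um"]].to_numpy(),
                                post[["x_um", "y_um"]].to_numpy())
        m2 = match_puncta(post[["x_um", "y_um"]].to_numpy(),
                          pre[["x_um", "y_um"]].to_numpy(), 2)
        return link_to_pre(tracks, m2, pre)

    def test_identical_scenes_all_linked(self):
        tracks = self._tracks_and_tables()
        assert not tracks["unlinked_pre"].any()
        assert np.allclose(tracks["fret_pre"], [50.0, 51.0, 52.0])

    def test_missing_pre_flagged(self):
        tracks = self._tracks_and_tables(drop_pre=1)
        assert tracks["unlinked_pre"].sum() == 1

    def test_dropout_fraction(self):
        rng = np.random.default_rng(3)
        n = 200
        post = pd.DataFrame({"x_um": rng.uniform(0, 200, n) * 5,
                             "y_um": rng.uniform(0, 200, n) * 5,
                             "fret_index": 50.0})
        keep = rng.random(n) > 0.10
        pre = post[keep].reset_index(drop=True)
        m1 = match_puncta(post[["x_um", "y_um"]].to_numpy(),
                          post[["x_um", "y_um"]].to_numpy(), 5)
        tracks = compute_recoil(m1, post[["x_um", "y_um"]].to_numpy(),
                                post[["x_um", "y_um"]].to_numpy())
        m2 = match_puncta(post[["x_um", "y_um"]].to_numpy(),
                          pre[["x_um", "y_um"]].to_numpy(), 1.0)
        linked = ~link_to_pre(tracks, m2, pre)["unlinked_pre"]
        # binomial 3-sigma band around 90%
        se = math.sqrt(0.9 * 0.1 / n)
        assert abs(linked.mean() - 0.9) < 3 * se


class TestJunctionSlope:
    def test_collinear_exact(self):
        xy = np.array([[i, i] for i in range(5)], dtype=float)  # slope 1
        ang, se, ok = junction_slope(xy[2], xy, radius_um=10)
        assert ang == pytest.approx(45.0, abs=1e-9)
        assert se == pytest.approx(0.0, abs=1e-9)
        assert ok

    def test_two_points_unreliable(self):
        xy = np.array([[0.0, 0.0], [1.0, 1.0]])
        _, _, ok = junction_slope(xy[0], xy, radius_um=10)
        assert not ok

    def test_outlier_robustness(self):
        xy = np.array([[i * 0.5, i * 0.35] for i in range(8)], dtype=float)
        clean_slope = 0.7  # y = 0.7 x
        outlier = np.array([[1.0, 3.5]])
        ang, se, ok = junction_slope(xy[3], np.vstack([xy, outlier]), radius_um=10)
        assert ok
        assert math.tan(math.radians(ang)) == pytest.approx(clean_slope, rel=0.05)

    def test_vertical_contact_no_infinities(self):
        xy = np.array([[2.0, i] for i in range(5)], dtype=float)
        ang, se, ok = junction_slope(xy[2], xy, radius_um=10)
        assert abs(ang) == pytest.approx(90.0, abs=1e-6)
        assert ok

    def test_high_se_unreliable(self):
        rng = np.random.default_rng(0)
        xy = rng.uniform(0, 3, size=(6, 2))  # isotropic blob: huge slope SE
        _, se, ok = junction_slope(xy[0], xy, radius_um=10, max_se_deg=9)
        assert se > 9 and not ok


class TestRecoilAngle:
    def test_parallel_is_zero(self):
        assert recoil_angle(0.7, 0.7) == pytest.approx(0.0, abs=1e-12)

    def test_perpendicular_vertical_recoil(self):
        assert recoil_angle_from_vector(np.array([0.0, 1.0]), 0.0) == pytest.approx(90.0)

    def test_arctan_one(self):
        assert recoil_angle(1.0, 0.0) == pytest.approx(45.0)

    @given(st.floats(-5, 5), st.floats(-5, 5))
    @settings(max_examples=100, deadline=None)
    def test_symmetry(self, m1, m2):
        assert recoil_angle(m1, m2) == pytest.approx(recoil_angle(m2, m1), abs=1e-9)

    def test_range(self):
        rng = np.random.default_rng(4)
        for _ in range(100):
            a = recoil_angle(rng.normal() * 5, rng.normal() * 5)
            assert 0.0 <= a <= 90.0

    def test_rotation_invariance(self):
        rng = np.random.default_rng(5)
        vec = np.array([1.2, 0.7])
        contact_deg = 23.0
        base = recoil_angle_from_vector(vec, contact_deg)
        for _ in range(10):
            th = rng.uniform(0, 2 * math.pi)
            rot = np.array([[math.cos(th), -math.sin(th)], [math.sin(th), math.cos(th)]])
            rotated = recoil_angle_from_vector(rot @ vec, contact_deg + math.degrees(th))
            assert rotated == pytest.approx(base, abs=1e-9)


class TestFilters:
    @staticmethod
    def _track_row(d_r, dx=None, dy=0.0, x=0.0, y=0.0):
        dx = d_r if dx is None else dx
        return {"x_pull": x, "y_pull": y, "recoil_dx": dx, "recoil_dy": dy,
                "d_r_um": float(np.hypot(dx, dy))}

    def test_small_recoil_boundary(self):
        tracks = pd.DataFrame([self._track_row(0.8), self._track_row(1.0, x=2.0)])
        out = filter_tracks(tracks, neighbor_radius_um=100, min_neighbors=1)
        assert "small_recoil" in out["flags"].iloc[0]
        assert "small_recoil" not in out["flags"].iloc[1]

    def test_window_boundary(self):
        tracks = pd.DataFrame([self._track_row(11.0), self._track_row(10.0, x=2.0)])
        out = filter_tracks(tracks, neighbor_radius_um=100, min_neighbors=1)
        assert "out_of_window" in out["flags"].iloc[0]
        assert "out_of_window" not in out["flags"].iloc[1]

    def test_isolated(self):
        rows = [self._track_row(2.0, x=0.0), self._track_row(2.0, x=1.0),
                self._track_row(2.0, x=100.0)]
        out = filter_tracks(pd.DataFrame(rows), neighbor_radius_um=10, min_neighbors=1)
        assert "isolated" in out["flags"].iloc[2]
        assert "isolated" not in out["flags"].iloc[0]

    def test_direction_mismatch(self):
        rows = [self._track_row(3.0, x=float(i)) for i in range(5)]
        rows.append(self._track_row(3.0, dx=-3.0, x=2.5))  # recoils opposite
        out = filter_tracks(pd.DataFrame(rows), neighbor_radius_um=10, min_neighbors=2)
        assert "direction_mismatch" in out["flags"].iloc[5]
        assert all("direction_mismatch" not in f for f in out["flags"].iloc[:5])

    def test_classify_orientation_boundary(self):
        assert classify_orientation(45.0) == "parallel"
        assert classify_orientation(45.1) == "perpendicular"
        assert classify_orientation(0.0) == "parallel"
        with pytest.raises(ValueError):
            classify_orientation(95.0)


class TestEndToEnd:
    def test_geometry_recovery(self):
        """Estimated (d_r, alpha_r) match ground truth within (0.1 um, 2 deg)
        for >= 95% of unflagged tracks."""
        n_total, n_good = 0, 0
        for seed, (dx, dy) in enumerate([(0.0, 4.0), (2.0, 3.0), (3.0, 1.0)]):
            base, poly = make_junction_scene(n_puncta=14, seed=seed)
            h = np.array([[1.0, 0.0, dx], [0.0, 1.0, dy], [0.0, 0.0, 1.0]])
            seq = simulate_pull_sequence(
                PullSimSpec(base_scene=base, homography=h, recoil_fraction=1.0,
                            junction_polyline=poly, seed=seed)
            )
            tracks = build_tracks(
                seq.tables["pre"], seq.tables["pull"], seq.tables["post"],
                control_points=seq.control_points,
            )
            ok = tracks[tracks["flags"] == ""]
            truth = seq.truth
            for _, row in ok.iterrows():
                t = truth.iloc[int(row["pull_id"])]
                n_total += 1
                if (abs(row["d_r_um"] - t["d_r_um"]) <= 0.1
                        and abs(row["alpha_r_deg"] - t["alpha_r_deg"]) <= 2.0):
                    n_good += 1
        assert n_total > 20
        assert n_good / n_total >= 0.95

    def test_acute_angle_helper(self):
        assert acute_angle_deg(170.0, 10.0) == pytest.approx(20.0)
        assert acute_angle_deg(-80.0, 80.0) == pytest.approx(20.0)
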