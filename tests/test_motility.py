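"""Trajectory linking, kinematics and the twelve-metric motility suite."""

import math

import numpy as np
import pytest

from abcells.motility import (
    Trajectory,
    aggregate,
    kinematics,
    link_trajectories,
    motility_metrics,
    msd_lag,
)
from abcells.synth import Brownian, gen_trajectory


def _traj(points, frames=None, areas=None):
    pts = np.asarray(points, dtype=float)
    return Trajectory(
        0, np.arange(len(pts)) if frames is None else frames, pts, areas=areas
    )


class TestLinking:
    def test_step_within_bound_links(self):
        trajs = link_trajectories([np.array([[0.0, 0]]), np.array([[5.2, 0]])])
        assert len(trajs) == 1 and len(trajs[0]) == 2

    def test_step_beyond_bound_splits_tracks(self):
        trajs = link_trajectories([np.array([[0.0, 0]]), np.array([[10.4, 0]])])
        assert len(trajs) == 2

    def test_two_frame_gap_bridged_collinearly(self):
        frames = [
            np.array([[0.0, 0.0]]),
            np.empty((0, 2)),
            np.empty((0, 2)),
            np.array([[6.0, 3.0]]),
        ]
        (tr,) = link_trajectories(frames)
        assert len(tr) == 4
        np.testing.assert_allclose(
            tr.positions, [[0, 0], [2, 1], [4, 2], [6, 3]]
        )
        assert tr.interpolated.tolist() == [False, True, True, False]

    def test_three_frame_gap_not_bridged(self):
        frames = [np.array([[0.0, 0.0]])] + [np.empty((0, 2))] * 3 + [
            np.array([[4.0, 0.0]])
        ]
        assert len(link_trajectories(frames)) == 2

    def test_mutual_nearest_neighbor_resolves_crossings(self):
        # two cells 8 µm apart moving 1 µm/frame: nearest-neighbor keeps lanes
        f0 = np.array([[0.0, 0.0], [0.0, 8.0]])
        f1 = np.array([[1.0, 0.0], [1.0, 8.0]])
        trajs = link_trajectories([f0, f1])
        assert len(trajs) == 2
        assert all(len(t) == 2 for t in trajs)

    def test_negative_bound_rejected(self):
        with pytest.raises(ValueError):
            link_trajectories([np.zeros((1, 2))], max_step_um=-1)


class TestKinematics:
    def test_three_four_five(self):
        k = kinematics(_traj([[0, 0], [3, 4]]))
        assert k.displacement_um[0] == pytest.approx(5.0)
        assert k.speed_um_per_frame[0] == pytest.approx(5.0)

    def test_stationary_is_all_zero(self):
        k = kinematics(_traj([[1, 1]] * 5))
        assert np.all(k.displacement_um == 0)
        assert np.all(k.acceleration_um_per_frame2 == 0)

    def test_quadratic_path_finite_differences(self):
        xs = np.array([k**2 for k in range(6)], float)
        k = kinematics(_traj(np.c_[xs, np.zeros(6)]))
        np.testing.assert_allclose(k.speed_um_per_frame, [1, 3, 5, 7, 9])
        np.testing.assert_allclose(k.acceleration_um_per_frame2, [2, 2, 2, 2])

    def test_single_point_rejected(self):
        with pytest.raises(ValueError):
            kinematics(_traj([[0, 0]]))


class TestMotilityMetrics:
    def test_straight_line_is_maximally_persistent(self):
        m = motility_metrics(_traj(np.c_[np.arange(6.0), np.zeros(6)]))
        assert m.directional_persistence == pytest.approx(1.0)
        assert m.meandering_index == pytest.approx(1.0)
        assert m.mean_turning_angle_deg == pytest.approx(0.0)
        assert m.directionality_ratio == pytest.approx(1.0)

    def test_closed_square_loop(self):
        m = motility_metrics(
            _traj([[0, 0], [1, 0], [1, 1], [0, 1], [0, 0]])
        )
        assert m.meandering_index == pytest.approx(0.0)
        assert m.mean_turning_angle_deg == pytest.approx(90.0)
        assert m.directional_persistence == pytest.approx(0.0, abs=1e-12)

    def test_msd_from_origin_definition(self):
        m = motility_metrics(_traj(np.c_[np.arange(4.0), np.zeros(4)]))
        assert m.msd == pytest.approx(14 / 3)

    def test_arrest_coefficient_half(self):
        steps = np.array([0.1, 0.1, 0.3, 0.3])
        m = motility_metrics(
            _traj(np.c_[np.concatenate([[0], np.cumsum(steps)]), np.zeros(5)])
        )
        assert m.arrest_coefficient == pytest.approx(0.5)

    def test_arrest_monotone_in_threshold(self):
        rng = np.random.default_rng(3)
        tr = _traj(np.cumsum(rng.normal(0, 0.3, (40, 2)), axis=0))
        coeffs = [
            motility_metrics(tr, arrest_threshold=t).arrest_coefficient
            for t in [0.05, 0.2, 0.5, 1.0]
        ]
        assert coeffs == sorted(coeffs)

    def test_two_point_gyration(self):
        m = motility_metrics(_traj([[-3.0, 0], [3.0, 0]]))
        assert m.radius_of_gyration == pytest.approx(3.0)

    def test_stationary_angles_missing_not_zero(self):
        m = motility_metrics(_traj([[2, 2]] * 4))
        assert math.isnan(m.directional_persistence)
        assert math.isnan(m.mean_turning_angle_deg)
        assert math.isnan(m.relative_motion_change)

    def test_rigid_motion_invariance(self):
        rng = np.random.default_rng(11)
        pts = np.cumsum(rng.normal(0, 1, (30, 2)), axis=0)
        th = 0.7
        R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        m0 = motility_metrics(_traj(pts))
        m1 = motility_metrics(_traj(pts @ R.T + [13.0, -4.0]))
        for name in ("msd", "directional_persistence", "meandering_index",
                     "mean_turning_angle_deg", "radius_of_gyration",
                     "arrest_coefficient", "mean_speed"):
            assert getattr(m0, name) == pytest.approx(getattr(m1, name), abs=1e-9)

    def test_brownian_lag_msd_slope(self):
        """Diffusive scaling: per-lag MSD slope approximates 2·σ²·dim."""
        sigma = 1.5
        curves = []
        rng = np.random.default_rng(21)
        for i in range(300):
            tr = gen_trajectory(Brownian(sigma), 50, rng=rng)
            curves.append(msd_lag(tr, max_lag=10))
        mean_curve = np.mean(curves, axis=0)
        slope = np.polyfit(np.arange(1, 11), mean_curve, 1)[0]
        assert slope == pytest.approx(2 * sigma**2, rel=0.1)


class TestAggregation:
    def test_dynamic_single_track_constant_speed(self):
        tr = _traj(np.c_[np.arange(5.0) * 2, np.zeros(5)])
        df = aggregate([tr], "dynamic")
        assert len(df) == 1
        assert df.mean_speed.iloc[0] == pytest.approx(2.0)
        assert list(df.columns[1:]) == [
            "msd", "directional_persistence", "meandering_index",
            "mean_turning_angle_deg", "radius_of_gyration",
            "arrest_coefficient", "shape_motion_coupling",
            "relative_motion_change", "velocity_cross_correlation",
            "directionality_ratio", "mean_speed", "mean_acceleration",
        ]

    def test_static_mean_over_overlapping_tracks(self):
        t1 = _traj(np.c_[np.arange(5.0), np.zeros(5)])
        t2 = Trajectory(1, np.arange(5), np.c_[np.arange(5.0) * 3, np.ones(5)])
        df = aggregate([t1, t2], "static")
        assert np.allclose(df.mean_speed_um_per_frame, 2.0)

    def test_static_staggered_tracks_use_present_cells_only(self):
        # hand-computed: track A speed 1 on frames 1-4, track B speed 3
        # only on frames 3-4 -> frame means 1, 1, 2, 2
        a = Trajectory(0, np.arange(5), np.c_[np.arange(5.0), np.zeros(5)])
        b = Trajectory(1, np.arange(2, 5), np.c_[np.arange(3.0) * 3, np.ones(3)])
        df = aggregate([a, b], "static").set_index("frame")
        assert df.loc[1, "mean_speed_um_per_frame"] == pytest.approx(1.0)
        assert df.loc[2, "mean_speed_um_per_frame"] == pytest.approx(1.0)
        assert df.loc[3, "mean_speed_um_per_frame"] == pytest.approx(2.0)
        assert df.loc[4, "mean_speed_um_per_frame"] == pytest.approx(2.0)
        assert df.loc[3, "n_cells"] == 2

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            aggregate([], "dynamic")


class TestSharpTurns:
    def test_square_loop_has_no_turns_above_default_threshold(self):
        from abcells.motility import sharp_turn_fraction
        sq = _traj([[0, 0], [1, 0], [1, 1], [0, 1], [0, 0]])
        assert sharp_turn_fraction(sq) == 0.0  # 90° turns are not > 90°
        assert sharp_turn_fraction(sq, threshold_deg=45.0) == 1.0

    def test_reversal_counts_as_sharp(self):
        from abcells.motility import sharp_turn_fraction
        zig = _traj([[0, 0], [1, 0], [0, 0], [1, 0]])
        assert sharp_turn_fraction(zig) == 1.0
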