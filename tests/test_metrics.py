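"""Per-trial metric computations against analytic oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as hst

import starmaze as sm
from starmaze.metrics import (
    MetricComputationError,
    find_capture,
    sample_ideal_trajectory,
)
from conftest import make_trajectory


class TestTotalPathLength:
    def test_three_four_five_triangle(self):
        traj = make_trajectory([(0, 0), (3, 4)])
        assert sm.total_path_length(traj) == pytest.approx(5.0)

    def test_concatenation_with_reverse_doubles_length(self):
        pts = [(0, 0), (1, 2), (3, 3), (5, 0)]
        forward = make_trajectory(pts)
        there_and_back = make_trajectory(pts + pts[-2::-1])
        assert sm.total_path_length(there_and_back) == pytest.approx(
            2 * sm.total_path_length(forward)
        )

    def test_dense_resampling_preserves_length(self):
        n = 5000
        s = np.linspace(0, 1, n)
        traj = sm.Trajectory(s, 3 * s, 4 * s)
        assert sm.total_path_length(traj) == pytest.approx(5.0, abs=1e-9)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(scale=hst.floats(min_value=0.1, max_value=50.0))
    def test_invariant_under_time_reparametrization(self, scale):
        t = np.array([0.0, 0.3, 1.1, 2.0])
        x = np.array([0.0, 1.0, -2.0, 4.0])
        y = np.array([0.0, 2.0, 2.0, -1.0])
        a = sm.Trajectory(t, x, y)
        b = sm.Trajectory(t * scale, x, y)
        assert sm.total_path_length(a) == pytest.approx(sm.total_path_length(b))


class TestDetectSuccess:
    def test_capture_time_interpolated(self, maze, training_spec):
        # straight run into the alley-3 reward at 1 m per second of sample spacing
        reward = maze.reward_point(3)
        start = maze.alley_end(1)
        traj = sample_ideal_trajectory(sm.ideal_path(1, 3, maze), speed_m_s=8.2)
        success, t_reward, alley = sm.detect_success(traj, training_spec, maze)
        assert success and alley == 3
        assert t_reward == pytest.approx((246.0 - 2.0) / 8.2, abs=1e-6)

    def test_reward_after_time_limit_is_failure(self, maze, training_spec):
        slow = sample_ideal_trajectory(sm.ideal_path(1, 3, maze), speed_m_s=1.8)
        # 246 m at 1.8 m/s needs ~136 s > the 120 s limit
        success, t_reward, alley = sm.detect_success(slow, training_spec, maze)
        assert not success and t_reward is None and alley is None

    def test_never_leaving_center_is_failure(self, maze, training_spec):
        traj = make_trajectory([(0, 0), (1, 0), (0, 1), (-1, 0)])
        assert sm.detect_success(traj, training_spec, maze) == (False, None, None)


class TestVisitedAlleys:
    def test_ideal_run_visits_exactly_start_and_goal(self, maze, ideal_training_trajectory):
        visited = sm.visited_alleys(ideal_training_trajectory, maze, start_alley=1)
        assert visited == (1, 3)

    def test_tour_through_every_alley_counts_five(self, maze):
        pts = []
        for a in range(1, 6):
            pts.append(maze.vertices[a - 1])
            pts.append(maze.vertices[a - 1] + 0.5 * maze.config.alley_length * maze.alley_units[a - 1])
            pts.append(maze.vertices[a - 1])
        visited = sm.visited_alleys(make_trajectory(pts), maze, start_alley=1)
        assert len(visited) == 5

    def test_shallow_graze_below_threshold_not_counted(self, maze):
        depth_fraction = 0.10
        graze_depth = 0.5 * depth_fraction * maze.config.alley_length
        pts = [
            maze.alley_end(1),
            maze.vertices[0],
            maze.vertices[1] + graze_depth * maze.alley_units[1],  # half the threshold into alley 2
            maze.vertices[1],
            maze.vertices[2],
            maze.alley_end(3),
        ]
        visited = sm.visited_alleys(make_trajectory(pts), maze, depth_fraction, start_alley=1)
        assert visited == (1, 3)

    def test_entry_order_preserved(self, maze):
        depth = 0.5 * maze.config.alley_length
        pts = [maze.alley_end(4), maze.vertices[3]]
        for a in (2, 5):
            pts += [maze.vertices[a - 1], maze.vertices[a - 1] + depth * maze.alley_units[a - 1],
                    maze.vertices[a - 1]]
        visited = sm.visited_alleys(make_trajectory(pts), maze, start_alley=4)
        assert visited == (4, 2, 5)


class TestDistanceError:
    def test_ideal_trace_has_zero_de(self, maze, training_spec, ideal_training_trajectory):
        de = sm.distance_error(ideal_training_trajectory, training_spec, maze)
        assert de == pytest.approx(0.0, abs=1e-6)

    def test_double_distance_gives_100_percent(self, maze, training_spec):
        # prepend an out-and-back stub of half the ideal length: travelled = 2 × ideal
        extra = 246.0
        u = maze.alley_units[0]
        stub = maze.alley_end(1) + (extra / 2) * np.array([u[1], -u[0]])  # sideways, reward-free
        ideal = sm.ideal_path(1, 3, maze)
        poly = np.vstack([maze.alley_end(1), stub, ideal.polyline])
        traj = sample_ideal_trajectory(sm.IdealPath(1, 3, poly, 0.0, 0.0), speed_m_s=8.2)
        de = sm.distance_error(traj, training_spec, maze)
        assert de == pytest.approx(100.0, abs=1e-6)

    def test_jittered_path_de_vanishes_with_amplitude(self, maze, training_spec):
        rng = np.random.default_rng(42)
        base = sample_ideal_trajectory(sm.ideal_path(1, 3, maze), speed_m_s=8.2)
        des = []
        for eps in (0.5, 0.05, 0.005):
            noise = rng.normal(0, eps, size=(len(base), 2))
            # keep endpoints exact so capture stays at the reward
            noise[0] = noise[-1] = 0.0
            traj = sm.Trajectory(base.time_s, base.x_m + noise[:, 0], base.y_m + noise[:, 1])
            des.append(sm.distance_error(traj, training_spec, maze))
        assert des[0] > des[1] > des[2] >= 0.0
        assert des[2] < 1.0

    def test_de_nonnegative_for_successful_runs(self, maze, training_spec):
        rng = np.random.default_rng(3)
        for _ in range(10):
            base = sample_ideal_trajectory(sm.ideal_path(1, 3, maze), speed_m_s=8.2)
            noise = rng.normal(0, 0.3, size=(len(base), 2))
            noise[0] = noise[-1] = 0.0
            traj = sm.Trajectory(base.time_s, base.x_m + noise[:, 0], base.y_m + noise[:, 1])
            success, _, _ = sm.detect_success(traj, training_spec, maze)
            if success:
                assert sm.distance_error(traj, training_spec, maze) >= -1e-9


class TestRotationAngle:
    def test_ideal_trace_has_zero_ra(self, maze, training_spec, ideal_training_trajectory):
        ra = sm.rotation_angle(ideal_training_trajectory, training_spec, maze)
        assert abs(ra) < 1.0

    def test_full_loop_adds_360_degrees(self, maze, training_spec):
        # insert a circle tangent to the centre chord: the polygonal exterior
        # angles of a tangent closed loop sum to exactly 360°
        ideal = sm.ideal_path(1, 3, maze)
        v1, v3 = ideal.polyline[1], ideal.polyline[2]
        mid = 0.5 * (v1 + v3)
        d = (v3 - v1) / np.hypot(*(v3 - v1))
        n = np.array([-d[1], d[0]])
        r = 1.0  # loop radius well above min_step
        center = mid + r * n
        phi = np.linspace(0, 2 * np.pi, 65)
        loop = center + r * (-np.outer(np.cos(phi), n) + np.outer(np.sin(phi), d))
        poly = np.vstack([ideal.polyline[:2], loop, ideal.polyline[2:]])
        traj = sample_ideal_trajectory(sm.IdealPath(1, 3, poly, 0.0, 0.0), speed_m_s=8.2)
        ra = sm.rotation_angle(traj, training_spec, maze)
        # small slack: the min-step decimation wiggles slightly at the tangency
        assert ra == pytest.approx(360.0, abs=5.0)

    def test_zigzag_corners_sum_exactly(self, maze, test_spec):
        # constructed polyline oracle: k alternating 90° corners → 90·k degrees
        k = 6
        step = 2.0
        pts = [np.array([0.0, 0.0])]
        heading = 0.0
        for i in range(k + 1):
            delta = np.array([np.cos(np.radians(heading)), np.sin(np.radians(heading))])
            pts.append(pts[-1] + step * delta)
            heading += 90.0 if i % 2 == 0 else -90.0
        traj = make_trajectory(pts)
        # failure trial: reference ideal is the nearer reward (alley 3 from start 4)
        ra = sm.rotation_angle(traj, test_spec, maze, min_step=0.05)
        ideal_min = sm.ideal_path(4, 3, maze).min_rotation_deg
        assert ra + ideal_min == pytest.approx(90.0 * k, abs=1e-6)

    def test_stationary_trajectory_raises(self, maze, training_spec):
        t = np.linspace(0, 1, 50)
        traj = sm.Trajectory(t, np.full_like(t, 0.001) * np.sin(t), np.zeros_like(t))
        with pytest.raises(MetricComputationError):
            sm.rotation_angle(traj, training_spec, maze)


class TestComputeTrialMetrics:
    def test_ideal_success_trial(self, maze, training_spec, ideal_training_trajectory):
        m = sm.compute_trial_metrics(ideal_training_trajectory, training_spec, maze)
        assert m.success
        assert m.visited_n == 2
        assert m.tpl_m == pytest.approx(246.0, abs=1e-9)
        assert m.de_pct == pytest.approx(0.0, abs=1e-6)
        assert abs(m.ra_deg) < 1.0
        assert m.mean_speed_m_s == pytest.approx(8.2, abs=1e-6)

    def test_stationary_trajectory_flags_ra(self, maze, training_spec):
        t = np.linspace(0, 10, 100)
        traj = sm.Trajectory(t, 0.0001 * np.sin(t), np.zeros_like(t))
        m = sm.compute_trial_metrics(traj, training_spec, maze)
        assert not m.success
        assert m.visited_n <= 1
        assert m.ra_deg is None
        assert any("ra" in note for note in m.notes)

    def test_noiseless_egocentric_agent_training_trial(self, maze, training_spec):
        from starmaze.simulate import AgentConfig, AgentState, simulate_trial

        state = AgentState(AgentConfig(strategy="egocentric", path_jitter_sd=0.0,
                                       initial_error_prob=0.0))
        traj, _ = simulate_trial(state, training_spec, maze, np.random.default_rng(0))
        m = sm.compute_trial_metrics(traj, training_spec, maze)
        assert m.success and m.visited_n == 2

    def test_capture_truncation_ignores_post_reward_samples(self, maze, training_spec):
        ideal = sm.ideal_path(1, 3, maze)
        onward = np.vstack([ideal.polyline, [maze.vertices[2], maze.alley_end(5)]])
        traj = sample_ideal_trajectory(sm.IdealPath(1, 3, onward, 0.0, 0.0), speed_m_s=8.2)
        m = sm.compute_trial_metrics(traj, training_spec, maze)
        assert m.success
        assert m.visited_alleys == (1, 3)
        assert m.tpl_m == pytest.approx(246.0, abs=1e-6)
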