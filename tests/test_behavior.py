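"""Arena tracking and odor-localization metrics."""

import numpy as np
import pytest

from glomkit.behavior import apply_exclusion, localization_metrics, track_centroid
from glomkit.datatypes import ArenaGeometry, Trajectory
from glomkit.synthetic import generate_trajectory, render_arena_video


def straight_trajectory(arena, start_dist=31.0, speed=1.0, frame_rate=8.0,
                        duration=40.0):
    """Straight run toward the active inlet starting at odor onset (t=0)."""
    source = arena.active_inlet_position()
    center = np.asarray(arena.center)
    u = (center - source) / np.linalg.norm(center - source)
    start = source + start_dist * u
    times = np.arange(int(duration * frame_rate) + 1) / frame_rate
    toward = -u
    positions = start + np.minimum(times, start_dist / speed)[:, None] * speed * toward
    return Trajectory(times=times, positions=positions)


class TestTrackCentroid:
    def test_square_blob_centroid(self):
        frames = np.zeros((3, 220, 120))
        # 4x4 blob centred at pixel (99.5, 199.5) in units of 0.1 cm/px
        frames[:, 198:202, 98:102] = 1.0
        traj = track_centroid(frames, pixel_scale=0.1, frame_rate=8.0)
        np.testing.assert_allclose(traj.positions[:, 0], 9.95, atol=1e-6)
        np.testing.assert_allclose(traj.positions[:, 1], 19.95, atol=1e-6)

    def test_moving_blob_speed(self):
        n = 17
        frames = np.zeros((n, 40, 80))
        for i in range(n):
            frames[i, 18:22, 10 + i : 14 + i] = 1.0
        traj = track_centroid(frames, pixel_scale=0.1, frame_rate=8.0)
        # 1 px/frame at 8 Hz and 0.1 cm/px -> 0.8 cm/s
        speeds = np.linalg.norm(np.diff(traj.positions, axis=0), axis=1) * 8.0
        np.testing.assert_allclose(speeds, 0.8, atol=1e-6)

    def test_synthetic_video_mean_error_below_one_pixel(self):
        arena = ArenaGeometry(odor_onset=5.0)
        traj, _ = generate_trajectory(arena, pre_duration=5.0, approach_delay=1.0,
                                      speed=8.0, tortuosity=0.5, frame_rate=8.0,
                                      seed=13, post_duration=10.0)
        scale = 0.5
        frames = render_arena_video(traj, arena, pixel_scale=scale,
                                    noise_sd=0.02, seed=13)
        tracked = track_centroid(frames, pixel_scale=scale, frame_rate=8.0)
        err = np.linalg.norm(tracked.positions - traj.positions, axis=1)
        assert err.mean() < scale  # < 1 pixel in cm

    def test_empty_frame_interpolated(self):
        frames = np.zeros((3, 20, 20))
        frames[0, 5:8, 5:8] = 1.0
        frames[2, 9:12, 9:12] = 1.0
        traj = track_centroid(frames, pixel_scale=1.0, frame_rate=8.0)
        # middle frame interpolates between neighbours
        np.testing.assert_allclose(
            traj.positions[1], (traj.positions[0] + traj.positions[2]) / 2
        )


class TestLocalizationMetrics:
    def test_straight_run_geometry(self):
        arena = ArenaGeometry(odor_onset=0.0)
        traj = straight_trajectory(arena, start_dist=31.0, speed=1.0)
        m = localization_metrics(traj, arena)
        assert m.arrived
        assert m.latency == pytest.approx(30.0, abs=1 / 8.0)
        assert m.path_length == pytest.approx(30.0, abs=1 / 8.0)
        assert m.initial_distance == pytest.approx(31.0)

    def test_stationary_animal_never_arrives(self):
        arena = ArenaGeometry(odor_onset=0.0)
        source = arena.active_inlet_position()
        pos = source + np.array([30.0, 0.0])
        times = np.arange(80) / 8.0
        traj = Trajectory(times=times, positions=np.tile(pos, (80, 1)))
        m = localization_metrics(traj, arena)
        assert not m.arrived
        assert np.isnan(m.latency)

    def test_path_length_matches_brute_force_segment_sum(self, rng):
        arena = ArenaGeometry(odor_onset=2.0)
        traj, _ = generate_trajectory(arena, pre_duration=2.0, approach_delay=1.0,
                                      speed=8.0, tortuosity=0.7, frame_rate=8.0,
                                      seed=3, post_duration=60.0)
        m = localization_metrics(traj, arena)
        source = arena.active_inlet_position()
        dist = np.hypot(*(traj.positions - source).T)
        post = traj.times >= arena.odor_onset
        i_on = int(np.argmax(post))
        hits = np.flatnonzero(post & (dist <= arena.arrival_radius))
        i_arr = int(hits[0]) if hits.size else traj.times.size - 1
        brute = sum(
            float(np.linalg.norm(traj.positions[i + 1] - traj.positions[i]))
            for i in range(i_on, i_arr)
        )
        assert m.path_length == pytest.approx(brute)
        if hits.size:
            assert m.latency == pytest.approx(traj.times[i_arr] - arena.odor_onset)

    def test_recovers_generator_delay_and_travel_time(self):
        arena = ArenaGeometry(odor_onset=10.0)
        traj, gt = generate_trajectory(
            arena, pre_duration=10.0, approach_delay=3.0, speed=5.0,
            tortuosity=0.0, frame_rate=8.0, seed=8, post_duration=60.0,
        )
        m = localization_metrics(traj, arena)
        assert m.arrived
        d_at_approach = np.linalg.norm(
            traj.positions[int(round(gt.approach_onset * 8))] - gt.source_position
        )
        expected = (gt.approach_onset - arena.odor_onset) + (
            d_at_approach - arena.arrival_radius
        ) / gt.speed
        assert m.latency == pytest.approx(expected, abs=2 / 8.0)

    def test_rotation_invariance(self):
        arena = ArenaGeometry(odor_onset=0.0, center=(0.0, 0.0))
        traj = straight_trajectory(arena, start_dist=20.0, speed=2.0)
        m0 = localization_metrics(traj, arena)
        # rotate arena and trajectory together by 90 degrees -> inlet 1
        rot = np.array([[0.0, -1.0], [1.0, 0.0]])
        traj_r = Trajectory(times=traj.times, positions=traj.positions @ rot.T)
        arena_r = ArenaGeometry(odor_onset=0.0, center=(0.0, 0.0), active_inlet=1)
        m1 = localization_metrics(traj_r, arena_r)
        assert m1.latency == pytest.approx(m0.latency)
        assert m1.path_length == pytest.approx(m0.path_length)
        assert m1.initial_distance == pytest.approx(m0.initial_distance)

    def test_path_at_least_displacement(self):
        arena = ArenaGeometry(odor_onset=2.0)
        traj, _ = generate_trajectory(arena, pre_duration=2.0, approach_delay=2.0,
                                      speed=8.0, tortuosity=0.9, frame_rate=8.0,
                                      seed=17, post_duration=60.0)
        m = localization_metrics(traj, arena)
        if m.arrived:
            assert m.path_length >= m.initial_distance - arena.arrival_radius - 1e-6

    def test_trajectory_ending_before_onset_raises(self):
        arena = ArenaGeometry(odor_onset=100.0)
        traj = straight_trajectory(ArenaGeometry(odor_onset=0.0), duration=10.0)
        with pytest.raises(ValueError):
            localization_metrics(traj, arena)


class TestApplyExclusion:
    def _metrics(self, initial_distance):
        from glomkit.behavior import BehaviorMetrics

        return BehaviorMetrics(
            latency=10.0, path_length=50.0, initial_distance=initial_distance,
            mean_velocity_pre=5.0, mean_velocity_post=5.0, arrived=True,
        )

    def test_close_start_excluded_by_default_rule(self):
        m = apply_exclusion(self._metrics(5.0), "min_initial_distance", 10.0)
        assert m.excluded
        assert "5.00" in m.exclusion_reason

    def test_boundary_is_kept(self):
        m = apply_exclusion(self._metrics(10.0), "min_initial_distance", 10.0)
        assert not m.excluded

    def test_literal_rule_direction(self):
        m = apply_exclusion(self._metrics(15.0), "max_initial_distance", 10.0)
        assert m.excluded

    def test_disabled_rule_never_excludes(self):
        m = apply_exclusion(self._metrics(0.5), None)
        assert not m.excluded
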