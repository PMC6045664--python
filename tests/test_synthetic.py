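"""Generator contracts: determinism, bookkeeping and parameter recovery."""

import numpy as np
import pytest

from glomkit import imaging
from glomkit.datatypes import ArenaGeometry
from glomkit.synthetic import (
    SimImagingConfig,
    expected_window_amplitude,
    generate_movie,
    generate_traces,
    generate_trajectory,
    transient_waveform,
)


class TestGenerateTraces:
    def test_same_seed_bit_identical(self, small_config):
        t1, tr1, _ = generate_traces(small_config)
        t2, tr2, _ = generate_traces(small_config)
        np.testing.assert_array_equal(t1.dff, t2.dff)
        assert tr1.equals(tr2)

    def test_trial_count_bookkeeping(self, small_config):
        traces, trials, _ = generate_traces(small_config)
        expected = (
            small_config.n_odors * small_config.n_repeats
            + small_config.blank_trials
        )
        assert traces.n_trials == expected
        assert len(trials) == expected
        assert trials["is_blank"].sum() == small_config.blank_trials
        # every non-blank odor appears exactly n_repeats times
        counts = trials.loc[~trials["is_blank"], "odor_id"].value_counts()
        assert (counts == small_config.n_repeats).all()

    def test_trials_tile_timeline_without_overlap(self, small_config):
        _, trials, _ = generate_traces(small_config)
        s = trials.sort_values("onset")
        assert (s["offset"].to_numpy()[:-1] <= s["onset"].to_numpy()[1:]).all()

    def test_noiseless_trace_equals_closed_form(self):
        cfg = SimImagingConfig(
            n_glomeruli=1, n_odors=1, n_repeats=1, blank_trials=0,
            responder_fraction=1.0, fixed_amplitude=0.8, noise_sd=0.0, seed=3,
        )
        traces, trials, gt = generate_traces(cfg)
        t = np.arange(traces.dff.shape[2]) / cfg.frame_rate
        expected = transient_waveform(
            t, cfg.baseline_duration, 0.8, cfg.rise_interval, cfg.decay_tau
        )
        np.testing.assert_allclose(traces.dff[0, 0], expected)

    def test_blank_trials_average_to_zero(self):
        # Monte-Carlo over 100 seeds: blank-trial mean ~ N(0, sd/sqrt(frames))
        means = []
        for seed in range(100):
            cfg = SimImagingConfig(
                n_glomeruli=1, n_odors=1, n_repeats=1, blank_trials=1,
                noise_sd=0.05, seed=seed, inter_trial_gap=5.0,
            )
            traces, trials, _ = generate_traces(cfg)
            k = trials.index[trials["is_blank"]][0]
            means.append(traces.dff[0, k].mean())
        n_frames = traces.dff.shape[2]
        assert abs(np.mean(means)) < 4 * 0.05 / np.sqrt(n_frames * 100)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            SimImagingConfig(responder_fraction=1.5)
        with pytest.raises(ValueError):
            SimImagingConfig(odor_duration=0.0)


class TestGenerateMovie:
    def test_same_seed_bit_identical(self):
        cfg = SimImagingConfig(n_glomeruli=4, n_odors=2, n_repeats=2,
                               blank_trials=1, field_of_view=(64, 64),
                               inter_trial_gap=5.0, seed=9)
        m1, r1, _, _ = generate_movie(cfg)
        m2, r2, _, _ = generate_movie(cfg)
        np.testing.assert_array_equal(m1.frames, m2.frames)
        np.testing.assert_array_equal(r1.label_image, r2.label_image)

    def test_labels_contiguous_from_one(self):
        cfg = SimImagingConfig(n_glomeruli=6, n_odors=1, n_repeats=1,
                               blank_trials=0, field_of_view=(64, 64),
                               inter_trial_gap=5.0, seed=2)
        _, rois, _, _ = generate_movie(cfg)
        assert rois.roi_ids == list(range(1, 7))

    def test_noiseless_single_glomerulus_peaks_at_amplitude(self):
        cfg = SimImagingConfig(
            n_glomeruli=1, n_odors=1, n_repeats=1, blank_trials=0,
            responder_fraction=1.0, fixed_amplitude=0.5, noise_sd=0.0,
            bleach_tau=np.inf, field_of_view=(32, 32),
            rise_interval=2.5,  # peak lands exactly on a frame at 4 fps
            inter_trial_gap=5.0, seed=4,
        )
        movie, rois, trials, _ = generate_movie(cfg)
        traces = imaging.movie_to_traces(movie, rois, trials)
        assert traces.dff[0, 0].max() == pytest.approx(0.50, abs=1e-6)

    def test_field_too_small_raises(self):
        cfg = SimImagingConfig(n_glomeruli=40, field_of_view=(24, 24),
                               n_odors=1, n_repeats=1, blank_trials=0,
                               inter_trial_gap=5.0, seed=0)
        with pytest.raises(RuntimeError, match="field of view"):
            generate_movie(cfg)

    def test_pipeline_recovers_true_amplitudes(self):
        cfg = SimImagingConfig(
            n_glomeruli=5, n_odors=3, n_repeats=3, blank_trials=2,
            responder_fraction=0.5, noise_sd=0.01, bleach_tau=np.inf,
            field_of_view=(64, 64), inter_trial_gap=10.0, seed=11,
        )
        movie, rois, trials, gt = generate_movie(cfg)
        traces = imaging.movie_to_traces(movie, rois, trials)
        responses = imaging.build_response_table(traces, trials)
        expected = expected_window_amplitude(cfg, gt.true_amplitudes)
        pixels_per_roi = min(
            np.sum(rois.label_image == rid) for rid in rois.roi_ids
        )
        mae = np.abs(responses.amplitude - expected).mean()
        assert mae < 3 * cfg.noise_sd / np.sqrt(pixels_per_roi)

    def test_bleached_movie_recovery_after_correction(self):
        cfg = SimImagingConfig(
            n_glomeruli=3, n_odors=2, n_repeats=2, blank_trials=2,
            responder_fraction=1.0, fixed_amplitude=0.4, noise_sd=0.0,
            bleach_tau=200.0, field_of_view=(48, 48),
            inter_trial_gap=10.0, seed=5,
        )
        movie, rois, trials, gt = generate_movie(cfg)
        traces = imaging.movie_to_traces(
            movie, rois, trials, bleach_mode="blank_trials"
        )
        responses = imaging.build_response_table(traces, trials)
        expected = expected_window_amplitude(cfg, gt.true_amplitudes)
        np.testing.assert_allclose(responses.amplitude, expected, atol=0.02)


class TestGenerateTrajectory:
    def test_straight_run_arrives_after_30_seconds(self):
        arena = ArenaGeometry(odor_onset=0.0)
        source = arena.active_inlet_position()
        center = np.asarray(arena.center)
        u = (center - source) / np.linalg.norm(center - source)
        start = source + 31.0 * u
        traj, gt = generate_trajectory(
            arena, pre_duration=0.0, approach_delay=0.0, speed=1.0,
            tortuosity=0.0, frame_rate=8.0, seed=0, start=tuple(start),
            post_duration=40.0,
        )
        dist = np.hypot(*(traj.positions - source).T)
        t_arrive = traj.times[np.flatnonzero(dist <= 1.0)[0]]
        assert t_arrive == pytest.approx(30.0, abs=2 / 8.0)

    def test_positions_stay_inside_arena(self):
        arena = ArenaGeometry(odor_onset=60.0)
        traj, _ = generate_trajectory(
            arena, pre_duration=60.0, approach_delay=5.0, speed=10.0,
            tortuosity=0.8, frame_rate=8.0, seed=21,
        )
        d = np.hypot(*(traj.positions - np.asarray(arena.center)).T)
        assert (d <= arena.radius + 1e-9).all()

    def test_same_seed_identical(self):
        arena = ArenaGeometry(odor_onset=30.0)
        t1, _ = generate_trajectory(arena, 30.0, 2.0, 8.0, 0.5, 8.0, seed=6)
        t2, _ = generate_trajectory(arena, 30.0, 2.0, 8.0, 0.5, 8.0, seed=6)
        np.testing.assert_array_equal(t1.positions, t2.positions)
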