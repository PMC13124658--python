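"""Epoching, trial averaging, dF/F0 arithmetic and SPL-group pooling."""

import logging

import numpy as np
import pytest

from wideca.dff import (
    EpochGroup,
    average_condition,
    compute_dff,
    epoch,
    pool_spl_groups,
    roi_timecourse,
)
from wideca.errors import EmptyRoiError, InvalidParameterError
from wideca.imgio import FrameGeometry, MovieStack
from wideca.protocol import ScheduleSpec, TrialEvent, TrialSchedule


def _movie(n_frames: int, geom=None) -> MovieStack:
    geom = geom or FrameGeometry(width_px=4, height_px=3)
    # frame i has constant value i + 1 so epochs are easy to identify
    frames = np.arange(1, n_frames + 1, dtype=float)[:, None, None] * np.ones((geom.height_px, geom.width_px))
    return MovieStack(frames=frames, timestamps_s=np.arange(n_frames) * 0.05, geometry=geom)


def _schedule(onsets, spls):
    spec = ScheduleSpec(spl_min_db=min(spls), spl_max_db=max(spls),
                        spl_step_db=2.0 if len(set(spls)) > 1 else 1.0,
                        reps_per_level=max(1, len(onsets) // len(set(spls))))
    events = tuple(TrialEvent(trial_index=i, onset_time_s=t, spl_db=s)
                   for i, (t, s) in enumerate(zip(onsets, spls)))
    return TrialSchedule(spec=spec, events=events)


class TestEpoching:
    def test_onset_at_frame_start_uses_that_frame(self):
        movie = _movie(30)
        sched = _schedule([0.50], [60.0])  # exactly the start of frame index 10
        groups = epoch(movie, sched, n_post=4)
        g = groups[60.0]
        # post-frame 1 is frame 10 (value 11); pre-frames are 7, 8, 9 (values 8..10)
        np.testing.assert_array_equal(g.frames[0, :, 0, 0], [8, 9, 10, 11, 12, 13, 14])
        assert g.onset_offsets_s[0] == pytest.approx(0.0)

    def test_onset_just_after_frame_start_uses_next_frame(self):
        movie = _movie(30)
        sched = _schedule([0.501], [60.0])
        g = epoch(movie, sched, n_post=4)[60.0]
        np.testing.assert_array_equal(g.frames[0, :, 0, 0], [9, 10, 11, 12, 13, 14, 15])
        assert g.onset_offsets_s[0] == pytest.approx(0.049)

    def test_edge_trials_dropped_and_logged(self, caplog):
        movie = _movie(12)
        sched = _schedule([0.05, 0.35], [60.0, 60.0])  # first has no 3-frame baseline
        with caplog.at_level(logging.WARNING, logger="wideca.dff"):
            groups = epoch(movie, sched, n_post=4)
        assert groups[60.0].n_trials == 1
        assert "dropped 1 trial" in caplog.text

    def test_groups_keyed_by_exact_spl(self):
        movie = _movie(40)
        sched = _schedule([0.5, 0.9, 1.3], [60.0, 62.0, 60.0])
        groups = epoch(movie, sched, n_post=4)
        assert sorted(groups) == [60.0, 62.0]
        assert groups[60.0].n_trials == 2

    def test_n_post_below_four_rejected(self):
        with pytest.raises(InvalidParameterError):
            epoch(_movie(20), _schedule([0.5], [60.0]), n_post=3)


class TestAverageCondition:
    def test_idempotent_on_identical_epochs(self):
        block = np.ones((3, 7, 2, 2)) * 5.0
        g = EpochGroup(spl_db=60.0, frames=block, onset_offsets_s=np.zeros(3), n_pre=3)
        np.testing.assert_array_equal(average_condition(g), block[0])

    def test_mean_of_two(self):
        a = np.full((7, 2, 2), 1.0)
        g = EpochGroup(spl_db=60.0, frames=np.stack([a, a + 2]), onset_offsets_s=np.zeros(2), n_pre=3)
        np.testing.assert_array_equal(average_condition(g), a + 1)

    def test_empty_group_rejected(self):
        g = EpochGroup(spl_db=60.0, frames=np.empty((0, 7, 2, 2)), onset_offsets_s=np.empty(0), n_pre=3)
        with pytest.raises(InvalidParameterError):
            average_condition(g)

    def test_trial_averaging_suppresses_noise_at_clt_rate(self):
        rng = np.random.default_rng(7)
        baseline, sigma, n = 1000.0, 0.005, 80
        block = baseline * (1.0 + rng.normal(0, sigma, size=(n, 7, 14, 24)))
        g = EpochGroup(spl_db=60.0, frames=block, onset_offsets_s=np.zeros(n), n_pre=3)
        mean = average_condition(g)
        assert np.abs(mean - baseline).max() < 4 * sigma / np.sqrt(n) * baseline


class TestComputeDff:
    def test_headline_scale_example(self):
        # pre-frames at 100, one post frame at 101.2 -> 1.2 %
        epoch_mean = np.concatenate([np.full((3, 2, 2), 100.0), np.full((4, 2, 2), 101.2)])
        d = compute_dff(epoch_mean)
        assert d.dff[0, 0, 0] == pytest.approx(1.2)

    def test_constant_movie_is_zero(self):
        d = compute_dff(np.full((8, 3, 3), 42.0))
        np.testing.assert_allclose(d.dff, 0.0, atol=1e-12)
        np.testing.assert_allclose(d.pooled, 0.0, atol=1e-12)

    def test_hand_arithmetic_oracle(self):
        # pre 100/100/106 -> F0 = 102; post frames 2-4 = 104/103/102
        # pooled = 100 * ((104+103+102)/3 - 102) / 102 = 0.98039215...%
        shape = (1, 1)
        pre = [100.0, 100.0, 106.0]
        posts = [99.0, 104.0, 103.0, 102.0]  # post-frame 1 excluded from pooling
        epoch_mean = np.array(pre + posts).reshape(7, *shape)
        d = compute_dff(epoch_mean)
        np.testing.assert_allclose(d.f0, 102.0, atol=1e-12)
        assert d.pooled[0, 0] == pytest.approx(100.0 * (103.0 - 102.0) / 102.0, abs=1e-10)

    def test_zero_baseline_pixels_masked_and_counted(self):
        epoch_mean = np.full((7, 2, 2), 50.0)
        epoch_mean[:3, 0, 0] = 0.0
        d = compute_dff(epoch_mean)
        assert d.masked_pixels == 1
        assert np.isnan(d.dff[:, 0, 0]).all()
        assert np.isfinite(d.dff[:, 1, 1]).all()

    def test_gain_invariance(self):
        rng = np.random.default_rng(3)
        epoch_mean = 100.0 + rng.uniform(0, 5, size=(8, 4, 4))
        d1 = compute_dff(epoch_mean)
        d2 = compute_dff(epoch_mean * 7.3)
        np.testing.assert_allclose(d1.dff, d2.dff, atol=1e-10)

    def test_ratio_of_averages_not_average_of_ratios(self):
        # heteroscedastic trials: the two orders of operations disagree and
        # the pipeline must follow ratio-of-trial-averages
        rng = np.random.default_rng(11)
        n = 40
        base = 100.0 * rng.lognormal(0, 0.5, size=n)  # per-trial gain spread
        trials = np.stack([
            np.concatenate([np.full((3, 1, 1), b), np.full((4, 1, 1), b * (1 + 0.012))])
            for b in base
        ])
        mean_epoch = trials.mean(axis=0)
        pipeline = compute_dff(mean_epoch).dff[0, 0, 0]
        ratio_of_averages = 100.0 * (mean_epoch[3, 0, 0] - mean_epoch[:3, 0, 0].mean()) / mean_epoch[:3, 0, 0].mean()
        average_of_ratios = np.mean([compute_dff(t).dff[0, 0, 0] for t in trials])
        assert pipeline == pytest.approx(ratio_of_averages, abs=1e-12)
        # identical relative responses make the two orders agree; perturb
        # the response heterogeneously to split them
        trials[::2, 3:] *= 1.01
        mean_epoch = trials.mean(axis=0)
        pipeline = compute_dff(mean_epoch).dff[0, 0, 0]
        average_of_ratios = np.mean([compute_dff(t).dff[0, 0, 0] for t in trials])
        assert pipeline != pytest.approx(average_of_ratios, abs=1e-6)


class TestPoolSplGroups:
    @staticmethod
    def _maps(spls, value_fn):
        return [(s, np.full((2, 2), value_fn(s))) for s in spls]

    def test_default_grouping_labels(self):
        spls = np.arange(42.0, 92.0, 2.0)
        groups = pool_spl_groups(self._maps(spls, lambda s: s), group_size=5)
        assert [lbl for lbl, _ in groups] == [
            "42-50 dB", "52-60 dB", "62-70 dB", "72-80 dB", "82-90 dB"
        ]

    def test_identical_maps_unchanged(self):
        groups = pool_spl_groups(self._maps([42, 44, 46, 48, 50], lambda s: 7.0), group_size=5)
        np.testing.assert_array_equal(groups[0][1], 7.0)

    def test_linear_maps_average_to_central_level(self):
        spls = [42, 44, 46, 48, 50]
        groups = pool_spl_groups(self._maps(spls, lambda s: 3.0 * s + 1.0), group_size=5)
        np.testing.assert_allclose(groups[0][1], 3.0 * 46 + 1.0)

    def test_unsorted_input_rejected(self):
        with pytest.raises(InvalidParameterError):
            pool_spl_groups(self._maps([44, 42], lambda s: s), group_size=2)

    def test_remainder_requires_flag(self):
        maps = self._maps([42, 44, 46], lambda s: s)
        with pytest.raises(InvalidParameterError):
            pool_spl_groups(maps, group_size=2)
        groups = pool_spl_groups(maps, group_size=2, allow_remainder=True)
        assert [lbl for lbl, _ in groups] == ["42-44 dB", "46-46 dB"]


class TestRoiTimecourse:
    def test_uniform_and_single_pixel(self):
        movie = np.arange(24, dtype=float).reshape(4, 2, 3)
        mask = np.ones((2, 3), dtype=bool)
        np.testing.assert_allclose(roi_timecourse(movie, mask), movie.mean(axis=(1, 2)))
        single = np.zeros((2, 3), dtype=bool)
        single[1, 2] = True
        np.testing.assert_array_equal(roi_timecourse(movie, single), movie[:, 1, 2])

    def test_fully_masked_roi_rejected(self):
        movie = np.full((2, 2, 2), np.nan)
        mask = np.ones((2, 2), dtype=bool)
        with pytest.raises(EmptyRoiError):
            roi_timecourse(movie, mask)
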