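"""Forward-model components: kernel and its calibration, dose-response,
spatial fields, epoch rendering against closed-form oracles, and the dataset
writer."""

import json

import numpy as np
import pytest
from scipy.integrate import quad

from wideca.dff import average_condition, compute_dff, epoch, roi_timecourse
from wideca.errors import CalibrationError, InvalidParameterError
from wideca.imgio import FrameGeometry, RoiDef, rasterize_roi
from wideca.protocol import ScheduleSpec, TrialEvent, TrialSchedule
from wideca.synthetic import (
    NoiseModel,
    ResponseField,
    ResponseKernel,
    amplitude_at,
    calibrate_default_kernel,
    generate_dataset,
    half_decay_time,
    kernel_value,
    kernel_window_mean,
    render_epochs,
    spatial_profile,
)

from conftest import silent_noise, tiny_config, tiny_rois


class TestKernel:
    def test_silent_before_onset_latency(self, default_kernel):
        assert kernel_value(default_kernel, 0.0) == 0.0
        assert kernel_value(default_kernel, default_kernel.onset_latency_s) == 0.0

    def test_unit_peak_at_analytic_peak_time(self):
        k = ResponseKernel(onset_latency_s=0.02, tau_rise_s=0.03, tau_decay_s=0.2)
        assert kernel_value(k, k.peak_time_s) == pytest.approx(1.0, abs=1e-12)

    def test_default_kernel_kinetics(self, default_kernel):
        assert default_kernel.peak_time_s == pytest.approx(0.150, abs=1e-3)
        assert half_decay_time(default_kernel) == pytest.approx(0.150, abs=1e-3)

    def test_sampled_peak_falls_in_expected_frame(self, default_kernel):
        # on the 20 Hz grid the frame-averaged peak lies in the window
        # covering 100-150 ms or 150-200 ms post-onset
        starts = np.arange(8) * 0.05
        vals = kernel_window_mean(default_kernel, starts, starts + 0.05)
        peak_start = starts[int(np.argmax(vals))]
        assert np.isclose(peak_start, 0.10) or np.isclose(peak_start, 0.15)

    def test_calibration_round_trip_recovers_taus(self):
        k = ResponseKernel(onset_latency_s=0.05, tau_rise_s=0.025, tau_decay_s=0.18)
        k2 = calibrate_default_kernel(
            target_peak_time_s=k.peak_time_s,
            target_half_decay_s=half_decay_time(k),
            onset_latency_s=0.05,
        )
        assert k2.tau_rise_s == pytest.approx(k.tau_rise_s, abs=1e-3)
        assert k2.tau_decay_s == pytest.approx(k.tau_decay_s, abs=1e-3)

    def test_infeasible_targets_raise(self):
        with pytest.raises(CalibrationError):
            calibrate_default_kernel(onset_latency_s=0.2)  # latency >= peak
        # a difference-of-exponentials kernel cannot decay to half in less
        # than ~1.678x its peak delay: 100 ms peak delay forces >= 168 ms
        with pytest.raises(CalibrationError):
            calibrate_default_kernel(
                target_peak_time_s=0.150, target_half_decay_s=0.150, onset_latency_s=0.050
            )


class TestDoseResponse:
    FIELD = ResponseField(name="f", center_mm=(3.0, 2.0), sigma_mm=0.6,
                          a_max_dff=0.012, s50_db=58.0, slope_db=1.2)

    def test_midpoint_and_saturation(self):
        f = self.FIELD
        assert amplitude_at(f, f.s50_db) == pytest.approx(f.a_max_dff / 2)
        assert amplitude_at(f, f.s50_db + 10 * f.slope_db) == pytest.approx(f.a_max_dff, abs=1e-4 * f.a_max_dff)

    def test_plateau_above_68_db(self):
        # spec'd plateau behavior: the response saturates by ~68 dB
        f = self.FIELD
        assert amplitude_at(f, 80.0) - amplitude_at(f, 68.0) < 0.05 * f.a_max_dff

    def test_strictly_increasing(self):
        spls = np.arange(42.0, 92.0, 2.0)
        vals = amplitude_at(self.FIELD, spls)
        assert np.all(np.diff(vals) > 0)


class TestSpatialProfile:
    GEOM = FrameGeometry()

    def test_peak_at_center_pixel(self):
        w = spatial_profile(self.FIELD_AT(3.55, 2.0), self.GEOM)
        assert w.max() == 1.0

    def test_value_at_one_sigma(self):
        f = self.FIELD_AT(3.55, 2.0)
        w = spatial_profile(f, self.GEOM)
        xx, yy = self.GEOM.pixel_centers_mm()
        d = np.sqrt((xx - f.center_mm[0]) ** 2 + (yy - f.center_mm[1]) ** 2)
        j = np.unravel_index(np.argmin(np.abs(d - f.sigma_mm)), d.shape)
        assert w[j] == pytest.approx(np.exp(-0.5), abs=0.02)

    def test_mass_matches_gaussian_integral(self):
        f = ResponseField(name="f", center_mm=(3.55, 2.0), sigma_mm=0.3,
                          a_max_dff=0.01, s50_db=58, slope_db=1.2)
        w = spatial_profile(f, self.GEOM)
        expected = 2 * np.pi * f.sigma_mm**2 / (self.GEOM.pitch_x_mm * self.GEOM.pitch_y_mm)
        assert w.sum() == pytest.approx(expected, rel=0.01)

    @staticmethod
    def FIELD_AT(x, y):
        return ResponseField(name="f", center_mm=(x, y), sigma_mm=0.6,
                             a_max_dff=0.012, s50_db=58.0, slope_db=1.2)

    def test_center_outside_field_rejected(self):
        with pytest.raises(InvalidParameterError):
            spatial_profile(self.FIELD_AT(8.0, 2.0), self.GEOM)


def _grid_aligned_schedule(n_trials: int, spl: float, period_s: float = 0.05) -> TrialSchedule:
    """Onsets exactly on the frame grid, far enough apart not to overlap."""
    spec = ScheduleSpec(spl_min_db=spl, spl_max_db=spl, spl_step_db=1.0, reps_per_level=n_trials)
    events = tuple(
        TrialEvent(trial_index=i, onset_time_s=(10 + 20 * i) * period_s, spl_db=spl)
        for i in range(n_trials)
    )
    return TrialSchedule(spec=spec, events=events)


class TestRenderEpochs:
    def test_null_model_is_exactly_baseline(self, default_kernel):
        cfg = tiny_config(default_kernel, fields=())
        sched = _grid_aligned_schedule(3, 80.0)
        out = render_epochs(cfg, sched, 0)
        np.testing.assert_array_equal(out.frames, 1000.0)

    def test_causality_pre_frames_at_baseline(self, default_kernel):
        cfg = tiny_config(default_kernel)
        sched = _grid_aligned_schedule(3, 90.0)
        out = render_epochs(cfg, sched, 0)
        np.testing.assert_array_equal(out.frames[:, :3], 1000.0)
        assert np.all(out.frames[:, 3:] >= 1000.0)
        assert out.frames[:, 4:].max() > 1000.0

    def test_roi_mean_dff_matches_closed_form_oracle(self, default_kernel):
        # noise off, one field, onsets on the frame grid, saturating SPL:
        # the pipeline's peak-frame ROI dF/F0 equals
        # a(SPL) x frame-window kernel mean x ROI-mean spatial weight
        field = ResponseField(name="SRAF", center_mm=(3.3, 2.1), sigma_mm=0.6,
                              a_max_dff=0.012, s50_db=58.0, slope_db=1.2)
        cfg = tiny_config(default_kernel, fields=(field,))
        sched = _grid_aligned_schedule(2, 90.0)
        out = render_epochs(cfg, sched, 0)
        grouped = epoch(out, n_post=cfg.n_post)
        d = compute_dff(average_condition(grouped[90.0]), spl_db=90.0)
        mask = rasterize_roi(tiny_rois().get("SRAF"), cfg.geometry)
        trace = roi_timecourse(d.dff, mask)

        starts = np.arange(cfg.n_post) * 0.05
        kbar = kernel_window_mean(default_kernel, starts, starts + 0.05)
        amp = amplitude_at(field, 90.0)
        w_roi = spatial_profile(field, cfg.geometry)[mask].mean()
        oracle = 100.0 * amp * kbar.max() * w_roi
        assert trace.max() == pytest.approx(oracle, abs=1e-10)

    def test_frame_value_matches_quadrature_oracle(self, default_kernel):
        # frame-exposure averaging: analytic window integral vs numeric quadrature
        starts = np.array([0.0, 0.05, 0.085, 0.1, 0.2, 0.35])
        for a in starts:
            analytic = kernel_window_mean(default_kernel, a, a + 0.05)
            numeric, _ = quad(lambda t: kernel_value(default_kernel, t), a, a + 0.05,
                              limit=200, epsabs=1e-13, epsrel=1e-12)
            numeric /= 0.05
            assert analytic == pytest.approx(numeric, abs=2e-7 * max(1.0, numeric))

    def test_superposition_of_fields(self, default_kernel):
        f1 = ResponseField(name="a", center_mm=(2.5, 2.0), sigma_mm=0.5,
                           a_max_dff=0.01, s50_db=58, slope_db=1.2)
        f2 = ResponseField(name="b", center_mm=(4.5, 2.0), sigma_mm=0.5,
                           a_max_dff=0.02, s50_db=60, slope_db=2.0)
        sched = _grid_aligned_schedule(2, 80.0)
        both = render_epochs(tiny_config(default_kernel, fields=(f1, f2)), sched, 0).frames
        only1 = render_epochs(tiny_config(default_kernel, fields=(f1,)), sched, 0).frames
        only2 = render_epochs(tiny_config(default_kernel, fields=(f2,)), sched, 0).frames
        base = 1000.0
        np.testing.assert_allclose(both - base, (only1 - base) + (only2 - base), atol=1e-9)

    def test_pooled_response_monotone_in_spl_without_noise(self, default_kernel):
        # grid-aligned onsets so every condition shares the same frame-window
        # gain; the pooled ROI response must then follow the sigmoid exactly
        from wideca.workflow import analyze_subject

        cfg = tiny_config(default_kernel, spl_min=42.0, spl_max=90.0, reps=1)
        levels = cfg.schedule_spec.levels_db
        events = tuple(
            TrialEvent(trial_index=i, onset_time_s=(10 + 20 * i) * 0.05, spl_db=float(s))
            for i, s in enumerate(levels)
        )
        sched = TrialSchedule(spec=cfg.schedule_spec, events=events)
        out = render_epochs(cfg, sched, 0)
        grouped = epoch(out, n_post=cfg.n_post)
        analysis = analyze_subject(grouped, tiny_rois(), cfg.geometry)
        sraf = analysis.pooled[analysis.pooled.roi == "SRAF"].sort_values("spl_db")
        assert np.all(np.diff(sraf.value.to_numpy()) > 0)

    def test_fewer_than_three_pre_frames_rejected(self, default_kernel):
        from dataclasses import replace

        with pytest.raises(InvalidParameterError):
            replace(tiny_config(default_kernel), n_pre=2)


class TestGenerateDataset:
    def test_counts_and_determinism(self, tmp_path, default_kernel):
        cfg = tiny_config(
            default_kernel,
            noise=NoiseModel(baseline_level=1000.0, shot_noise_scale=0.002,
                             hemo_amplitude_dff=0.0005, artifact_amplitude_dff=0.001),
            n_subjects=2,
            reps=5,
            spl_min=70.0,
            spl_max=74.0,
            jitter=0.1,
        )
        out_a = generate_dataset(cfg, tmp_path / "a")
        out_b = generate_dataset(cfg, tmp_path / "b")
        for sub in range(2):
            events = (out_a / f"sub{sub:02d}_events.csv").read_text()
            assert events.count("\n") == 16  # header + 3 levels x 5 reps
            assert events == (out_b / f"sub{sub:02d}_events.csv").read_text()
            tif_a = (out_a / f"sub{sub:02d}_epochs.tif").read_bytes()
            tif_b = (out_b / f"sub{sub:02d}_epochs.tif").read_bytes()
            assert tif_a == tif_b
        truth_a = json.loads((out_a / "ground_truth.json").read_text())
        truth_b = json.loads((out_b / "ground_truth.json").read_text())
        assert truth_a == truth_b
        assert truth_a["config"]["n_subjects"] == 2

    def test_subject_schedules_differ(self, tmp_path, default_kernel):
        cfg = tiny_config(default_kernel, n_subjects=2, reps=5, spl_min=70.0, spl_max=74.0)
        out = generate_dataset(cfg, tmp_path / "d")
        a = (out / "sub00_events.csv").read_text()
        b = (out / "sub01_events.csv").read_text()
        assert a != b
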