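"""Forward simulation of transcranial widefield GCaMP movies of the auditory
cortex with known ground truth.

Model
-----
Each pixel of each frame is rendered as

    F = F0 * (1 + sum_fields a(SPL) * w(x, y) * kbar + hemo + artifact) * (1 + eps)

where ``a(SPL)`` is a logistic dose-response amplitude, ``w`` an isotropic
Gaussian spatial weight, ``kbar`` the indicator response kernel averaged over
the frame's exposure window (analytic integral of a difference of
exponentials), ``hemo`` a spatially uniform slow sinusoid with per-trial
random phase, ``artifact`` a sound-evoked but level-independent slow component
with a subject-specific smooth spatial pattern, and ``eps`` i.i.d. Gaussian
relative shot noise.  Epochs (3 pre-stimulus + 8 post-stimulus frames by
default) are rendered directly on the global 20 Hz frame grid, so stimulus
onsets fall at a uniformly distributed offset within the frame period exactly
as they do when epoching a continuous recording.

Calibration
-----------
The defaults are calibrated so that the measurement pipeline (ratio of
trial-averaged images to the 3-frame pre-stimulus baseline, pooling of the
2nd-4th post-stimulus frames, ROI averaging, n = 6 subjects) reproduces the
study-scale observables: a 1.2 % plateau dF/F0 at the most responsive field,
~150 ms time to peak and ~150 ms half-decay, a 56 dB detection threshold, and
first detectable response in the frame starting 50 ms after onset.  The
forward amplitude exceeds the measured plateau by the inverse of the
analytically computed measurement gain (frame-window kernel averaging x ROI
spatial averaging x subject-jitter mean); nothing is fitted to data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy import ndimage
from scipy.optimize import brentq

from .errors import CalibrationError, InvalidParameterError
from .imgio import FrameGeometry, MovieStack, RoiDef, RoiSet, write_events, write_stack
from .protocol import ScheduleSpec, TrialSchedule, build_schedule

__all__ = [
    "ResponseKernel",
    "ResponseField",
    "NoiseModel",
    "SimulationConfig",
    "SubjectEpochs",
    "kernel_value",
    "kernel_window_mean",
    "calibrate_default_kernel",
    "amplitude_at",
    "spatial_profile",
    "render_epochs",
    "generate_dataset",
    "default_response_fields",
    "default_roi_set",
    "default_simulation_config",
    "pooled_measurement_gain",
    "roi_spatial_gain",
    "sample_null_pooled_responses",
]


# ---------------------------------------------------------------------------
# Response kernel


@dataclass(frozen=True)
class ResponseKernel:
    """Indicator impulse response: silent until ``onset_latency_s``, then a
    difference of exponentials normalized to unit peak."""

    onset_latency_s: float
    tau_rise_s: float
    tau_decay_s: float

    def __post_init__(self) -> None:
        if self.onset_latency_s < 0:
            raise InvalidParameterError("onset_latency_s must be >= 0")
        if not (0 < self.tau_rise_s < self.tau_decay_s):
            raise InvalidParameterError("require 0 < tau_rise_s < tau_decay_s")

    @property
    def peak_delay_s(self) -> float:
        """Delay from response onset (not stimulus onset) to the peak."""
        tr, td = self.tau_rise_s, self.tau_decay_s
        return float(np.log(td / tr) * tr * td / (td - tr))

    @property
    def peak_time_s(self) -> float:
        """Time of the continuous-time peak, from stimulus onset."""
        return self.onset_latency_s + self.peak_delay_s

    @property
    def _norm(self) -> float:
        u = self.peak_delay_s
        return 1.0 / (np.exp(-u / self.tau_decay_s) - np.exp(-u / self.tau_rise_s))


def kernel_value(kernel: ResponseKernel, t_s):
    """Kernel value at time(s) ``t_s`` from stimulus onset; in [0, 1]."""
    t = np.asarray(t_s, dtype=float)
    u = t - kernel.onset_latency_s
    with np.errstate(over="ignore"):
        v = kernel._norm * (np.exp(-np.maximum(u, 0.0) / kernel.tau_decay_s)
                            - np.exp(-np.maximum(u, 0.0) / kernel.tau_rise_s))
    out = np.where(u > 0, v, 0.0)
    return out if out.ndim else float(out)


def _kernel_integral(kernel: ResponseKernel, u) -> np.ndarray:
    """Antiderivative of the kernel in response time u (= t - latency), 0 at u=0."""
    u = np.maximum(np.asarray(u, dtype=float), 0.0)
    tr, td = kernel.tau_rise_s, kernel.tau_decay_s
    return kernel._norm * (td * (1.0 - np.exp(-u / td)) - tr * (1.0 - np.exp(-u / tr)))


def kernel_window_mean(kernel: ResponseKernel, t_start_s, t_end_s):
    """Mean kernel value over the exposure window [t_start_s, t_end_s]
    (times from stimulus onset), computed from the analytic integral."""
    a = np.asarray(t_start_s, dtype=float) - kernel.onset_latency_s
    b = np.asarray(t_end_s, dtype=float) - kernel.onset_latency_s
    width = b - a
    out = (_kernel_integral(kernel, b) - _kernel_integral(kernel, a)) / width
    return out if out.ndim else float(out)


def half_decay_time(kernel: ResponseKernel) -> float:
    """Time for the continuous kernel to fall from its peak to half, seconds."""
    u_star = kernel.peak_delay_s
    f = lambda u: kernel_value(kernel, kernel.onset_latency_s + u) - 0.5
    hi = u_star + 60 * kernel.tau_decay_s
    return float(brentq(f, u_star, hi, xtol=1e-12)) - u_star


def calibrate_default_kernel(
    target_peak_time_s: float = 0.150,
    target_half_decay_s: float = 0.150,
    onset_latency_s: float = 0.100,
    tol_s: float = 1e-3,
) -> ResponseKernel:
    """Solve for (tau_rise, tau_decay) such that the kernel peaks at
    ``target_peak_time_s`` after stimulus onset and falls to half its peak
    ``target_half_decay_s`` later, both within ``tol_s``.

    The family is parameterized by the tau ratio rho = tau_decay/tau_rise;
    for a fixed peak delay u* the half-decay grows monotonically with rho
    from ~1.678 u* (the alpha-function limit), so a 1-D bracketed root-find
    suffices.  Raises :class:`CalibrationError` when no solution exists in
    the admissible region (e.g. half-decay targets below 1.678 u*).
    """
    if target_peak_time_s <= 0 or target_half_decay_s <= 0:
        raise CalibrationError("targets must be positive")
    if onset_latency_s >= target_peak_time_s:
        raise CalibrationError("onset_latency_s must be smaller than target_peak_time_s")
    u_star = target_peak_time_s - onset_latency_s

    def kernel_of(rho: float) -> ResponseKernel:
        tr = u_star * (rho - 1.0) / (rho * np.log(rho))
        return ResponseKernel(onset_latency_s=onset_latency_s, tau_rise_s=tr, tau_decay_s=rho * tr)

    def half_of(rho: float) -> float:
        return half_decay_time(kernel_of(rho))

    lo, hi = 1.0 + 1e-6, 1e6
    s_lo, s_hi = half_of(lo), half_of(hi)
    if not (s_lo - tol_s <= target_half_decay_s <= s_hi):
        raise CalibrationError(
            f"no kernel with peak delay {u_star * 1e3:.1f} ms reaches half-decay "
            f"{target_half_decay_s * 1e3:.1f} ms (admissible range >= {s_lo * 1e3:.1f} ms)"
        )
    rho = brentq(lambda r: half_of(r) - target_half_decay_s, lo, hi, xtol=1e-10)
    kernel = kernel_of(rho)
    if abs(kernel.peak_time_s - target_peak_time_s) > tol_s or abs(
        half_decay_time(kernel) - target_half_decay_s
    ) > tol_s:
        raise CalibrationError("calibration did not converge to the requested tolerance")
    return kernel


# ---------------------------------------------------------------------------
# Spatial response fields and dose-response


@dataclass(frozen=True)
class ResponseField:
    """A spatially localized responsive cortical field with logistic
    (sigmoidal) SPL dependence of its peak fractional fluorescence change."""

    name: str
    center_mm: tuple[float, float]
    sigma_mm: float
    a_max_dff: float
    s50_db: float
    slope_db: float

    def __post_init__(self) -> None:
        if self.sigma_mm <= 0:
            raise InvalidParameterError("sigma_mm must be positive")
        if self.a_max_dff < 0:
            raise InvalidParameterError("a_max_dff must be >= 0")
        if self.slope_db <= 0:
            raise InvalidParameterError("slope_db must be positive")


def amplitude_at(field: ResponseField, spl_db) -> np.ndarray | float:
    """Logistic dose-response amplitude at the given SPL(s), dimensionless
    fractional change; strictly increasing, saturating at ``a_max_dff``."""
    s = np.asarray(spl_db, dtype=float)
    out = field.a_max_dff / (1.0 + np.exp(-(s - field.s50_db) / field.slope_db))
    return out if out.ndim else float(out)


def spatial_profile(field: ResponseField, geometry: FrameGeometry) -> np.ndarray:
    """Isotropic Gaussian weight map on pixel centers, renormalized so the
    pixel nearest the field center has weight exactly 1."""
    cx, cy = field.center_mm
    if not (0 <= cx <= geometry.field_width_mm and 0 <= cy <= geometry.field_height_mm):
        raise InvalidParameterError(f"field {field.name!r} center {field.center_mm} lies outside the imaging field")
    xx, yy = geometry.pixel_centers_mm()
    d2 = (xx - cx) ** 2 + (yy - cy) ** 2
    w = np.exp(-d2 / (2.0 * field.sigma_mm**2))
    return w / w.max()


# ---------------------------------------------------------------------------
# Noise model


@dataclass(frozen=True)
class NoiseModel:
    """Baseline fluorescence and the three nuisance components.

    baseline_level
        Mean baseline fluorescence per pixel, camera counts.
    shot_noise_scale
        Std of i.i.d. relative (multiplicative) frame noise per pixel.
    hemo_amplitude_dff / hemo_freq_hz / hemo_phase_jitter
        Spatially uniform slow sinusoid (vasomotion-like); the phase is drawn
        per trial uniformly from ``[-jitter, +jitter]`` so that averaging many
        randomized-ISI trials cancels it.
    artifact_amplitude_dff / artifact_corr_mm / artifact_ramp_s
        Sound-evoked, SPL-independent slow component: each subject carries a
        fixed zero-mean smooth spatial pattern (Gaussian random field with the
        given correlation length and pixel-level std) that ramps up linearly
        over ``artifact_ramp_s`` after every stimulus.  It does not average
        out across trials and is the dominant source of between-subject
        variability at sub-threshold SPLs.
    """

    baseline_level: float = 8000.0
    shot_noise_scale: float = 0.005
    hemo_amplitude_dff: float = 0.001
    hemo_freq_hz: float = 0.3
    hemo_phase_jitter: float = float(np.pi)
    artifact_amplitude_dff: float = 0.0015
    artifact_corr_mm: float = 0.8
    artifact_ramp_s: float = 0.3

    def __post_init__(self) -> None:
        if self.baseline_level <= 0:
            raise InvalidParameterError("baseline_level must be positive")
        for name in ("shot_noise_scale", "hemo_amplitude_dff", "hemo_freq_hz",
                     "hemo_phase_jitter", "artifact_amplitude_dff"):
            if getattr(self, name) < 0:
                raise InvalidParameterError(f"{name} must be >= 0")

    def is_silent(self) -> bool:
        return self.shot_noise_scale == 0 and self.hemo_amplitude_dff == 0 and self.artifact_amplitude_dff == 0


@dataclass(frozen=True)
class SimulationConfig:
    geometry: FrameGeometry
    fields: tuple[ResponseField, ...]
    kernel: ResponseKernel
    noise: NoiseModel
    schedule_spec: ScheduleSpec
    n_subjects: int = 6
    rng_seed: int = 0
    n_pre: int = 3
    n_post: int = 8
    subject_jitter_sigma: float = 0.1

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise InvalidParameterError("n_subjects must be >= 1")
        if self.n_pre < 3:
            raise InvalidParameterError("n_pre must be >= 3 (the baseline uses 3 pre-stimulus frames)")
        if self.n_post < 4:
            raise InvalidParameterError("n_post must be >= 4 (pooling uses post frames 2-4)")
        for f in self.fields:
            cx, cy = f.center_mm
            if not (0 <= cx <= self.geometry.field_width_mm and 0 <= cy <= self.geometry.field_height_mm):
                raise InvalidParameterError(f"field {f.name!r} center lies outside the imaging field")

    def to_dict(self) -> dict:
        return {
            "geometry": self.geometry.to_dict(),
            "fields": [
                {
                    "name": f.name,
                    "center_mm": [float(c) for c in f.center_mm],
                    "sigma_mm": float(f.sigma_mm),
                    "a_max_dff": float(f.a_max_dff),
                    "s50_db": float(f.s50_db),
                    "slope_db": float(f.slope_db),
                }
                for f in self.fields
            ],
            "kernel": {
                "onset_latency_s": float(self.kernel.onset_latency_s),
                "tau_rise_s": float(self.kernel.tau_rise_s),
                "tau_decay_s": float(self.kernel.tau_decay_s),
            },
            "noise": {
                "baseline_level": self.noise.baseline_level,
                "shot_noise_scale": self.noise.shot_noise_scale,
                "hemo_amplitude_dff": self.noise.hemo_amplitude_dff,
                "hemo_freq_hz": self.noise.hemo_freq_hz,
                "hemo_phase_jitter": self.noise.hemo_phase_jitter,
                "artifact_amplitude_dff": self.noise.artifact_amplitude_dff,
                "artifact_corr_mm": self.noise.artifact_corr_mm,
                "artifact_ramp_s": self.noise.artifact_ramp_s,
            },
            "schedule_spec": {
                "spl_min_db": self.schedule_spec.spl_min_db,
                "spl_max_db": self.schedule_spec.spl_max_db,
                "spl_step_db": self.schedule_spec.spl_step_db,
                "reps_per_level": self.schedule_spec.reps_per_level,
                "isi_min_s": self.schedule_spec.isi_min_s,
                "isi_max_s": self.schedule_spec.isi_max_s,
                "rng_seed": self.schedule_spec.rng_seed,
            },
            "n_subjects": self.n_subjects,
            "rng_seed": self.rng_seed,
            "n_pre": self.n_pre,
            "n_post": self.n_post,
            "subject_jitter_sigma": self.subject_jitter_sigma,
        }


# ---------------------------------------------------------------------------
# Per-subject deterministic randomness

_STREAM_SCHEDULE, _STREAM_JITTER, _STREAM_ARTIFACT, _STREAM_TRIALS = range(4)


def _subject_seedseq(config: SimulationConfig, subject_index: int, stream: int) -> np.random.SeedSequence:
    return np.random.SeedSequence(entropy=config.rng_seed, spawn_key=(subject_index, stream))


def subject_schedule(config: SimulationConfig, subject_index: int, stimulus_duration_s: float = 0.05) -> TrialSchedule:
    """The (seeded) randomized schedule presented to one subject."""
    if not 0 <= subject_index < config.n_subjects:
        raise InvalidParameterError("subject_index out of range")
    seed = int(np.random.default_rng(_subject_seedseq(config, subject_index, _STREAM_SCHEDULE)).integers(2**31))
    spec = replace(config.schedule_spec, rng_seed=seed)
    return build_schedule(spec, stimulus_duration_s=stimulus_duration_s)


def subject_amplitude_factor(config: SimulationConfig, subject_index: int) -> float:
    """Multiplicative lognormal response-amplitude jitter for one subject."""
    rng = np.random.default_rng(_subject_seedseq(config, subject_index, _STREAM_JITTER))
    return float(rng.lognormal(mean=0.0, sigma=config.subject_jitter_sigma))


def subject_artifact_map(config: SimulationConfig, subject_index: int) -> np.ndarray:
    """Zero-mean smooth spatial pattern of the evoked artifact, pixel std
    equal to ``artifact_amplitude_dff``."""
    g = config.geometry
    noise = config.noise
    if noise.artifact_amplitude_dff == 0:
        return np.zeros((g.height_px, g.width_px))
    rng = np.random.default_rng(_subject_seedseq(config, subject_index, _STREAM_ARTIFACT))
    white = rng.standard_normal((g.height_px, g.width_px))
    sig = (noise.artifact_corr_mm / g.pitch_y_mm, noise.artifact_corr_mm / g.pitch_x_mm)
    smooth = ndimage.gaussian_filter(white, sigma=sig, mode="wrap")
    smooth -= smooth.mean()
    sd = smooth.std()
    if sd == 0:
        return np.zeros_like(smooth)
    return smooth * (noise.artifact_amplitude_dff / sd)


def _ramp_window_mean(t_start, t_end, ramp_s: float) -> np.ndarray:
    """Mean of g(u) = clip(u / ramp_s, 0, 1) over [t_start, t_end] (times from
    stimulus onset), via the analytic antiderivative."""
    def G(u):  # integral of g from 0 to u, for u >= 0
        u = np.maximum(np.asarray(u, dtype=float), 0.0)
        return np.where(u <= ramp_s, u**2 / (2 * ramp_s), ramp_s / 2 + (u - ramp_s))

    a = np.asarray(t_start, dtype=float)
    b = np.asarray(t_end, dtype=float)
    return (G(b) - G(a)) / (b - a)


# ---------------------------------------------------------------------------
# Epoch rendering


@dataclass
class SubjectEpochs:
    """Per-trial epoch stacks for one subject.

    ``frames`` has shape (n_trials, n_pre + n_post, height, width); frame f of
    trial t starts at ``frame_times_s[t, f]`` (absolute recording time).
    ``onset_offsets_s`` records the alignment of each stimulus onset within
    post-frame 1 (the first frame starting at or after the onset).
    """

    frames: np.ndarray
    spls_db: np.ndarray
    onsets_s: np.ndarray
    frame_times_s: np.ndarray
    onset_offsets_s: np.ndarray
    n_pre: int
    n_post: int
    geometry: FrameGeometry
    subject_index: int = 0

    @property
    def n_trials(self) -> int:
        return len(self.frames)


def render_epochs(config: SimulationConfig, schedule: TrialSchedule, subject_index: int) -> SubjectEpochs:
    """Render all epochs of one subject on the global frame grid.

    Post-frame 1 is the first frame whose start time is at or after the
    stimulus onset; because ISIs are continuous, the onset offset within the
    frame period is uniformly distributed.  The response term uses the
    analytic frame-exposure average of the kernel, so with zero noise the
    rendered values match continuous-time quadrature to floating precision.
    """
    g = config.geometry
    n_pre, n_post = config.n_pre, config.n_post
    n_frames = n_pre + n_post
    T = g.frame_period_s
    onsets = schedule.onsets_s
    spls = schedule.spls_db
    n_trials = len(onsets)
    if n_trials == 0:
        raise InvalidParameterError("schedule has no trials")

    first_post_idx = np.ceil(onsets / T - 1e-12).astype(int)
    if np.any(first_post_idx - n_pre < 0):
        raise InvalidParameterError("first trial too close to recording start for the pre-stimulus baseline")
    frame_idx = first_post_idx[:, None] + np.arange(-n_pre, n_post)[None, :]
    frame_starts = frame_idx * T  # absolute, (n_trials, n_frames)
    deltas = first_post_idx * T - onsets  # in [0, T)

    # response term: shared kernel window means x per-trial field amplitudes
    rel_start = frame_starts - onsets[:, None]
    kbar = kernel_window_mean(config.kernel, rel_start, rel_start + T)  # (n_trials, n_frames)
    jitter = subject_amplitude_factor(config, subject_index)
    # combined spatial response per trial: sum_f a_f(spl) * w_f(x,y)
    combined = np.zeros((n_trials, g.height_px, g.width_px))
    for f in config.fields:
        a = np.asarray(amplitude_at(f, spls)) * jitter
        combined += a[:, None, None] * spatial_profile(f, g)[None, :, :]

    trial_rng = np.random.default_rng(_subject_seedseq(config, subject_index, _STREAM_TRIALS))
    noise = config.noise

    phases = trial_rng.uniform(-noise.hemo_phase_jitter, noise.hemo_phase_jitter, size=n_trials)
    hemo = noise.hemo_amplitude_dff * np.sin(
        2 * np.pi * noise.hemo_freq_hz * frame_starts + phases[:, None]
    ) if noise.hemo_amplitude_dff > 0 else np.zeros_like(frame_starts)

    art_map = subject_artifact_map(config, subject_index)
    art_time = _ramp_window_mean(rel_start, rel_start + T, noise.artifact_ramp_s)

    out = np.empty((n_trials, n_frames, g.height_px, g.width_px))
    base = noise.baseline_level
    use_artifact = noise.artifact_amplitude_dff > 0
    for t in range(n_trials):
        sig = kbar[t][:, None, None] * combined[t][None, :, :]
        frame = 1.0 + sig + hemo[t][:, None, None]
        if use_artifact:
            frame = frame + art_time[t][:, None, None] * art_map[None, :, :]
        out[t] = base * frame
    if noise.shot_noise_scale > 0:
        out *= 1.0 + trial_rng.normal(0.0, noise.shot_noise_scale, size=out.shape)

    return SubjectEpochs(
        frames=out,
        spls_db=spls.copy(),
        onsets_s=onsets.copy(),
        frame_times_s=frame_starts,
        onset_offsets_s=deltas,
        n_pre=n_pre,
        n_post=n_post,
        geometry=g,
        subject_index=subject_index,
    )


# ---------------------------------------------------------------------------
# Calibrated defaults

_MEASURED_PLATEAU_DFF = 0.012  # pipeline-measured plateau fractional change at the most responsive field
_DEFAULT_ROI_RADIUS_MM = 0.25
_DEFAULT_SIGMA_MM = 0.6
_DEFAULT_S50_DB = 58.0
_DEFAULT_SLOPE_DB = 1.2
# centers chosen to keep the fields and background ROI well separated on the
# 7.1 x 4.0 mm field (x: anterior->posterior, y: dorsal->ventral)
_DEFAULT_CENTERS = {"SRAF": (3.3, 2.1), "PAF": (4.9, 1.3), "VAF": (2.3, 3.0)}
_BACKGROUND_CENTER = (6.4, 0.7)
_REGIONAL_SCALE = {"SRAF": 1.0, "PAF": 0.6, "VAF": 0.5}


def pooled_measurement_gain(
    kernel: ResponseKernel,
    frame_rate_hz: float = 20.0,
    pooled_frames: tuple[int, ...] = (2, 3, 4),
    n_offsets: int = 512,
) -> float:
    """Expected pooled-frame kernel amplitude seen by the pipeline.

    Averages the frame-exposure-window kernel mean over the pooled
    post-stimulus frames and over the uniform onset offset within the frame
    period.  This is the factor by which frame integration attenuates the
    unit-peak kernel in the pooled dF/F0 measure.
    """
    T = 1.0 / frame_rate_hz
    deltas = (np.arange(n_offsets) + 0.5) * T / n_offsets
    total = 0.0
    for f in pooled_frames:
        starts = (f - 1) * T + deltas
        total += kernel_window_mean(kernel, starts, starts + T).mean()
    return float(total / len(pooled_frames))


def roi_spatial_gain(sigma_mm: float, roi_radius_mm: float = _DEFAULT_ROI_RADIUS_MM) -> float:
    """Mean Gaussian field weight over a concentric circular ROI (closed form)."""
    x = roi_radius_mm**2 / (2.0 * sigma_mm**2)
    return float((1.0 - np.exp(-x)) / x)


def default_response_fields(
    measured_plateau_dff: float = _MEASURED_PLATEAU_DFF,
    kernel: ResponseKernel | None = None,
    frame_rate_hz: float = 20.0,
    subject_jitter_sigma: float = 0.1,
) -> tuple[ResponseField, ...]:
    """The paper-scale field model: SRAF (most responsive), PAF, VAF.

    The forward amplitude is the measured plateau divided by the analytic
    measurement gain so that the full pipeline recovers
    ``measured_plateau_dff`` at the SRAF ROI.
    """
    kernel = kernel or calibrate_default_kernel()
    gain = (
        pooled_measurement_gain(kernel, frame_rate_hz)
        * roi_spatial_gain(_DEFAULT_SIGMA_MM)
        * float(np.exp(subject_jitter_sigma**2 / 2))
    )
    a_max = measured_plateau_dff / gain
    return tuple(
        ResponseField(
            name=name,
            center_mm=_DEFAULT_CENTERS[name],
            sigma_mm=_DEFAULT_SIGMA_MM,
            a_max_dff=a_max * _REGIONAL_SCALE[name],
            s50_db=_DEFAULT_S50_DB,
            slope_db=_DEFAULT_SLOPE_DB,
        )
        for name in ("SRAF", "PAF", "VAF")
    )


def default_roi_set(radius_mm: float = _DEFAULT_ROI_RADIUS_MM) -> RoiSet:
    """ROI1-ROI4: one ROI at each field center plus a background ROI."""
    entries = [RoiDef(name=n, center_mm=c, radius_mm=radius_mm) for n, c in _DEFAULT_CENTERS.items()]
    entries.append(RoiDef(name="Back", center_mm=_BACKGROUND_CENTER, radius_mm=radius_mm))
    return RoiSet(entries=tuple(entries))


def default_simulation_config(
    rng_seed: int = 0,
    n_subjects: int = 6,
    reps_per_level: int = 80,
    geometry: FrameGeometry | None = None,
    noise: NoiseModel | None = None,
) -> SimulationConfig:
    """The study-condition configuration with all calibrated defaults."""
    geometry = geometry or FrameGeometry()
    noise = noise if noise is not None else NoiseModel()
    kernel = calibrate_default_kernel()
    return SimulationConfig(
        geometry=geometry,
        fields=default_response_fields(kernel=kernel, frame_rate_hz=geometry.frame_rate_hz),
        kernel=kernel,
        noise=noise,
        schedule_spec=ScheduleSpec(reps_per_level=reps_per_level, rng_seed=rng_seed),
        n_subjects=n_subjects,
        rng_seed=rng_seed,
    )


def reduced_geometry() -> FrameGeometry:
    """Half-resolution geometry (120 x 68 px) covering the same field."""
    return FrameGeometry(width_px=120, height_px=68)


# ---------------------------------------------------------------------------
# Dataset writer


def generate_dataset(config: SimulationConfig, out_dir) -> Path:
    """Render the full dataset to disk: per-subject event logs and epoch
    TIFFs plus a ground-truth record of every parameter.

    Regenerating with the same config is bit-identical.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for s in range(config.n_subjects):
        schedule = subject_schedule(config, s)
        write_events(schedule, out / f"sub{s:02d}_events.csv")
        epochs = render_epochs(config, schedule, s)
        n_trials, n_frames = epochs.frames.shape[:2]
        flat = epochs.frames.reshape(n_trials * n_frames, *epochs.frames.shape[2:])
        stack = MovieStack(
            frames=flat,
            timestamps_s=epochs.frame_times_s.reshape(-1),
            geometry=config.geometry,
        )
        write_stack(
            stack,
            out / f"sub{s:02d}_epochs.tif",
            dtype="uint16",
            extra_metadata={
                "n_pre": config.n_pre,
                "n_post": config.n_post,
                "n_trials": int(n_trials),
                "subject_index": s,
                "subject_amplitude_factor": subject_amplitude_factor(config, s),
            },
        )
    truth = {
        "config": config.to_dict(),
        "derived": {
            "kernel_peak_time_s": config.kernel.peak_time_s,
            "kernel_half_decay_s": half_decay_time(config.kernel),
            "pooled_measurement_gain": pooled_measurement_gain(config.kernel, config.geometry.frame_rate_hz),
            "subject_amplitude_factors": [
                subject_amplitude_factor(config, s) for s in range(config.n_subjects)
            ],
        },
    }
    (out / "ground_truth.json").write_text(json.dumps(truth, sort_keys=True, indent=1) + "\n")
    return out


# ---------------------------------------------------------------------------
# Curve-level null sampler (for statistical calibration checks)


def sample_null_pooled_responses(
    n_subjects: int,
    n_levels: int,
    rng: np.random.Generator,
    noise: NoiseModel | None = None,
    roi_pixels: int = 56,
    trials_per_level: int = 20,
    pooled_frames: int = 3,
    artifact_retention: float = 1.0,
    ramp_gain: float = 0.5,
) -> np.ndarray:
    """Per-subject pooled ROI responses (percent) for a stimulus-free ROI.

    Curve-level reduction of the movie noise model: a per-subject artifact
    offset (constant across levels) plus independent shot noise per level.
    Used to check type-I error calibration of the inference chain without
    rendering thousands of movies.
    """
    noise = noise or NoiseModel()
    shot_sd = 100.0 * noise.shot_noise_scale * np.sqrt(
        1.0 / (roi_pixels * trials_per_level * pooled_frames) + 1.0 / (roi_pixels * trials_per_level * 3)
    )
    offset_sd = 100.0 * noise.artifact_amplitude_dff * artifact_retention * ramp_gain
    offsets = rng.normal(0.0, offset_sd, size=(n_subjects, 1))
    return offsets + rng.normal(0.0, shot_sd, size=(n_subjects, n_levels))
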