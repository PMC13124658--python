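"""Auditory stimulation protocol: click-shaped band-noise envelope and the
randomized multi-intensity trial schedule.

The stimulus is a band-limited (1.25-40 kHz) noise burst shaped by a click
envelope: a 12.5 microsecond linear rise to peak followed by an exponential
decay with a 3 ms half-life, truncated at 50 ms total duration.  Peak sound
pressure levels span 42-90 dB SPL in 2 dB steps; each level is presented many
times in fully interleaved random order with inter-sound (silent) intervals
drawn uniformly from 250-1750 ms.  SPL is carried as a label throughout the
package; no physical amplitude calibration is attempted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidParameterError

__all__ = [
    "ClickStimulus",
    "ScheduleSpec",
    "TrialEvent",
    "TrialSchedule",
    "click_envelope_value",
    "make_click_envelope",
    "make_band_noise_click",
    "build_schedule",
]


@dataclass(frozen=True)
class ClickStimulus:
    """Parameters of the click-shaped band-noise stimulus.

    Defaults reproduce the protocol used throughout the package: 12.5 us
    linear rise, 3 ms exponential half-life, 50 ms hard truncation,
    1.25-40 kHz band at a 384 kHz audio rate.
    """

    rise_time_s: float = 12.5e-6
    decay_half_life_s: float = 3e-3
    duration_s: float = 0.05
    band_low_hz: float = 1250.0
    band_high_hz: float = 40000.0
    audio_rate_hz: float = 384000.0

    def __post_init__(self) -> None:
        if self.rise_time_s <= 0 or self.duration_s <= 0 or self.audio_rate_hz <= 0:
            raise InvalidParameterError("rise_time_s, duration_s and audio_rate_hz must be positive")
        if self.rise_time_s >= self.duration_s:
            raise InvalidParameterError("rise_time_s must be shorter than duration_s")
        if self.decay_half_life_s <= 0:
            raise InvalidParameterError("decay_half_life_s must be positive")
        if not (0 < self.band_low_hz < self.band_high_hz):
            raise InvalidParameterError("band edges must satisfy 0 < band_low_hz < band_high_hz")
        if self.audio_rate_hz < 2 * self.band_high_hz:
            raise InvalidParameterError("audio_rate_hz must be at least twice band_high_hz (Nyquist)")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration_s * self.audio_rate_hz))


@dataclass(frozen=True)
class ScheduleSpec:
    """Randomized multi-intensity trial schedule parameters."""

    spl_min_db: float = 42.0
    spl_max_db: float = 90.0
    spl_step_db: float = 2.0
    reps_per_level: int = 80
    isi_min_s: float = 0.25
    isi_max_s: float = 1.75
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.spl_step_db <= 0:
            raise InvalidParameterError("spl_step_db must be positive")
        span = self.spl_max_db - self.spl_min_db
        n = span / self.spl_step_db
        if span < 0 or abs(n - round(n)) > 1e-9:
            raise InvalidParameterError("(spl_max_db - spl_min_db) must be a non-negative multiple of spl_step_db")
        if self.reps_per_level < 1:
            raise InvalidParameterError("reps_per_level must be >= 1")
        if not (0 < self.isi_min_s <= self.isi_max_s):
            raise InvalidParameterError("require 0 < isi_min_s <= isi_max_s")

    @property
    def levels_db(self) -> np.ndarray:
        n = int(round((self.spl_max_db - self.spl_min_db) / self.spl_step_db)) + 1
        return self.spl_min_db + self.spl_step_db * np.arange(n)

    @property
    def n_trials(self) -> int:
        return len(self.levels_db) * self.reps_per_level


@dataclass(frozen=True)
class TrialEvent:
    trial_index: int
    onset_time_s: float
    spl_db: float


@dataclass(frozen=True)
class TrialSchedule:
    """The full randomized stimulus sequence driving simulation and epoching."""

    spec: ScheduleSpec
    events: tuple[TrialEvent, ...]
    stimulus_duration_s: float = 0.05

    @property
    def onsets_s(self) -> np.ndarray:
        return np.array([e.onset_time_s for e in self.events])

    @property
    def spls_db(self) -> np.ndarray:
        return np.array([e.spl_db for e in self.events])

    @property
    def total_duration_s(self) -> float:
        if not self.events:
            return 0.0
        return self.events[-1].onset_time_s + self.stimulus_duration_s

    def __len__(self) -> int:
        return len(self.events)


def click_envelope_value(stim: ClickStimulus, t_s):
    """Continuous-time click envelope, peak-normalized to 1.

    Linear 0->1 rise over ``rise_time_s``, then ``2**(-(t-rise)/half_life)``,
    exactly 0 at and after ``duration_s`` (and before 0).
    """
    t = np.asarray(t_s, dtype=float)
    rise = np.clip(t / stim.rise_time_s, 0.0, 1.0)
    decay = np.power(2.0, -(np.maximum(t - stim.rise_time_s, 0.0)) / stim.decay_half_life_s)
    out = np.where(t < stim.rise_time_s, rise, decay)
    out = np.where((t < 0) | (t >= stim.duration_s), 0.0, out)
    return out if out.ndim else float(out)


def make_click_envelope(stim: ClickStimulus) -> np.ndarray:
    """Sample the click envelope on the stimulus audio grid.

    Returns ``round(duration_s * audio_rate_hz)`` samples at times
    ``k / audio_rate_hz``.
    """
    t = np.arange(stim.n_samples) / stim.audio_rate_hz
    return click_envelope_value(stim, t)


def make_band_noise_click(stim: ClickStimulus, rng_seed: int) -> np.ndarray:
    """White noise band-limited to [band_low_hz, band_high_hz], multiplied by
    the click envelope, peak absolute amplitude scaled to 1.

    Band limiting uses an ideal (brick-wall) spectral mask, which is zero
    phase and keeps out-of-band power at numerical-noise level.
    """
    if not (0 < stim.band_low_hz < stim.band_high_hz < stim.audio_rate_hz / 2):
        raise InvalidParameterError("band edges must lie strictly inside (0, audio_rate_hz / 2)")
    rng = np.random.default_rng(rng_seed)
    white = rng.standard_normal(stim.n_samples)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(stim.n_samples, d=1.0 / stim.audio_rate_hz)
    spec[(freqs < stim.band_low_hz) | (freqs > stim.band_high_hz)] = 0.0
    noise = np.fft.irfft(spec, n=stim.n_samples)
    out = noise * make_click_envelope(stim)
    peak = np.max(np.abs(out))
    if peak > 0:
        out = out / peak
    return out


def band_limited_noise(stim: ClickStimulus, rng_seed: int) -> np.ndarray:
    """The pre-envelope band-limited noise (for spectral inspection)."""
    if not (0 < stim.band_low_hz < stim.band_high_hz < stim.audio_rate_hz / 2):
        raise InvalidParameterError("band edges must lie strictly inside (0, audio_rate_hz / 2)")
    rng = np.random.default_rng(rng_seed)
    white = rng.standard_normal(stim.n_samples)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(stim.n_samples, d=1.0 / stim.audio_rate_hz)
    spec[(freqs < stim.band_low_hz) | (freqs > stim.band_high_hz)] = 0.0
    return np.fft.irfft(spec, n=stim.n_samples)


def build_schedule(spec: ScheduleSpec, stimulus_duration_s: float = 0.05) -> TrialSchedule:
    """Build the fully interleaved randomized trial schedule.

    Every SPL level appears exactly ``reps_per_level`` times in a uniformly
    random order; silent inter-sound intervals (offset to next onset) are
    i.i.d. uniform on ``[isi_min_s, isi_max_s]``, including a lead-in interval
    before the first trial.  The presentation order and the ISI draws come
    from two independent child streams of ``rng_seed`` so either is
    reproducible in isolation.
    """
    order_ss, isi_ss = np.random.SeedSequence(spec.rng_seed).spawn(2)
    order_rng = np.random.default_rng(order_ss)
    isi_rng = np.random.default_rng(isi_ss)

    levels = np.repeat(spec.levels_db, spec.reps_per_level)
    order = order_rng.permutation(len(levels))
    spls = levels[order]

    isis = isi_rng.uniform(spec.isi_min_s, spec.isi_max_s, size=len(spls))
    onsets = np.cumsum(isis + stimulus_duration_s) - stimulus_duration_s

    events = tuple(
        TrialEvent(trial_index=i, onset_time_s=float(onsets[i]), spl_db=float(spls[i]))
        for i in range(len(spls))
    )
    return TrialSchedule(spec=spec, events=events, stimulus_duration_s=stimulus_duration_s)
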