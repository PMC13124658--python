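# Methods

This note documents the measurement model, the synthetic forward model and
its calibration, the numerical choices, and the limits of what the passing
tests demonstrate.

## Measurement pipeline

**Epoching.** Post-stimulus frame 1 is the first frame whose start time is at
or after the stimulus onset; the three frames immediately before it form the
baseline. Because inter-stimulus intervals are continuous (uniform on
250–1750 ms plus the 50 ms stimulus), onsets are not locked to the 20 Hz
frame grid: the onset offset within the frame period is uniform on [0, 50) ms.
Trials whose window falls outside the recording are dropped and counted,
never padded.

**ΔF/F₀.** Images are averaged across the trials of a condition *first*; the
ratio is taken on the trial-mean images against the mean of the three
pre-stimulus frames (F₀). This ratio-of-averages order matters: on
heteroscedastic data it differs from averaging per-trial ratios, and a
property test pins the pipeline to the former. Pixels with non-positive
baseline are masked to NaN and counted. ΔF/F₀ is reported in percent
everywhere.

**Pooling.** The evoked-response map is the arithmetic mean of post-stimulus
frames 2–4 (the 50–100, 100–150 and 150–200 ms windows); frame 1 (0–50 ms)
is excluded. For display-style group maps, pooled maps of five neighboring
SPL levels are averaged (42–50, 52–60, 62–70, 72–80, 82–90 dB).

**Inference.** All comparisons are paired two-sided t-tests of a target ROI
against the background ROI across subjects, written against the closed-form
definitions (t = mean(d)/(sd(d)/√n), df = n−1) so they are oracle-testable;
Holm's step-down adjustment is the max-accumulated `(m−j+1)·p₍ⱼ₎` rule.
Threshold search uses uncorrected planned tests by default (both modes are
exposed); Holm families are never mixed across quantities (SPL levels for
dose–response, post-stimulus frames for time courses, ROI pairs for regional
comparisons). Identical paired samples raise a degenerate-data error in the
primitive; the screening routines map that case to p = 1 (no difference) or
p = 0 (exact non-zero constant shift), which only arises on synthetic input.

**Kinetics.** Time-to-peak is the frame-window midpoint of the maximum
post-stimulus sample — the only convention under which "approximately
150 ms" is well-defined on a 50 ms grid. Half-decay is the first
linear-interpolated crossing of half the peak after the peak, minus the peak
time; traces that never fall below half are reported censored at the window
end. The earliest-response criterion (the first post-stimulus frame
exceeding 3× the pre-stimulus SD of the trace) is a documented, configurable
choice; the frame-wise paired-t/Holm table provides the inference-based
alternative and both agree on the default simulation.

## Synthetic forward model

Each epoch pixel is rendered as
`F = F₀·(1 + Σ a(SPL)·w(x,y)·k̄ + hemo + artifact)·(1 + ε)`:

- **Indicator kernel** — difference of exponentials, silent for a 100 ms
  onset latency, unit continuous-time peak. The frame value uses the
  *analytic integral* of the kernel over the 50 ms exposure window, so
  noise-free renders match continuous-time quadrature to ≤ 1e-6 relative
  error. The latency is 100 ms rather than something shorter for two reasons
  that the data constrain jointly: (i) a difference-of-exponentials kernel
  cannot decay to half its peak in less than ≈1.678× its peak delay (the
  α-function limit), so a 150 ms time-to-peak with a 150 ms half-decay
  requires a peak delay of at most ~89 ms — with 100 ms latency the
  calibration (τ_rise ≈ 20.0 ms, τ_decay ≈ 185.9 ms) hits both targets
  exactly; (ii) with unlocked onsets, any latency shorter than one frame
  period leaks signal into post-frame 1 in proportion to the onset offset,
  which would make the frame starting at 0 ms "detectable" — with 100 ms
  latency post-frame 1 carries exactly zero signal for every offset and the
  frame starting at 50 ms is the earliest that can respond, which is
  precisely the observable a 20 Hz camera reports.
- **Dose–response** — logistic in SPL per field, midpoint 58 dB, scale
  1.2 dB. Three Gaussian fields (σ = 0.6 mm) model the suprarhinal (SRAF,
  most responsive), posterior (PAF, 0.6×) and ventral (VAF, 0.5×) auditory
  fields; a background ROI sits away from all three.
- **Forward amplitude** — the 1.2 % plateau is a *measured* quantity, not a
  forward parameter: frame-exposure averaging plus pooling windows that
  straddle the response onset attenuate the unit kernel to 0.692 (expected
  over the uniform onset offset), and the ROI-mean of the Gaussian field
  contributes 0.958. The forward peak amplitude is therefore
  1.2 % / (0.692 × 0.958 × 1.005) ≈ 1.80 %, computed analytically at
  config-construction time (`analysis/01_calibrate_model.py` reproduces the
  derivation); nothing is fitted to simulation output.
- **Noise.** (i) Gaussian relative shot noise, σ = 0.5 % per pixel per frame
  (Gaussian rather than Poisson because only trial-averaged quantities
  matter); (ii) a spatially uniform hemodynamic sinusoid (0.1 % ΔF/F₀,
  0.3 Hz) with per-trial random phase, which averages out over randomized
  trials — exactly the protocol's rationale for 80 repetitions; (iii) a
  sound-evoked but level-independent artifact: each subject owns a fixed
  zero-mean smooth spatial pattern (Gaussian random field, 0.8 mm
  correlation length, 0.15 % pixel SD) that ramps up linearly over 0.3 s
  after every stimulus. Unlike (i) and (ii) it does *not* vanish under trial
  averaging; it is what gives the across-subject SE bars a realistic
  ~0.05 % scale at sub-threshold SPLs, makes sub-threshold significance
  tests strongly correlated across levels (as they are when each animal
  carries its own stable artifact map), and is the reason the analysis
  compares ROIs against a background ROI with paired statistics at all.
  Per-subject response amplitudes are additionally jittered by a lognormal
  factor (σ = 0.1).
- **Rendering.** Epochs are rendered directly on the global frame grid
  (3 pre + 8 post frames) instead of materializing a ~35-minute continuous
  movie, and are mutually independent: cross-trial response bleed (the
  previous response is still ~50 % of peak at the shortest 300 ms
  onset-to-onset gap, ~10 % at the mean ~1.05 s gap, which in a continuous
  recording would slightly raise the next trial's baseline and shrink its
  measured ΔF/F₀ by a few percent of itself) is deliberately not emulated —
  it would rescale, not distort, every recovered quantity. Datasets are
  written as
  16-bit TIFF (baseline 8000 counts, so quantization is 0.004 % ΔF/F₀ —
  negligible against all noise terms) with timestamps and geometry in a JSON
  ImageDescription tag.

### Calibration of the dose–response operating point

With only shot noise, a paired n = 6 test would detect effects of ~0.02 %
ΔF/F₀ and place the threshold near 48 dB for any plausible sigmoid, and the
seven sub-56 dB levels would each carry an independent 5 % false-positive
chance (≥26 % familywise). The artifact component fixes both: the detection
limit becomes ~0.08 % and sub-threshold tests share the per-subject offsets.
A curve-level scan (2000 replicates per point, `analysis/01`) over the
sigmoid midpoint then shows a 56 dB median detected threshold with ~90 % of
replicates within one 2 dB step for s50 = 57–58 dB at slope 1.2 dB; the
defaults are frozen at s50 = 58 dB.

## What the recovery experiments show — and what they do not

The recovery suite (ten seeds × six subjects, 120 × 68 px, 20 trials/level;
~3 min total, chosen so the whole suite stays interactive) demonstrates that
the pipeline recovers from raw frames: the 1.2 % plateau (median ~1.26 %,
the +0.05 upward nudge being the max-over-25-levels selection bias), the
56 dB threshold (median 56, typically 8/10 seeds within one step; the
occasional low-threshold seed is an artifact-offset draw large enough to
make the whole sub-threshold range significant — visible in real data too),
time-to-peak 125 ms and half-decay ~170 ms (the 50 ms grid quantizes the
true 150/150 ms kernel: the sampled peak sits in the 100–150 ms frame whose
midpoint is 125 ms, and measuring decay from a reduced sampled peak adds
~+20 ms — both within half a frame), and the earliest significant frame at
50 ms.

The generator does **not** emulate: baseline fluorescence heterogeneity
(anatomy), optical PSF/skull scattering beyond the Gaussian field widths,
photobleaching, motion, cross-trial response bleed, or Poisson photon
statistics. Passing recovery therefore validates the *analysis chain* under
the stated noise phenomenology, not robustness to every acquisition
pathology.

## Numerical choices and degenerate inputs

- Kernel calibration is a bracketed 1-D root-find in the τ-ratio (half-decay
  is monotone in it for fixed peak delay); infeasible targets raise a
  calibration error rather than returning a nearest fit.
- The frame at an onset falling exactly on a frame start is post-frame 1
  (ties break toward the earlier frame); a 1e-12-relative guard absorbs
  floating-point onset/period roundoff.
- ROI rasterization takes pixels whose *centers* lie within the circle;
  a fully off-grid ROI is an error, not an empty mean.
- `pool_spl_groups` refuses remainder groups unless explicitly allowed;
  group labels carry the SPL range.
- Envelope times are exact in closed form (linear 12.5 µs rise — the shape
  is unstated upstream of the analysis and ≤5 samples at 384 kHz — then
  2^(−t/3 ms), hard-truncated at 50 ms); band-limiting uses a zero-phase
  brick-wall spectral mask.
- Single-subject curves report SE = 0 with an explicit flag; zero-variance
  paired differences are an error in the statistical primitive and a
  resolved case (p ∈ {0, 1}) in the screening routines.
- All randomness derives from named `SeedSequence` streams
  (subject × {schedule, amplitude, artifact, trials}), so any sub-stream is
  reproducible in isolation and datasets are bit-identical across runs.
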