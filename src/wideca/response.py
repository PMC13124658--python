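"""From ROI time courses to the headline quantities: dose-response curves,
detection threshold, peak response, response kinetics, and frame-wise
significance.

Statistical conventions
-----------------------
All comparisons are paired (within-subject) two-sided t-tests of a target ROI
against the background ROI.  The threshold search uses uncorrected planned
tests by default, with Holm step-down available; the Holm family for a
time-course comparison is the set of post-stimulus frames and for a
dose-response the set of tested SPL levels — families are never mixed.
Peak times are reported at frame-window midpoints, which is what makes
"approximately 150 ms" well-defined on a 50 ms frame grid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DegenerateDataError, InvalidParameterError
from .stats import ComparisonResult, holm_adjust, mean_se, paired_t


def _paired_or_degenerate(xs, ys, label: str = "", alpha: float = 0.05) -> ComparisonResult:
    """Paired t-test that resolves zero-variance differences instead of
    erroring: identical samples carry no evidence (p = 1), while a constant
    non-zero shift is unambiguous (p = 0).  Used by the screening routines
    where degenerate cells are legitimate inputs (e.g. simulated nulls)."""
    try:
        return paired_t(xs, ys, label=label, alpha=alpha)
    except DegenerateDataError:
        d = float(np.mean(np.asarray(xs, dtype=float) - np.asarray(ys, dtype=float)))
        p = 1.0 if d == 0.0 else 0.0
        t = 0.0 if d == 0.0 else float(np.inf if d > 0 else -np.inf)
        return ComparisonResult(label=label, t_statistic=t, degrees_of_freedom=len(xs) - 1,
                                p_raw=p, p_adjusted=p, significant=bool(p < alpha))

__all__ = [
    "ResponseCurve",
    "KineticsEstimate",
    "ThresholdResult",
    "build_response_curve",
    "detect_threshold",
    "peak_response",
    "estimate_kinetics",
    "timepoint_significance",
    "regional_comparison",
]


@dataclass(frozen=True)
class ResponseCurve:
    """Per-ROI mean dF/F0 (percent) versus SPL across subjects, with SE."""

    roi: str
    spl_db: np.ndarray
    mean: np.ndarray
    se: np.ndarray
    n_subjects: int
    single_subject: bool = False

    def __post_init__(self) -> None:
        if np.any(np.diff(self.spl_db) <= 0):
            raise InvalidParameterError("SPL levels must be strictly ascending")
        if np.any(self.se < 0) or self.n_subjects < 1:
            raise InvalidParameterError("SE must be >= 0 and n_subjects >= 1")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"spl_db": self.spl_db, "roi": self.roi, "dff_percent": self.mean, "se": self.se,
             "n": self.n_subjects}
        )


@dataclass(frozen=True)
class KineticsEstimate:
    """Onset, time-to-peak and half-decay of an ROI time course (ms).

    ``half_decay_censored`` flags a trace that never falls to half its peak
    within the analysis window (the estimate is then the window-end bound).
    ``earliest_response_ms`` is None when no frame exceeds the criterion.
    """

    earliest_response_ms: float | None
    time_to_peak_ms: float
    half_decay_ms: float
    half_decay_censored: bool
    peak_value: float


@dataclass(frozen=True)
class ThresholdResult:
    """Minimum SPL with a significant target-vs-background response."""

    roi: str
    threshold_spl_db: float | None
    table: pd.DataFrame  # spl_db, t, p_raw, p_adjusted, significant
    alpha: float
    correction: str


def build_response_curve(per_subject: pd.DataFrame, roi: str) -> ResponseCurve:
    """Across-subject mean and SE of pooled ROI responses per SPL.

    ``per_subject`` needs columns ``subject``, ``spl_db``, ``value``; every
    subject must supply a value for every SPL (missing cells are listed in
    the error).  SE is the sample standard deviation over subjects / sqrt(n);
    a single subject yields SE = 0 with ``single_subject=True``.
    """
    required = {"subject", "spl_db", "value"}
    if not required.issubset(per_subject.columns):
        raise InvalidParameterError(f"per_subject must have columns {sorted(required)}")
    pivot = per_subject.pivot_table(index="subject", columns="spl_db", values="value")
    if pivot.isna().any().any():
        missing = [
            f"subject {s} @ {c} dB" for s, c in zip(*np.where(pivot.isna().values))
        ]
        raise InvalidParameterError("missing subject/SPL cells: " + ", ".join(
            f"subject {pivot.index[i]} @ {pivot.columns[j]} dB" for i, j in zip(*np.where(pivot.isna().values))
        ))
    stats = [mean_se(pivot[c].to_numpy()) for c in pivot.columns]
    return ResponseCurve(
        roi=roi,
        spl_db=np.asarray(pivot.columns, dtype=float),
        mean=np.array([s.mean for s in stats]),
        se=np.array([s.se for s in stats]),
        n_subjects=len(pivot),
        single_subject=len(pivot) == 1,
    )


def detect_threshold(
    target: np.ndarray,
    background: np.ndarray,
    spl_db: np.ndarray,
    alpha: float = 0.05,
    correction: str = "none",
    roi: str = "",
) -> ThresholdResult:
    """Lowest SPL whose paired target-vs-background test is significant.

    ``target`` and ``background`` are (n_subjects, n_levels) per-subject
    pooled responses over identical SPL levels.  With ``correction='holm'``
    the family is the set of tested levels and the adjusted p decides.
    Returns threshold None when no level reaches significance.
    """
    target = np.asarray(target, dtype=float)
    background = np.asarray(background, dtype=float)
    spl_db = np.asarray(spl_db, dtype=float)
    if target.shape != background.shape or target.ndim != 2 or target.shape[1] != len(spl_db):
        raise InvalidParameterError("target/background must be (n_subjects, n_levels) over identical levels")
    if target.shape[0] < 2:
        raise InvalidParameterError("threshold detection needs n >= 2 subjects for a variance estimate")
    if correction not in ("none", "holm"):
        raise InvalidParameterError("correction must be 'none' or 'holm'")
    results = [_paired_or_degenerate(target[:, j], background[:, j], label=f"{spl_db[j]:g} dB", alpha=alpha)
               for j in range(len(spl_db))]
    p_raw = np.array([r.p_raw for r in results])
    p_adj = holm_adjust(p_raw) if correction == "holm" else p_raw.copy()
    significant = p_adj < alpha
    table = pd.DataFrame(
        {
            "spl_db": spl_db,
            "t": [r.t_statistic for r in results],
            "p_raw": p_raw,
            "p_adjusted": p_adj,
            "significant": significant,
        }
    )
    threshold = float(spl_db[np.argmax(significant)]) if significant.any() else None
    return ThresholdResult(roi=roi, threshold_spl_db=threshold, table=table, alpha=alpha, correction=correction)


def peak_response(curve: ResponseCurve) -> tuple[float, float]:
    """(SPL, mean dF/F0) of the maximum of the curve; ties break toward the
    lowest SPL."""
    if len(curve.mean) == 0:
        raise InvalidParameterError("empty response curve")
    i = int(np.argmax(curve.mean))  # argmax returns the first maximum
    return float(curve.spl_db[i]), float(curve.mean[i])


def estimate_kinetics(
    frame_start_times_s: np.ndarray,
    trace: np.ndarray,
    onset_time_s: float = 0.0,
    criterion_sd: float = 3.0,
) -> KineticsEstimate:
    """Kinetics of an ROI dF/F0 time course sampled on the frame grid.

    ``frame_start_times_s`` are the start times of the frames (relative to
    the recording or to the onset, as long as ``onset_time_s`` matches);
    frames starting before ``onset_time_s`` are the pre-stimulus baseline.

    * time-to-peak: time of the maximum post-stimulus sample, reported at
      the frame-window midpoint, relative to onset;
    * half-decay: first time after the peak at which the linear
      interpolation between samples crosses half the peak, minus the peak
      time; censored at the window end when the trace never falls below;
    * earliest response: start time of the first post-stimulus frame whose
      value exceeds ``criterion_sd`` times the pre-stimulus SD of the trace
      (a documented, configurable detection criterion).
    """
    times = np.asarray(frame_start_times_s, dtype=float)
    trace = np.asarray(trace, dtype=float)
    if times.shape != trace.shape or times.ndim != 1 or len(times) < 2:
        raise InvalidParameterError("need matching 1-D frame times and trace with >= 2 samples")
    T = float(np.median(np.diff(times)))
    pre = times < onset_time_s - 1e-12
    post = ~pre
    if post.sum() < 3:
        raise InvalidParameterError("trace must cover the peak and >= 2 post-peak frames")
    post_times = times[post]
    post_vals = trace[post]
    mid = post_times + T / 2.0 - onset_time_s

    i_peak = int(np.argmax(post_vals))
    peak_val = float(post_vals[i_peak])
    time_to_peak_ms = 1e3 * float(mid[i_peak])

    half = peak_val / 2.0
    half_decay_ms = None
    censored = False
    after = post_vals[i_peak:]
    after_mid = mid[i_peak:]
    below = np.where(after[1:] < half)[0] + 1
    if len(below) == 0:
        half_decay_ms = 1e3 * float(after_mid[-1] - mid[i_peak])
        censored = True
    else:
        j = below[0]  # first sample below half; interpolate from the previous one
        frac = (after[j - 1] - half) / (after[j - 1] - after[j])
        t_cross = after_mid[j - 1] + frac * (after_mid[j] - after_mid[j - 1])
        half_decay_ms = 1e3 * float(t_cross - mid[i_peak])

    earliest = None
    if pre.sum() >= 2:
        pre_sd = float(np.std(trace[pre], ddof=1))
        crit = criterion_sd * pre_sd
        hits = np.where(post_vals > crit)[0]
        if len(hits):
            earliest = 1e3 * float(post_times[hits[0]] - onset_time_s)

    return KineticsEstimate(
        earliest_response_ms=earliest,
        time_to_peak_ms=time_to_peak_ms,
        half_decay_ms=half_decay_ms,
        half_decay_censored=censored,
        peak_value=peak_val,
    )


def timepoint_significance(
    target_traces: np.ndarray,
    background_traces: np.ndarray,
    frame_start_times_s: np.ndarray,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Paired t-test per post-stimulus frame with Holm adjustment over the
    frame family.

    ``target_traces`` / ``background_traces`` are (n_subjects, n_frames)
    time-aligned post-stimulus ROI traces.  Returns a frame-indexed table
    with raw p, Holm-adjusted p and significance flags.
    """
    target = np.asarray(target_traces, dtype=float)
    background = np.asarray(background_traces, dtype=float)
    times = np.asarray(frame_start_times_s, dtype=float)
    if target.shape != background.shape or target.ndim != 2 or target.shape[1] != len(times):
        raise InvalidParameterError("traces must be (n_subjects, n_frames) aligned with frame times")
    if target.shape[0] < 2:
        raise InvalidParameterError("timepoint significance needs n >= 2 subjects")
    results = [_paired_or_degenerate(target[:, j], background[:, j], alpha=alpha) for j in range(target.shape[1])]
    p_raw = np.array([r.p_raw for r in results])
    p_adj = holm_adjust(p_raw)
    return pd.DataFrame(
        {
            "frame_start_ms": 1e3 * times,
            "t": [r.t_statistic for r in results],
            "p_raw": p_raw,
            "p_adjusted": p_adj,
            "significant": p_adj < alpha,
        }
    )


def regional_comparison(
    responses: dict[str, np.ndarray],
    background: str = "Back",
    reference: str = "SRAF",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Regional differences at one SPL: every ROI vs the background ROI, and
    every non-reference ROI vs the reference, each family Holm-adjusted
    separately."""
    for needed in (background, reference):
        if needed not in responses:
            raise InvalidParameterError(f"responses must include the {needed!r} ROI")
    rows = []
    vs_back = [r for r in responses if r != background]
    res_back = [paired_t(responses[r], responses[background], label=f"{r} vs {background}") for r in vs_back]
    adj_back = holm_adjust([r.p_raw for r in res_back])
    for roi, r, p in zip(vs_back, res_back, adj_back):
        rows.append({"comparison": r.label, "family": "vs_background", "t": r.t_statistic,
                     "p_raw": r.p_raw, "p_adjusted": p, "significant": p < alpha})
    vs_ref = [r for r in responses if r not in (background, reference)]
    res_ref = [paired_t(responses[r], responses[reference], label=f"{r} vs {reference}") for r in vs_ref]
    adj_ref = holm_adjust([r.p_raw for r in res_ref])
    for roi, r, p in zip(vs_ref, res_ref, adj_ref):
        rows.append({"comparison": r.label, "family": "vs_reference", "t": r.t_statistic,
                     "p_raw": r.p_raw, "p_adjusted": p, "significant": p < alpha})
    return pd.DataFrame(rows)
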