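"""End-to-end study orchestration: simulate subjects, run the dF/F0 pipeline,
and assemble dose-response curves, thresholds and kinetics.

This is the layer the CLI, the analysis drivers and the acceptance checks all
share, so that every reported number flows through the same code path.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dff import CondDff, EpochGroup, average_condition, compute_dff, epoch, roi_timecourse
from .errors import InvalidParameterError
from .imgio import RoiSet, rasterize_roi
from .response import (
    KineticsEstimate,
    ResponseCurve,
    ThresholdResult,
    build_response_curve,
    detect_threshold,
    estimate_kinetics,
    timepoint_significance,
)
from .synthetic import SimulationConfig, SubjectEpochs, render_epochs, subject_schedule

__all__ = [
    "SubjectAnalysis",
    "StudyResult",
    "analyze_subject",
    "simulate_subject",
    "run_study",
    "DEFAULT_PLATEAU_BAND_DB",
]

DEFAULT_PLATEAU_BAND_DB = (70.0, 90.0)  # conditions pooled for the kinetics time course


@dataclass
class SubjectAnalysis:
    """Pipeline outputs for one subject."""

    subject: int
    pooled: pd.DataFrame  # columns: subject, spl_db, roi, value  (percent)
    cond_dff: dict[float, CondDff]
    band_trace: dict[str, np.ndarray]  # pooled-band ROI time courses, percent
    band_times_s: np.ndarray  # post-frame start times relative to onset
    full_times_s: np.ndarray  # pre+post frame start times relative to onset
    band_full_trace: dict[str, np.ndarray]  # incl. pre-stimulus frames


@dataclass
class StudyResult:
    """Across-subject study outputs."""

    curves: dict[str, ResponseCurve]
    threshold: ThresholdResult
    kinetics: dict[str, KineticsEstimate]
    timepoint_table: pd.DataFrame
    per_subject: pd.DataFrame
    subjects: list[SubjectAnalysis] = field(repr=False, default_factory=list)


def simulate_subject(config: SimulationConfig, subject_index: int):
    """Schedule + rendered epochs for one subject."""
    schedule = subject_schedule(config, subject_index)
    return schedule, render_epochs(config, schedule, subject_index)


def analyze_subject(
    epochs_by_spl: dict[float, EpochGroup],
    rois: RoiSet,
    geometry,
    subject: int = 0,
    plateau_band_db: tuple[float, float] = DEFAULT_PLATEAU_BAND_DB,
) -> SubjectAnalysis:
    """Run the dF/F0 pipeline for one subject.

    Produces the per-SPL pooled ROI responses (the dose-response data) and
    the plateau-band pooled ROI time courses (the kinetics data).  The band
    time course averages the epochs of all band conditions at the trial
    level before the ratio is taken, mirroring the per-condition order of
    operations.
    """
    if not epochs_by_spl:
        raise InvalidParameterError("no epoched conditions to analyze")
    masks = {r.name: rasterize_roi(r, geometry) for r in rois}

    rows = []
    cond_dff: dict[float, CondDff] = {}
    for spl, group in epochs_by_spl.items():
        mean_epoch = average_condition(group)
        d = compute_dff(mean_epoch, spl_db=spl, n_pre=group.n_pre, n_trials=group.n_trials)
        cond_dff[spl] = d
        for name, mask in masks.items():
            vals = d.pooled[mask]
            rows.append({"subject": subject, "spl_db": spl, "roi": name,
                         "value": float(np.nanmean(vals))})

    lo, hi = plateau_band_db
    band_groups = [g for spl, g in epochs_by_spl.items() if lo <= spl <= hi]
    if not band_groups:
        raise InvalidParameterError(f"no conditions inside the plateau band {plateau_band_db}")
    n_pre = band_groups[0].n_pre
    band_frames = np.concatenate([g.frames for g in band_groups], axis=0)
    band_mean = band_frames.mean(axis=0)
    band_dff = compute_dff(band_mean, n_pre=n_pre, n_trials=len(band_frames))
    some = next(iter(epochs_by_spl.values()))
    T = 1.0 / geometry.frame_rate_hz
    n_post = band_mean.shape[0] - n_pre
    post_times = np.arange(n_post) * T
    full_times = np.arange(-n_pre, n_post) * T
    band_trace = {}
    band_full = {}
    # the full (pre+post) trace in dF/F0 units: apply the same baseline to pre frames
    f0 = band_dff.f0
    with np.errstate(invalid="ignore", divide="ignore"):
        full_dff = 100.0 * (band_mean - np.where(f0 > 0, f0, np.nan)[None]) / np.where(f0 > 0, f0, np.nan)[None]
    for name, mask in masks.items():
        band_trace[name] = roi_timecourse(band_dff.dff, mask)
        band_full[name] = roi_timecourse(full_dff, mask)

    return SubjectAnalysis(
        subject=subject,
        pooled=pd.DataFrame(rows),
        cond_dff=cond_dff,
        band_trace=band_trace,
        band_times_s=post_times,
        full_times_s=full_times,
        band_full_trace=band_full,
    )


def run_study(
    config: SimulationConfig,
    rois: RoiSet,
    target_roi: str = "SRAF",
    background_roi: str = "Back",
    alpha: float = 0.05,
    correction: str = "none",
    plateau_band_db: tuple[float, float] = DEFAULT_PLATEAU_BAND_DB,
    keep_subjects: bool = False,
) -> StudyResult:
    """Simulate all subjects, analyze each, and assemble the study-level
    results: dose-response curves per ROI, the target-vs-background detection
    threshold, kinetics of the subject-averaged plateau-band time course, and
    the frame-wise significance table."""
    analyses: list[SubjectAnalysis] = []
    for s in range(config.n_subjects):
        _, epochs = simulate_subject(config, s)
        grouped = epoch(epochs, n_post=config.n_post, n_pre=config.n_pre)
        analyses.append(
            analyze_subject(grouped, rois, config.geometry, subject=s, plateau_band_db=plateau_band_db)
        )
        if not keep_subjects:
            analyses[-1].cond_dff = {}
    return run_study_from_analyses(
        analyses, rois, target_roi=target_roi, background_roi=background_roi,
        alpha=alpha, correction=correction, keep_subjects=keep_subjects,
    )


def run_study_from_analyses(
    analyses: list[SubjectAnalysis],
    rois: RoiSet,
    target_roi: str = "SRAF",
    background_roi: str = "Back",
    alpha: float = 0.05,
    correction: str = "none",
    keep_subjects: bool = True,
) -> StudyResult:
    """Assemble study-level results from already-analyzed subjects."""
    per_subject = pd.concat([a.pooled for a in analyses], ignore_index=True)
    roi_names = rois.names()
    curves = {
        name: build_response_curve(per_subject[per_subject.roi == name], name) for name in roi_names
    }

    spls = curves[target_roi].spl_db
    def matrix(name: str) -> np.ndarray:
        pivot = per_subject[per_subject.roi == name].pivot_table(index="subject", columns="spl_db", values="value")
        return pivot.to_numpy()

    if len(analyses) >= 2:
        threshold = detect_threshold(
            matrix(target_roi), matrix(background_roi), spls, alpha=alpha, correction=correction, roi=target_roi
        )
    else:
        threshold = ThresholdResult(roi=target_roi, threshold_spl_db=None, table=pd.DataFrame(),
                                    alpha=alpha, correction=correction)

    times = analyses[0].band_times_s
    full_times = analyses[0].full_times_s
    kinetics = {}
    for name in roi_names:
        full_mean = np.mean([a.band_full_trace[name] for a in analyses], axis=0)
        kinetics[name] = estimate_kinetics(full_times, full_mean, onset_time_s=0.0)

    target_traces = np.stack([a.band_trace[target_roi] for a in analyses])
    back_traces = np.stack([a.band_trace[background_roi] for a in analyses])
    if len(analyses) >= 2:
        tp_table = timepoint_significance(target_traces, back_traces, times, alpha=alpha)
    else:
        tp_table = pd.DataFrame()

    return StudyResult(
        curves=curves,
        threshold=threshold,
        kinetics=kinetics,
        timepoint_table=tp_table,
        per_subject=per_subject,
        subjects=analyses if keep_subjects else [],
    )
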