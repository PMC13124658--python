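"""Core image processing: trial epoching, per-condition trial averaging,
dF/F0 against the 3-frame pre-stimulus baseline, pooled response maps, and
SPL-group pooling.

Order of operations matters and is fixed by design: images are averaged
across trials FIRST and the ratio to the averaged baseline is taken on the
trial-mean images (ratio of averages, not average of ratios).  dF/F0 is
reported in percent everywhere.  The pooled response map is the arithmetic
mean of the 2nd-4th post-stimulus frames, i.e. the 50-100, 100-150 and
150-200 ms windows; post-frame 1 (0-50 ms) is excluded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .errors import EmptyRoiError, InvalidParameterError
from .imgio import MovieStack
from .protocol import TrialSchedule
from .synthetic import SubjectEpochs

logger = logging.getLogger(__name__)

__all__ = [
    "EpochGroup",
    "CondDff",
    "epoch",
    "average_condition",
    "compute_dff",
    "pool_spl_groups",
    "roi_timecourse",
    "N_PRE_FRAMES",
    "POOLED_POST_FRAMES",
]

N_PRE_FRAMES = 3  # the baseline is the mean of the three pre-stimulus frames
POOLED_POST_FRAMES = (2, 3, 4)  # 1-based post-stimulus frame indices pooled into the response map


@dataclass
class EpochGroup:
    """All epochs of one SPL condition: (n_trials, n_pre + n_post, H, W)."""

    spl_db: float
    frames: np.ndarray
    onset_offsets_s: np.ndarray  # onset position within post-frame 1, per trial
    n_pre: int

    @property
    def n_trials(self) -> int:
        return len(self.frames)


@dataclass
class CondDff:
    """Trial-averaged dF/F0 for one condition (percent units)."""

    spl_db: float
    f0: np.ndarray  # baseline image, (H, W)
    dff: np.ndarray  # (n_post, H, W), percent
    pooled: np.ndarray  # mean of pooled post frames, (H, W), percent
    n_trials: int
    masked_pixels: int


def epoch(movie_or_epochs, schedule: TrialSchedule | None = None, n_post: int = 8,
          n_pre: int = N_PRE_FRAMES) -> dict[float, EpochGroup]:
    """Cut a recording into per-trial epochs and group them by SPL.

    Post-frame 1 is the first frame whose start time is at or after the trial
    onset; the ``n_pre`` frames immediately before it form the baseline.
    Trials whose window does not fit inside the recording are dropped with a
    logged warning.  Accepts either a continuous :class:`MovieStack` (with a
    schedule) or a pre-rendered :class:`SubjectEpochs`.
    """
    if n_post < 4:
        raise InvalidParameterError("n_post must be >= 4 (pooling uses post frames 2-4)")
    if isinstance(movie_or_epochs, SubjectEpochs):
        se = movie_or_epochs
        if se.n_pre < n_pre:
            raise InvalidParameterError("rendered epochs carry fewer pre-stimulus frames than requested")
        groups: dict[float, list[int]] = {}
        for i, spl in enumerate(se.spls_db):
            groups.setdefault(float(spl), []).append(i)
        pre_skip = se.n_pre - n_pre
        stop = se.n_pre + min(n_post, se.n_post)
        if se.n_post < n_post:
            raise InvalidParameterError("rendered epochs carry fewer post-stimulus frames than requested")
        return {
            spl: EpochGroup(
                spl_db=spl,
                frames=se.frames[idx, pre_skip:stop],
                onset_offsets_s=se.onset_offsets_s[idx],
                n_pre=n_pre,
            )
            for spl, idx in sorted(groups.items())
        }

    movie: MovieStack = movie_or_epochs
    if schedule is None:
        raise InvalidParameterError("a schedule is required to epoch a continuous movie")
    T = movie.geometry.frame_period_s
    t0 = movie.timestamps_s[0]
    n_frames = movie.n_frames
    groups_arr: dict[float, list[tuple[np.ndarray, float]]] = {}
    dropped = 0
    for event in schedule.events:
        first_post = int(np.ceil((event.onset_time_s - t0) / T - 1e-12))
        start = first_post - n_pre
        stop = first_post + n_post
        if start < 0 or stop > n_frames:
            dropped += 1
            continue
        delta = t0 + first_post * T - event.onset_time_s
        groups_arr.setdefault(float(event.spl_db), []).append((movie.frames[start:stop], delta))
    if dropped:
        logger.warning("epoch: dropped %d trial(s) whose window fell outside the recording", dropped)
    return {
        spl: EpochGroup(
            spl_db=spl,
            frames=np.stack([f for f, _ in items]),
            onset_offsets_s=np.array([d for _, d in items]),
            n_pre=n_pre,
        )
        for spl, items in sorted(groups_arr.items())
    }


def average_condition(group: EpochGroup) -> np.ndarray:
    """Frame-wise arithmetic mean across the trials of one condition."""
    if group.n_trials == 0:
        raise InvalidParameterError(f"condition {group.spl_db} dB has no epochs to average")
    return group.frames.mean(axis=0)


def compute_dff(mean_epoch: np.ndarray, spl_db: float = float("nan"), n_pre: int = N_PRE_FRAMES,
                n_trials: int = 0) -> CondDff:
    """dF/F0 of a trial-averaged epoch against its 3-frame baseline.

    F0 is the pixel-wise mean of the ``n_pre`` pre-stimulus frames; each
    post-stimulus frame becomes ``100 * (frame - F0) / F0`` percent.  Pixels
    with non-positive baseline are masked to NaN and counted.
    """
    mean_epoch = np.asarray(mean_epoch, dtype=float)
    if mean_epoch.ndim != 3 or len(mean_epoch) <= n_pre:
        raise InvalidParameterError("mean_epoch must be (n_pre + n_post, H, W) with at least one post frame")
    f0 = mean_epoch[:n_pre].mean(axis=0)
    bad = f0 <= 0
    masked = int(bad.sum())
    safe_f0 = np.where(bad, np.nan, f0)
    dff = 100.0 * (mean_epoch[n_pre:] - safe_f0[None]) / safe_f0[None]
    lo, hi = POOLED_POST_FRAMES[0] - 1, POOLED_POST_FRAMES[-1]
    pooled = dff[lo:hi].mean(axis=0)
    return CondDff(spl_db=spl_db, f0=f0, dff=dff, pooled=pooled, n_trials=n_trials, masked_pixels=masked)


def pool_spl_groups(
    pooled_maps: list[tuple[float, np.ndarray]],
    group_size: int = 5,
    allow_remainder: bool = False,
) -> list[tuple[str, np.ndarray]]:
    """Average pooled response maps over consecutive blocks of neighboring
    SPL levels (e.g. 42-50, 52-60, ... dB for 2 dB steps, group size 5).

    Input must be sorted ascending by SPL; the level count must be divisible
    into full groups unless ``allow_remainder`` is set.
    """
    spls = [s for s, _ in pooled_maps]
    if any(b <= a for a, b in zip(spls, spls[1:])):
        raise InvalidParameterError("pooled maps must be sorted by strictly ascending SPL")
    if group_size < 1:
        raise InvalidParameterError("group_size must be >= 1")
    n = len(pooled_maps)
    if n % group_size and not allow_remainder:
        raise InvalidParameterError(
            f"{n} conditions do not divide into groups of {group_size}; pass allow_remainder=True to keep the tail"
        )
    out = []
    for start in range(0, n, group_size):
        chunk = pooled_maps[start : start + group_size]
        label = f"{chunk[0][0]:g}-{chunk[-1][0]:g} dB"
        out.append((label, np.mean([m for _, m in chunk], axis=0)))
    return out


def roi_timecourse(dff_movie: np.ndarray, roi_mask: np.ndarray) -> np.ndarray:
    """Frame-wise mean dF/F0 (percent) over the ROI pixels.

    Masked (NaN) pixels are excluded; an ROI with no valid pixel raises.
    """
    movie = np.asarray(dff_movie, dtype=float)
    mask = np.asarray(roi_mask, dtype=bool)
    if movie.ndim != 3 or mask.shape != movie.shape[1:]:
        raise InvalidParameterError("dff_movie must be (frames, H, W) with a matching (H, W) ROI mask")
    vals = movie[:, mask]
    valid = ~np.isnan(vals)
    if not valid.any(axis=1).all():
        raise EmptyRoiError("ROI contains no valid (unmasked) pixels in at least one frame")
    return np.nanmean(vals, axis=1)
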