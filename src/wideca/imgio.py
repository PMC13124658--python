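"""File formats: timestamped multipage TIFF stacks, trial event logs, ROI
definition files, and flat key-value run configuration.

Conventions
-----------
Pixel coordinates have their origin at the top-left of the image; x increases
along the width (the 7.1 mm anterior-posterior axis), y along the height (the
4.0 mm dorsal-ventral axis).  Pixel centers sit at ``(index + 0.5) * pitch``.
Raw movies are stored as grayscale 16-bit unsigned TIFF; derived dF/F0 maps
use a 32-bit float variant of the same writer.  Timestamps and geometry are
stored as a JSON text block in the TIFF ImageDescription tag so files are
self-describing; all writers are byte-deterministic for identical inputs.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile

from .errors import EmptyRoiError, FormatError, InvalidParameterError
from .protocol import ScheduleSpec, TrialEvent, TrialSchedule

__all__ = [
    "FrameGeometry",
    "MovieStack",
    "RoiDef",
    "RoiSet",
    "write_stack",
    "read_stack",
    "write_events",
    "read_events",
    "write_rois",
    "read_rois",
    "rasterize_roi",
]

_EVENT_COLUMNS = ["trial_index", "onset_time_s", "spl_db"]
_ROI_COLUMNS = ["name", "center_x_mm", "center_y_mm", "radius_mm"]


@dataclass(frozen=True)
class FrameGeometry:
    """Frame pixel counts, physical field size, and frame rate.

    Defaults correspond to 240 x 135 pixel frames covering a 7.1 x 4.0 mm
    cortical field sampled at 20 Hz.
    """

    width_px: int = 240
    height_px: int = 135
    field_width_mm: float = 7.1
    field_height_mm: float = 4.0
    frame_rate_hz: float = 20.0

    def __post_init__(self) -> None:
        if min(self.width_px, self.height_px) < 1 or min(
            self.field_width_mm, self.field_height_mm, self.frame_rate_hz
        ) <= 0:
            raise InvalidParameterError("all FrameGeometry fields must be positive")

    @property
    def pitch_x_mm(self) -> float:
        return self.field_width_mm / self.width_px

    @property
    def pitch_y_mm(self) -> float:
        return self.field_height_mm / self.height_px

    @property
    def frame_period_s(self) -> float:
        return 1.0 / self.frame_rate_hz

    def pixel_centers_mm(self) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) coordinates of pixel centers, each shaped (height, width)."""
        x = (np.arange(self.width_px) + 0.5) * self.pitch_x_mm
        y = (np.arange(self.height_px) + 0.5) * self.pitch_y_mm
        return np.meshgrid(x, y)

    def to_dict(self) -> dict:
        return {
            "width_px": self.width_px,
            "height_px": self.height_px,
            "field_width_mm": self.field_width_mm,
            "field_height_mm": self.field_height_mm,
            "frame_rate_hz": self.frame_rate_hz,
        }


@dataclass(frozen=True)
class MovieStack:
    """A timestamped frame stack with physical pixel geometry."""

    frames: np.ndarray  # (time, height, width), non-negative intensities
    timestamps_s: np.ndarray  # per-frame start times
    geometry: FrameGeometry

    def __post_init__(self) -> None:
        if self.frames.ndim != 3:
            raise FormatError("frames must be a 3-D (time, height, width) array")
        if len(self.timestamps_s) != len(self.frames):
            raise FormatError("timestamps_s: frame count must equal timestamp count")
        if self.frames.shape[1] != self.geometry.height_px or self.frames.shape[2] != self.geometry.width_px:
            raise FormatError("geometry: frame shape does not match geometry")
    def validate_uniform(self, tol: float = 1e-9) -> None:
        """Check timestamps are strictly increasing with spacing equal to
        1/frame_rate_hz (the continuous-recording contract; concatenated
        epoch files may legitimately contain overlapping trial windows)."""
        if len(self.timestamps_s) > 1:
            spacing = np.diff(self.timestamps_s)
            if np.any(spacing <= 0):
                raise FormatError("timestamps_s must be strictly increasing for a continuous movie")
            if np.any(np.abs(spacing - self.geometry.frame_period_s) > tol):
                raise FormatError("timestamps_s: spacing must equal 1/frame_rate_hz for a continuous movie")

    @property
    def n_frames(self) -> int:
        return len(self.frames)


def write_stack(stack: MovieStack, path, dtype: str = "uint16", extra_metadata: dict | None = None) -> None:
    """Write a multipage TIFF with JSON metadata (timestamps, geometry).

    ``dtype='uint16'`` is the raw-movie container; values outside
    [0, 65535] raise.  ``dtype='float32'`` is the variant used for dF/F0 maps.
    """
    frames = np.asarray(stack.frames)
    if dtype == "uint16":
        if frames.size and (frames.min() < 0 or frames.max() > 65535):
            raise FormatError("frames: values outside [0, 65535] cannot be stored in a 16-bit container")
        data = np.round(frames).astype(np.uint16)
    elif dtype == "float32":
        data = frames.astype(np.float32)
    else:
        raise InvalidParameterError(f"unsupported dtype {dtype!r}; use 'uint16' or 'float32'")
    meta = {
        "format": "wideca-movie-v1",
        "timestamps_s": [round(float(t), 9) for t in stack.timestamps_s],
        "geometry": stack.geometry.to_dict(),
    }
    if extra_metadata:
        meta["extra"] = extra_metadata
    description = json.dumps(meta, sort_keys=True)
    with tifffile.TiffWriter(str(path)) as tif:
        tif.write(data, description=description, photometric="minisblack", contiguous=True)


def read_stack(path) -> MovieStack:
    """Read a stack written by :func:`write_stack`; lossless round-trip."""
    try:
        with tifffile.TiffFile(str(path)) as tif:
            frames = tif.asarray()
            description = tif.pages[0].description
    except (tifffile.TiffFileError, FileNotFoundError) as exc:
        raise FormatError(f"{path}: not a readable TIFF stack ({exc})") from exc
    if frames.ndim == 2:
        frames = frames[None]
    try:
        meta = json.loads(description)
    except (json.JSONDecodeError, TypeError) as exc:
        raise FormatError(f"{path}: missing or malformed JSON metadata in ImageDescription") from exc
    if "timestamps_s" not in meta or "geometry" not in meta:
        missing = [k for k in ("timestamps_s", "geometry") if k not in meta]
        raise FormatError(f"{path}: metadata missing required field(s) {missing}")
    geometry = FrameGeometry(**meta["geometry"])
    timestamps = np.asarray(meta["timestamps_s"], dtype=float)
    if frames.min() < 0:
        raise FormatError(f"{path}: frames contain negative intensities")
    return MovieStack(frames=frames, timestamps_s=timestamps, geometry=geometry)


def read_stack_metadata(path) -> dict:
    """Return the raw JSON metadata block (including any 'extra' record)."""
    with tifffile.TiffFile(str(path)) as tif:
        return json.loads(tif.pages[0].description)


def write_events(schedule: TrialSchedule, path) -> None:
    """Serialize a trial schedule as a CSV event log (times to 1 us)."""
    frame = pd.DataFrame(
        {
            "trial_index": [e.trial_index for e in schedule.events],
            "onset_time_s": [f"{e.onset_time_s:.6f}" for e in schedule.events],
            "spl_db": [e.spl_db for e in schedule.events],
        }
    )
    frame.to_csv(path, index=False, lineterminator="\n")


def read_events(path, spec: ScheduleSpec | None = None, stimulus_duration_s: float = 0.05) -> TrialSchedule:
    """Parse a CSV event log back into a TrialSchedule.

    Rows are validated against the event invariants; violations raise
    :class:`FormatError` with the offending line number (header = line 1).
    """
    try:
        frame = pd.read_csv(path)
    except (pd.errors.ParserError, FileNotFoundError, UnicodeDecodeError) as exc:
        raise FormatError(f"{path}: cannot parse event log ({exc})") from exc
    if list(frame.columns) != _EVENT_COLUMNS:
        raise FormatError(f"{path}: header must be {','.join(_EVENT_COLUMNS)}")
    events = []
    last_onset = -np.inf
    for row_number, row in enumerate(frame.itertuples(index=False), start=2):
        try:
            idx = int(row.trial_index)
            onset = float(row.onset_time_s)
            spl = float(row.spl_db)
        except (TypeError, ValueError) as exc:
            raise FormatError(f"{path}: malformed row at line {row_number}") from exc
        if onset <= last_onset:
            raise FormatError(f"{path}: onset times must be strictly increasing (line {row_number})")
        if onset < 0:
            raise FormatError(f"{path}: negative onset time (line {row_number})")
        last_onset = onset
        events.append(TrialEvent(trial_index=idx, onset_time_s=onset, spl_db=spl))
    if spec is None:
        spls = sorted({e.spl_db for e in events})
        if len(spls) >= 2:
            step = min(np.diff(spls))
            spec = ScheduleSpec(
                spl_min_db=spls[0],
                spl_max_db=spls[0] + step * round((spls[-1] - spls[0]) / step),
                spl_step_db=step,
                reps_per_level=max(1, len(events) // max(1, len(spls))),
            )
        else:
            only = spls[0] if spls else 0.0
            spec = ScheduleSpec(spl_min_db=only, spl_max_db=only, spl_step_db=1.0, reps_per_level=max(1, len(events)))
    return TrialSchedule(spec=spec, events=tuple(events), stimulus_duration_s=stimulus_duration_s)


@dataclass(frozen=True)
class RoiDef:
    """A circular region of interest in field coordinates."""

    name: str
    center_mm: tuple[float, float]
    radius_mm: float

    def __post_init__(self) -> None:
        if self.radius_mm <= 0:
            raise InvalidParameterError(f"ROI {self.name!r}: radius must be positive")


@dataclass(frozen=True)
class RoiSet:
    entries: tuple[RoiDef, ...]

    def __iter__(self):
        return iter(self.entries)

    def __len__(self) -> int:
        return len(self.entries)

    def names(self) -> list[str]:
        return [r.name for r in self.entries]

    def get(self, name: str) -> RoiDef:
        for r in self.entries:
            if r.name == name:
                return r
        raise KeyError(name)


def write_rois(rois: RoiSet, path) -> None:
    frame = pd.DataFrame(
        {
            "name": [r.name for r in rois],
            "center_x_mm": [r.center_mm[0] for r in rois],
            "center_y_mm": [r.center_mm[1] for r in rois],
            "radius_mm": [r.radius_mm for r in rois],
        }
    )
    frame.to_csv(path, index=False, lineterminator="\n")


def read_rois(path) -> RoiSet:
    try:
        frame = pd.read_csv(path)
    except (pd.errors.ParserError, FileNotFoundError, UnicodeDecodeError) as exc:
        raise FormatError(f"{path}: cannot parse ROI file ({exc})") from exc
    if list(frame.columns) != _ROI_COLUMNS:
        raise FormatError(f"{path}: header must be {','.join(_ROI_COLUMNS)}")
    entries = []
    for row_number, row in enumerate(frame.itertuples(index=False), start=2):
        try:
            entries.append(
                RoiDef(
                    name=str(row.name),
                    center_mm=(float(row.center_x_mm), float(row.center_y_mm)),
                    radius_mm=float(row.radius_mm),
                )
            )
        except (TypeError, ValueError, InvalidParameterError) as exc:
            raise FormatError(f"{path}: malformed ROI at line {row_number} ({exc})") from exc
    return RoiSet(entries=tuple(entries))


def rasterize_roi(roi: RoiDef, geometry: FrameGeometry) -> np.ndarray:
    """Boolean (height, width) mask of pixels whose centers lie within the ROI.

    Deterministic; raises :class:`EmptyRoiError` when no pixel center falls
    inside the circle (e.g. the ROI lies off the imaging field).
    """
    xx, yy = geometry.pixel_centers_mm()
    cx, cy = roi.center_mm
    mask = (xx - cx) ** 2 + (yy - cy) ** 2 <= roi.radius_mm**2
    if not mask.any():
        raise EmptyRoiError(f"ROI {roi.name!r} at {roi.center_mm} mm rasterizes to zero pixels")
    return mask
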