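"""Ingestion and calibration of per-frame ultrasound landmark annotations.

Each video frame carries two manually annotated points: the lateral edge of
the acromion (the fixed bony reference) and the greater tuberosity of the
humeral head (the moving landmark).  Coordinates follow the image convention:
x increases to the right, y increases downward (deeper below the skin
surface).  Subtracting the per-frame acromial annotation from the greater
tuberosity and scaling by the probe calibration yields the relative
trajectory, in cm, on which all downstream kinematics are computed.  Because
the subtraction is done per frame, slow transducer drift common to both
landmarks cancels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import FormatError, InsufficientDataError, ParseError

__all__ = [
    "LandmarkFrame",
    "Calibration",
    "RelativeTrajectory",
    "read_landmark_csv",
    "write_landmark_csv",
    "to_relative_trajectory",
]

#: Required CSV header columns, in canonical order.
CSV_COLUMNS = ("frame_index", "time_s", "acr_x_px", "acr_y_px", "gt_x_px", "gt_y_px")

#: Longest run of consecutive unusable frames that may be bridged by
#: linear interpolation; longer gaps abort ingestion.
MAX_INTERP_GAP = 2


@dataclass(frozen=True)
class LandmarkFrame:
    """One annotated video frame.

    Attributes
    ----------
    frame_index : int
        Zero-based frame number, strictly increasing within a recording.
    time : float
        Acquisition time in seconds.
    acr : tuple of float
        Pixel coordinates (x, y) of the lateral acromial edge.
    gt : tuple of float
        Pixel coordinates (x, y) of the greater tuberosity.
    """

    frame_index: int
    time: float
    acr: tuple[float, float]
    gt: tuple[float, float]


@dataclass(frozen=True)
class Calibration:
    """Pixel-to-cm scan-geometry calibration.

    Ultrasound pixel spacing may differ between axes, so separate scale
    factors are allowed; use :meth:`isotropic` for the common square-pixel
    case.  ``y_axis_down`` records the vertical convention of the source
    coordinates: ``True`` (default, image convention) means larger y is
    deeper below the transducer.
    """

    cm_per_pixel_x: float
    cm_per_pixel_y: float
    y_axis_down: bool = True

    def __post_init__(self) -> None:
        for name in ("cm_per_pixel_x", "cm_per_pixel_y"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"{name} must be positive and finite, got {v!r}")

    @classmethod
    def isotropic(cls, cm_per_pixel: float, y_axis_down: bool = True) -> "Calibration":
        return cls(cm_per_pixel, cm_per_pixel, y_axis_down)


@dataclass(frozen=True)
class RelativeTrajectory:
    """Greater-tuberosity position relative to the acromial reference, in cm.

    ``y`` is the vertical separation of the greater tuberosity *below* the
    acromial edge: positive values mean the tuberosity sits deeper than the
    acromion, and the per-phase minimum of ``y`` is the minimal vertical
    acromiohumeral distance.
    """

    times: np.ndarray
    x: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        x = np.asarray(self.x, dtype=float)
        y = np.asarray(self.y, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)
        if not (times.shape == x.shape == y.shape) or times.ndim != 1:
            raise ValueError("times, x, y must be 1-D arrays of equal length")
        if times.size < 3:
            raise InsufficientDataError(
                f"trajectory needs >= 3 samples, got {times.size}"
            )
        if not np.all(np.diff(times) > 0):
            raise ValueError("times must be strictly increasing")
        if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
            raise ValueError("trajectory coordinates must be finite")

    @property
    def n(self) -> int:
        return self.times.size

    def points(self, start: int | None = None, stop: int | None = None) -> np.ndarray:
        """Return (n, 2) array of (x, y) samples over ``[start, stop)``."""
        return np.column_stack([self.x[start:stop], self.y[start:stop]])


def read_landmark_csv(path) -> list[LandmarkFrame]:
    """Read and validate a landmark annotation CSV.

    The file must carry the header ``frame_index,time_s,acr_x_px,acr_y_px,
    gt_x_px,gt_y_px`` with one row per frame.  Rows are returned sorted by
    frame index.  Empty coordinate cells are admitted as NaN (a missing
    annotation) and handled later by :func:`to_relative_trajectory`;
    non-numeric text is a hard parse error.

    Raises
    ------
    FormatError
        If a required column is missing or a frame index is duplicated.
    ParseError
        If a cell holds non-numeric text (message names the data row).
    InsufficientDataError
        If fewer than 3 rows are present.
    """
    df = pd.read_csv(path, dtype=str, skipinitialspace=True)
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"missing required column(s): {', '.join(missing)}")
    if len(df) < 3:
        raise InsufficientDataError(
            f"landmark CSV must contain >= 3 rows, got {len(df)}"
        )

    numeric = {}
    for col in CSV_COLUMNS:
        raw = df[col].str.strip() if df[col].dtype == object else df[col]
        vals = pd.to_numeric(raw, errors="coerce")
        bad = vals.isna() & raw.notna() & (raw != "")
        if bad.any():
            row = int(bad.idxmax()) + 2  # 1-based, counting the header row
            raise ParseError(
                f"non-numeric value {df[col][bad.idxmax()]!r} in column "
                f"{col!r} at file row {row}"
            )
        # exact strtod conversion (pd.to_numeric's fast path loses ulps)
        numeric[col] = np.array(
            [float(s) if isinstance(s, str) and s else np.nan for s in raw],
            dtype=float,
        )

    fi = numeric["frame_index"]
    if np.isnan(fi).any() or np.isnan(numeric["time_s"]).any():
        raise ParseError("frame_index and time_s may not be empty")
    if len(np.unique(fi)) != len(fi):
        dupes = pd.Series(fi)[pd.Series(fi).duplicated()].unique()
        raise FormatError(f"duplicate frame_index value(s): {dupes.tolist()}")

    order = np.argsort(fi, kind="stable")
    frames = [
        LandmarkFrame(
            frame_index=int(fi[i]),
            time=float(numeric["time_s"][i]),
            acr=(float(numeric["acr_x_px"][i]), float(numeric["acr_y_px"][i])),
            gt=(float(numeric["gt_x_px"][i]), float(numeric["gt_y_px"][i])),
        )
        for i in order
    ]
    times = np.array([f.time for f in frames])
    if not np.all(np.diff(times) > 0):
        raise FormatError("time_s must be strictly increasing with frame_index")
    return frames


def write_landmark_csv(frames: list[LandmarkFrame], path) -> None:
    """Write frames to CSV in the canonical column order (full float precision)."""
    df = pd.DataFrame(
        {
            "frame_index": [f.frame_index for f in frames],
            "time_s": [f.time for f in frames],
            "acr_x_px": [f.acr[0] for f in frames],
            "acr_y_px": [f.acr[1] for f in frames],
            "gt_x_px": [f.gt[0] for f in frames],
            "gt_y_px": [f.gt[1] for f in frames],
        }
    )
    df.to_csv(path, index=False)  # str(float) repr round-trips exactly


def _interp_gaps(times: np.ndarray, arr: np.ndarray) -> np.ndarray:
    valid = np.isfinite(arr)
    if valid.all():
        return arr
    out = arr.copy()
    out[~valid] = np.interp(times[~valid], times[valid], arr[valid])
    return out


def to_relative_trajectory(
    frames: list[LandmarkFrame], cal: Calibration
) -> RelativeTrajectory:
    """Convert frames into the calibrated relative trajectory.

    Per frame, the relative position is ``(gt - acr)`` componentwise, scaled
    to cm.  The vertical coordinate is re-oriented (if needed) so that
    positive ``y`` always means the greater tuberosity is deeper than the
    acromial edge.  Runs of at most :data:`MAX_INTERP_GAP` consecutive frames
    with any missing/non-finite coordinate are bridged by linear
    interpolation in time (with a warning); longer gaps abort.
    """
    if len(frames) < 3:
        raise InsufficientDataError(f"need >= 3 frames, got {len(frames)}")
    times = np.array([f.time for f in frames], dtype=float)
    acr = np.array([f.acr for f in frames], dtype=float)
    gt = np.array([f.gt for f in frames], dtype=float)

    usable = np.isfinite(acr).all(axis=1) & np.isfinite(gt).all(axis=1)
    if not usable.all():
        if not (usable[0] and usable[-1]):
            raise InsufficientDataError(
                "first and last frames must have complete annotations"
            )
        # longest run of consecutive unusable frames
        run = longest = 0
        for u in usable:
            run = 0 if u else run + 1
            longest = max(longest, run)
        if longest > MAX_INTERP_GAP:
            raise InsufficientDataError(
                f"gap of {longest} consecutive unusable frames exceeds the "
                f"interpolation limit of {MAX_INTERP_GAP}"
            )
        warnings.warn(
            f"interpolated {int((~usable).sum())} frame(s) with missing "
            "landmark annotations",
            stacklevel=2,
        )
        bad = ~usable
        acr[bad] = np.nan
        gt[bad] = np.nan
        for arr in (acr, gt):
            for j in range(2):
                arr[:, j] = _interp_gaps(times, arr[:, j])

    rel = gt - acr
    x = rel[:, 0] * cal.cm_per_pixel_x
    y = rel[:, 1] * cal.cm_per_pixel_y
    if not cal.y_axis_down:
        y = -y
    return RelativeTrajectory(times=times, x=x, y=y)
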