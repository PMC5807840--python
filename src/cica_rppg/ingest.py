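"""Reading video frames, trace files and ground-truth PPG records.

The temporal input to every downstream stage is a :class:`TraceMatrix`:
three channel-wise traces (R, G, B) obtained by spatial averaging of the
skin pixels of each frame, at a fixed sampling rate.  Face detection and
tracking are out of scope; the region of interest is supplied explicitly
(full frame, rectangle, mask file) or by a simple channel-ratio skin
heuristic.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd


# --------------------------------------------------------------------------
# Domain types
# --------------------------------------------------------------------------

@dataclass
class TraceMatrix:
    """Channel-major RGB temporal traces.

    Attributes
    ----------
    values : (3, N) float array
        Row order is fixed: R, G, B.  Arbitrary intensity units.
    fs : float
        Sampling rate in Hz.
    t0 : float
        Start time of the first sample in seconds.
    """

    values: np.ndarray
    fs: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != 3:
            raise ValueError(
                f"trace matrix must be 3xN, got shape {self.values.shape}"
            )
        if self.values.shape[1] < 2:
            raise ValueError("trace matrix needs at least 2 samples")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("trace matrix contains non-finite entries")
        if not self.fs > 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")

    @property
    def n(self) -> int:
        return self.values.shape[1]

    @property
    def m(self) -> int:
        return self.values.shape[0]

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n) / self.fs

    def copy_with(self, values: np.ndarray) -> "TraceMatrix":
        return TraceMatrix(values=values, fs=self.fs, t0=self.t0)

    def window(self, start: int, stop: int) -> "TraceMatrix":
        """Sample-index slice [start, stop)."""
        return TraceMatrix(
            values=self.values[:, start:stop],
            fs=self.fs,
            t0=self.t0 + start / self.fs,
        )


@dataclass
class ROISpec:
    """Region-of-interest selection for spatial averaging.

    ``mode`` is one of ``full-frame``, ``rectangle``, ``mask-file``,
    ``skin-heuristic``.  Rectangles are 0-based half-open
    ``(x0, y0, x1, y1)`` pixel bounds; a mask file is a static 2-D binary
    image matching the frame shape.
    """

    mode: str = "full-frame"
    rectangle: Optional[tuple[int, int, int, int]] = None
    mask_path: Optional[str] = None
    mask: Optional[np.ndarray] = field(default=None, repr=False)

    _MODES = ("full-frame", "rectangle", "mask-file", "skin-heuristic")

    def __post_init__(self) -> None:
        if self.mode not in self._MODES:
            raise ValueError(f"unknown ROI mode {self.mode!r}")
        if self.mode == "rectangle" and self.rectangle is None:
            raise ValueError("rectangle mode requires rectangle bounds")
        if self.mode == "mask-file" and self.mask_path is None and self.mask is None:
            raise ValueError("mask-file mode requires mask_path or mask")

    def resolve_mask(self, frame: np.ndarray) -> np.ndarray:
        """Boolean H×W mask of pixels to average for this frame."""
        h, w = frame.shape[:2]
        if self.mode == "full-frame":
            return np.ones((h, w), dtype=bool)
        if self.mode == "rectangle":
            x0, y0, x1, y1 = self.rectangle
            if not (0 <= x0 < x1 <= w and 0 <= y0 < y1 <= h):
                raise ValueError(
                    f"rectangle {self.rectangle} outside frame bounds {w}x{h}"
                )
            mask = np.zeros((h, w), dtype=bool)
            mask[y0:y1, x0:x1] = True
            return mask
        if self.mode == "mask-file":
            if self.mask is None:
                import imageio.v3 as iio

                m = np.asarray(iio.imread(self.mask_path))
                if m.ndim == 3:
                    m = m[..., 0]
                self.mask = m > 0
            if self.mask.shape != (h, w):
                raise ValueError(
                    f"mask shape {self.mask.shape} != frame shape {(h, w)}"
                )
            return self.mask
        # skin-heuristic
        return skin_heuristic_mask(frame)


@dataclass
class PPGRecord:
    """Ground-truth contact PPG: waveform, heart-rate series, timestamps."""

    waveform: np.ndarray
    hr: np.ndarray
    timestamps: np.ndarray
    fs: float = 30.0

    def __post_init__(self) -> None:
        self.waveform = np.asarray(self.waveform, dtype=float)
        self.hr = np.asarray(self.hr, dtype=float)
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        n = len(self.waveform)
        if len(self.hr) != n or len(self.timestamps) != n:
            raise ValueError(
                "waveform, hr and timestamps must have equal lengths "
                f"({n}, {len(self.hr)}, {len(self.timestamps)})"
            )
        finite_hr = self.hr[np.isfinite(self.hr)]
        if finite_hr.size and (np.any(finite_hr <= 0) or np.any(finite_hr >= 300)):
            raise ValueError("heart rates must lie in (0, 300) bpm where present")


# --------------------------------------------------------------------------
# Skin heuristic
# --------------------------------------------------------------------------

#: Default channel-ratio bounds for the skin heuristic.  A pixel is "skin"
#: when R > G > B in the loose sense below and is neither too dark nor
#: saturated: R >= r_min, R > G, G > B·g_over_b_min, R/G within
#: [rg_min, rg_max].
SKIN_DEFAULTS = {
    "r_min": 40.0,
    "rg_min": 1.05,
    "rg_max": 3.0,
    "g_over_b_min": 1.0,
    "max_value": 250.0,
}


def skin_heuristic_mask(frame: np.ndarray, **bounds) -> np.ndarray:
    """Deterministic channel-ratio skin mask for an 8-bit RGB frame.

    A pixel qualifies when its red channel dominates green, green is at
    least as large as blue, the red/green ratio lies inside configurable
    bounds, and no channel is saturated.  Returns a boolean H×W array;
    may be empty (the caller validates).
    """
    cfg = {**SKIN_DEFAULTS, **bounds}
    f = np.asarray(frame, dtype=float)
    if f.ndim != 3 or f.shape[2] != 3:
        raise ValueError(f"expected H x W x 3 frame, got shape {f.shape}")
    r, g, b = f[..., 0], f[..., 1], f[..., 2]
    with np.errstate(divide="ignore", invalid="ignore"):
        rg = np.where(g > 0, r / np.maximum(g, 1e-12), np.inf)
    mask = (
        (r >= cfg["r_min"])
        & (rg >= cfg["rg_min"])
        & (rg <= cfg["rg_max"])
        & (g >= cfg["g_over_b_min"] * b)
        & (f.max(axis=2) <= cfg["max_value"])
    )
    return mask


# --------------------------------------------------------------------------
# Video ingestion
# --------------------------------------------------------------------------

def _iter_frames(video_path: str | Path):
    """Yield H×W×3 RGB frames from a container supported by imageio.

    Multi-page TIFF stacks (the lossless container used by the synthetic
    renderer) are read through tifffile; everything else goes through
    imageio's frame iterator.
    """
    path = Path(video_path)
    if not path.exists():
        raise FileNotFoundError(f"video file not found: {path}")
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        with tifffile.TiffFile(str(path)) as tf:
            for page in tf.pages:
                frame = page.asarray()
                if frame.ndim == 2:
                    frame = np.stack([frame] * 3, axis=-1)
                yield frame
        return
    import imageio.v3 as iio

    for frame in iio.imiter(str(path)):
        frame = np.asarray(frame)
        if frame.ndim == 2:
            frame = np.stack([frame] * 3, axis=-1)
        if frame.shape[2] == 4:  # drop alpha
            frame = frame[..., :3]
        yield frame


def read_video_traces(
    video_path: str | Path,
    roi: ROISpec | None = None,
    fs_override: float | None = None,
) -> TraceMatrix:
    """Spatially average the ROI of every frame into 3×N RGB traces.

    Frames are converted to double precision before averaging.  ``fs`` is
    taken from container metadata when available, else from
    ``fs_override`` (default 30 Hz, the nominal webcam rate).
    """
    roi = roi or ROISpec()
    cols = []
    for i, frame in enumerate(_iter_frames(video_path)):
        if frame.ndim != 3 or frame.shape[2] != 3:
            raise ValueError(
                f"frame {i} has {frame.shape[2] if frame.ndim == 3 else 1} "
                "channels, expected 3"
            )
        mask = roi.resolve_mask(frame)
        if not mask.any():
            raise ValueError(f"empty ROI in frame {i}")
        f = frame.astype(np.float64)
        cols.append(f[mask].mean(axis=0))
    if len(cols) < 2:
        raise ValueError(f"video has {len(cols)} frame(s), need at least 2")
    fs = fs_override
    if fs is None:
        fs = _container_fps(video_path)
    if fs is None:
        fs = 30.0
    return TraceMatrix(values=np.array(cols).T, fs=float(fs))


def _container_fps(video_path: str | Path) -> Optional[float]:
    try:
        import imageio.v3 as iio

        meta = iio.immeta(str(video_path))
        fps = meta.get("fps")
        if fps and fps > 0:
            return float(fps)
    except Exception:
        pass
    return None


# --------------------------------------------------------------------------
# Trace CSV I/O
# --------------------------------------------------------------------------

def write_traces_csv(tm: TraceMatrix, path: str | Path) -> None:
    """Write traces as ``time,R,G,B`` CSV (UTF-8, '.' decimal)."""
    df = pd.DataFrame(
        {
            "time": tm.times,
            "R": tm.values[0],
            "G": tm.values[1],
            "B": tm.values[2],
        }
    )
    df.to_csv(path, index=False, float_format="%.12g")


def read_traces_csv(path: str | Path) -> TraceMatrix:
    """Read a ``time,R,G,B`` CSV back into a :class:`TraceMatrix`.

    The sampling rate is recovered from the median time step; time must be
    strictly increasing and cells must be numeric.
    """
    df = pd.read_csv(path)
    required = ["time", "R", "G", "B"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    for col in required:
        bad = np.flatnonzero(~np.isfinite(df[col].to_numpy(dtype=float)))
        if bad.size:
            raise ValueError(f"{path}: non-finite value in column {col!r}, row {bad[0]}")
    t = df["time"].to_numpy(dtype=float)
    dt = np.diff(t)
    if len(t) < 2 or np.any(dt <= 0):
        bad = int(np.flatnonzero(dt <= 0)[0]) + 1 if len(t) >= 2 else 0
        raise ValueError(f"{path}: time not strictly increasing at row {bad}")
    fs = 1.0 / float(np.median(dt))
    values = df[["R", "G", "B"]].to_numpy(dtype=float).T
    return TraceMatrix(values=values, fs=fs, t0=float(t[0]))


# --------------------------------------------------------------------------
# Ground-truth PPG
# --------------------------------------------------------------------------

def read_ppg_ground_truth(path: str | Path, dialect: str = "ubfc-3row") -> PPGRecord:
    """Parse a ground-truth PPG record.

    Dialects
    --------
    ``ubfc-3row``
        Three whitespace-separated text rows: waveform, heart rates (bpm),
        timestamps (s) — the pulse-oximeter export layout.
    ``csv``
        Columns ``timestamp,waveform,hr``.
    """
    path = Path(path)
    if dialect == "ubfc-3row":
        with open(path, "r", encoding="utf-8") as fh:
            rows = [ln for ln in fh.read().splitlines() if ln.strip()]
        if len(rows) != 3:
            raise ValueError(
                f"{path}: expected 3 non-empty rows (waveform/hr/timestamps), "
                f"got {len(rows)}"
            )
        try:
            parsed = [np.array([float(v) for v in row.split()]) for row in rows]
        except ValueError as exc:
            raise ValueError(f"{path}: unparseable number: {exc}") from exc
        waveform, hr, ts = parsed
        if not (len(waveform) == len(hr) == len(ts)):
            raise ValueError(
                f"{path}: row lengths differ: "
                f"{len(waveform)}/{len(hr)}/{len(ts)}"
            )
    elif dialect == "csv":
        df = pd.read_csv(path)
        missing = [c for c in ("timestamp", "waveform", "hr") if c not in df.columns]
        if missing:
            raise ValueError(f"{path}: missing columns {missing}")
        ts = df["timestamp"].to_numpy(dtype=float)
        waveform = df["waveform"].to_numpy(dtype=float)
        hr = df["hr"].to_numpy(dtype=float)
    else:
        raise ValueError(f"unknown ground-truth dialect {dialect!r}")
    dt = np.diff(ts)
    fs = 1.0 / float(np.median(dt)) if len(ts) > 1 and np.all(dt > 0) else 30.0
    return PPGRecord(waveform=waveform, hr=hr, timestamps=ts, fs=fs)


def write_ppg_ground_truth(rec: PPGRecord, path: str | Path, dialect: str = "ubfc-3row") -> None:
    """Serialize a :class:`PPGRecord` (inverse of :func:`read_ppg_ground_truth`)."""
    if dialect == "ubfc-3row":
        with open(path, "w", encoding="utf-8") as fh:
            for row in (rec.waveform, rec.hr, rec.timestamps):
                fh.write(" ".join(f"{v:.10g}" for v in row) + "\n")
    elif dialect == "csv":
        pd.DataFrame(
            {"timestamp": rec.timestamps, "waveform": rec.waveform, "hr": rec.hr}
        ).to_csv(path, index=False, float_format="%.10g")
    else:
        raise ValueError(f"unknown ground-truth dialect {dialect!r}")
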