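"""Image-stack I/O and wide-linescan extraction along dendrite polylines.

The acquisition this mirrors is single-channel epifluorescence time-lapse:
one grayscale frame every ``frame_interval`` seconds (30 s in the reference
protocol).  Fluorescence along a dendrite is read out as a *linescan*: a
multipoint polyline drawn along the dendrite, sampled at 1-px arc-length
steps, averaging intensity over a fixed width (18 px by convention)
perpendicular to the local path direction.

Coordinate convention: 0-based ``(row, col)``, pixel centers at integer
coordinates.  Bilinear interpolation is used at non-integer sample
positions; samples that would leave the frame raise :class:`GeometryError`
rather than clamping silently.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile
from scipy.ndimage import map_coordinates

from .errors import FormatError, GeometryError, ParameterError

__all__ = [
    "ImageStack",
    "DendritePath",
    "LinescanSeries",
    "read_stack",
    "write_stack",
    "extract_linescan",
    "linescan_to_frame",
]


@dataclass
class ImageStack:
    """Time-ordered stack of 2D grayscale frames.

    Parameters
    ----------
    frames : ndarray, shape (n_frames, H, W)
        Intensity frames in acquisition order.
    frame_interval : float
        Seconds between consecutive captures (> 0).
    bit_depth : int, optional
        Nominal camera bit depth; metadata only.
    """

    frames: np.ndarray
    frame_interval: float = 30.0
    bit_depth: int | None = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ParameterError(
                f"frames must be a (n_frames, H, W) array, got ndim={self.frames.ndim}"
            )
        if self.frames.shape[0] < 1:
            raise ParameterError("stack must contain at least one frame")
        if not self.frame_interval > 0:
            raise ParameterError("frame_interval must be > 0")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        """(H, W) of a single frame."""
        return self.frames.shape[1:]

    @property
    def times(self) -> np.ndarray:
        """Seconds since the first post-stimulation capture."""
        return np.arange(self.n_frames) * float(self.frame_interval)


@dataclass
class DendritePath:
    """Polyline annotation of a dendrite in pixel coordinates.

    ``control_points`` are ordered ``(row, col)`` vertices; ``width`` is the
    perpendicular averaging width in pixels (default 18); ``pixel_size`` is
    the lateral calibration in μm/px.
    """

    control_points: np.ndarray
    width: int = 18
    pixel_size: float = 0.2

    def __post_init__(self) -> None:
        pts = np.asarray(self.control_points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 2:
            raise ParameterError("control_points must be an (n >= 2, 2) array of (row, col)")
        if np.any(np.all(np.diff(pts, axis=0) == 0, axis=1)):
            raise ParameterError("consecutive control points must be distinct")
        if int(self.width) < 1:
            raise ParameterError("width must be >= 1 pixel")
        if not self.pixel_size > 0:
            raise ParameterError("pixel_size must be > 0")
        self.control_points = pts
        self.width = int(self.width)

    @property
    def arc_length(self) -> float:
        """Total polyline length in pixels."""
        return float(np.linalg.norm(np.diff(self.control_points, axis=0), axis=1).sum())

    @classmethod
    def from_csv(cls, path: str | Path, width: int = 18, pixel_size: float = 0.2) -> "DendritePath":
        """Load control points from a two-column (row, col) CSV."""
        df = pd.read_csv(path, comment="#")
        cols = [c for c in ("row", "col") if c in df.columns]
        pts = df[cols].to_numpy() if len(cols) == 2 else df.iloc[:, :2].to_numpy()
        return cls(pts, width=width, pixel_size=pixel_size)


@dataclass
class LinescanSeries:
    """Per-frame 1D fluorescence profiles along one dendrite.

    ``profiles`` has shape (n_frames, L) with one row per capture; ``times``
    are seconds since the first post-stimulation frame (``times[0] == 0``).
    """

    profiles: np.ndarray
    times: np.ndarray
    pixel_size: float = 0.2
    dendrite_id: str = "d0"
    condition: str = "vehicle"
    path: DendritePath | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.profiles = np.asarray(self.profiles, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.profiles.ndim != 2 or self.profiles.shape[1] < 1:
            raise ParameterError("profiles must be a (n_frames, L) array with L >= 1")
        if self.times.shape != (self.profiles.shape[0],):
            raise ParameterError("times must have one entry per frame")
        if np.any(np.diff(self.times) <= 0):
            raise ParameterError("times must be strictly increasing")
        if self.times[0] != 0:
            raise ParameterError("times[0] must be 0 (first post-stimulation capture)")
        if not self.pixel_size > 0:
            raise ParameterError("pixel_size must be > 0")

    @property
    def n_frames(self) -> int:
        return self.profiles.shape[0]

    @property
    def length(self) -> int:
        """Profile length L in pixels."""
        return self.profiles.shape[1]

    @property
    def length_um(self) -> float:
        return self.length * self.pixel_size


def read_stack(source: str | Path, frame_interval: float = 30.0) -> ImageStack:
    """Read a multi-page grayscale TIFF into an :class:`ImageStack`.

    Pages become frames in file order; intensities are preserved losslessly.
    RGB / multi-channel files and zero-page files are rejected.
    """
    source = Path(source)
    if not source.exists():
        raise FileNotFoundError(source)
    arr = tifffile.imread(source)
    if arr.size == 0:
        raise FormatError(f"{source}: no image pages")
    if arr.ndim == 2:
        arr = arr[None, ...]
    if arr.ndim != 3:
        raise FormatError(
            f"{source}: expected single-channel grayscale pages, got shape {arr.shape}"
        )
    if arr.shape[-1] in (3, 4) and arr.shape[-1] < min(arr.shape[:-1]):
        # heuristic: trailing small axis of 3/4 means RGB(A) pages
        raise FormatError(f"{source}: RGB/multi-channel TIFF is unsupported")
    bit_depth = arr.dtype.itemsize * 8 if np.issubdtype(arr.dtype, np.integer) else None
    return ImageStack(frames=arr, frame_interval=frame_interval, bit_depth=bit_depth)


def write_stack(stack: ImageStack, dest: str | Path, dtype: str = "uint16") -> Path:
    """Write an :class:`ImageStack` as a multi-page grayscale TIFF.

    Float frames are rounded and clipped into the target integer range.
    """
    dest = Path(dest)
    frames = stack.frames
    if np.issubdtype(frames.dtype, np.floating):
        info = np.iinfo(dtype)
        frames = np.clip(np.rint(frames), info.min, info.max).astype(dtype)
    tifffile.imwrite(dest, frames, photometric="minisblack")
    return dest


def _sample_coordinates(path: DendritePath) -> np.ndarray:
    """Arc-length sample coordinates for a polyline linescan.

    Returns an array of shape (L, width, 2) of (row, col) positions: L
    centers at unit arc-length spacing, each with ``width`` perpendicular
    offsets at unit spacing centered on the path (even widths straddle the
    centerline, e.g. offsets -8.5 ... +8.5 for width 18).
    """
    pts = path.control_points
    seg = np.diff(pts, axis=0)
    seg_len = np.linalg.norm(seg, axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])
    total = cum[-1]
    n_samples = int(np.floor(total)) + 1
    s = np.arange(n_samples, dtype=float)
    idx = np.clip(np.searchsorted(cum, s, side="right") - 1, 0, len(seg) - 1)
    frac = (s - cum[idx]) / seg_len[idx]
    centers = pts[idx] + frac[:, None] * seg[idx]
    tangent = seg[idx] / seg_len[idx, None]
    normal = np.stack([-tangent[:, 1], tangent[:, 0]], axis=1)
    offsets = np.arange(path.width, dtype=float) - (path.width - 1) / 2.0
    return centers[:, None, :] + offsets[None, :, None] * normal[:, None, :]


def extract_linescan(
    stack: ImageStack,
    path: DendritePath,
    dendrite_id: str = "d0",
    condition: str = "vehicle",
) -> LinescanSeries:
    """Extract a wide-linescan profile series along a dendrite polyline.

    For every frame the polyline is sampled at 1-px arc-length steps; at
    each step the intensity is averaged over ``path.width`` bilinear samples
    spaced 1 px apart along the local perpendicular.  Profile length is
    ``floor(arc length) + 1`` and does not depend on frame content.

    Raises
    ------
    GeometryError
        If any sample (path dilated by width/2) falls outside the frame,
        naming the first offending arc position.
    """
    coords = _sample_coordinates(path)  # (L, w, 2)
    H, W = stack.shape
    rows, cols = coords[..., 0], coords[..., 1]
    bad = (rows < 0) | (rows > H - 1) | (cols < 0) | (cols > W - 1)
    if np.any(bad):
        first = int(np.argwhere(bad.any(axis=1))[0, 0])
        raise GeometryError(
            f"linescan sample at arc position {first} px leaves the "
            f"{H}x{W} frame (path width {path.width})"
        )
    flat = coords.reshape(-1, 2).T  # (2, L*w)
    profiles = np.empty((stack.n_frames, coords.shape[0]), dtype=float)
    for t in range(stack.n_frames):
        vals = map_coordinates(
            stack.frames[t].astype(float), flat, order=1, mode="constant", cval=np.nan
        )
        profiles[t] = vals.reshape(coords.shape[:2]).mean(axis=1)
    return LinescanSeries(
        profiles=profiles,
        times=stack.times,
        pixel_size=path.pixel_size,
        dendrite_id=dendrite_id,
        condition=condition,
        path=path,
    )


def linescan_to_frame(series: LinescanSeries) -> pd.DataFrame:
    """Long-format view of a linescan series.

    Columns: dendrite_id, condition, frame, time_s, pixel, intensity.
    """
    n, L = series.profiles.shape
    return pd.DataFrame(
        {
            "dendrite_id": np.repeat(series.dendrite_id, n * L),
            "condition": np.repeat(series.condition, n * L),
            "frame": np.repeat(np.arange(n), L),
            "time_s": np.repeat(series.times, L),
            "pixel": np.tile(np.arange(L), n),
            "intensity": series.profiles.ravel(),
        }
    )
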