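"""Moving-average-quotient puncta detection on 1D fluorescence profiles.

The detector is deliberately simple and selection-bias-free: two moving
averages are computed along the dendrite profile — a short one (5 px, the
approximate minimum punctum size) and a long one (31 px, the local dendrite
region) — and their quotient is thresholded.  Positions where

    shortMA(x) / longMA(x) > 1.1

are flagged as peaks; each maximal run of contiguous flagged pixels is one
punctum.  Both averages are indexed by window-center pixel, and quotients
exist only where the full long window fits (15-px margins at each end carry
no detections); truncated edge windows would otherwise inflate quotients.

Because the quotient divides two local averages of the same profile, the
detector is invariant to any positive rescaling of the profile — per-frame
bleach correction cannot change what is detected — but *not* to additive
offsets, which shrink quotients toward 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import DegenerateInputError, ParameterError

__all__ = [
    "DetectionParams",
    "Punctum",
    "PunctaSet",
    "moving_average",
    "detect_puncta",
    "puncta_density",
    "puncta_to_frame",
]


@dataclass(frozen=True)
class DetectionParams:
    """Detector settings: window sizes in pixels and the quotient threshold.

    ``min_run_length`` (default 1 = off) optionally discards flagged runs
    shorter than the given number of pixels.
    """

    short_window: int = 5
    long_window: int = 31
    quotient_threshold: float = 1.1
    min_run_length: int = 1

    def __post_init__(self) -> None:
        if self.short_window < 3 or self.short_window % 2 == 0:
            raise ParameterError("short_window must be odd and >= 3")
        if self.long_window <= self.short_window or self.long_window % 2 == 0:
            raise ParameterError("long_window must be odd and > short_window")
        if not self.quotient_threshold > 1:
            raise ParameterError("quotient_threshold must be > 1")
        if self.min_run_length < 1:
            raise ParameterError("min_run_length must be >= 1")


@dataclass(frozen=True)
class Punctum:
    """One detected peak region, 0-based half-open [start, end) in px."""

    start: int
    end: int
    center: int
    center_quotient: float


@dataclass
class PunctaSet:
    """Detection result for one profile at one frame.

    ``positions`` are the pixel indices of valid quotient centers (where the
    long window fits); ``flags`` and ``quotients`` align with them.
    ``puncta`` are disjoint, sorted maximal runs of flagged pixels.
    """

    positions: np.ndarray
    quotients: np.ndarray
    flags: np.ndarray
    puncta: list[Punctum]
    profile_length: int

    @property
    def n_puncta(self) -> int:
        return len(self.puncta)

    @property
    def centers(self) -> np.ndarray:
        return np.array([p.center for p in self.puncta], dtype=int)


def moving_average(profile: np.ndarray, window: int) -> np.ndarray:
    """Valid-mode sliding mean: value *j* = mean(profile[j : j + window]).

    Output length is ``L - window + 1``; the first value averages the first
    ``window`` pixels, the next shifts by one pixel, and so on.
    """
    profile = np.asarray(profile, dtype=float)
    if profile.ndim != 1:
        raise ParameterError("profile must be 1D")
    if window < 1:
        raise ParameterError("window must be >= 1")
    if profile.size < window:
        raise ParameterError(
            f"profile of length {profile.size} is shorter than window {window}"
        )
    return np.convolve(profile, np.full(window, 1.0 / window), mode="valid")


def detect_puncta(profile: np.ndarray, params: DetectionParams = DetectionParams()) -> PunctaSet:
    """Flag peaks where the short/long moving-average quotient exceeds threshold.

    Both averages are aligned on window-center pixels; valid positions are
    those where the 31-px (long) window fits entirely.  Contiguous flagged
    positions form puncta; each punctum's center is the position of its
    maximal quotient.

    Raises
    ------
    ParameterError
        Profile shorter than the long window, or negative intensities.
    DegenerateInputError
        A long-window average is nonpositive where evaluated.
    """
    profile = np.asarray(profile, dtype=float)
    if profile.ndim != 1 or profile.size < params.long_window:
        raise ParameterError(
            f"profile must be 1D with length >= {params.long_window}"
        )
    if np.any(profile < 0):
        raise ParameterError("profile intensities must be >= 0")
    L = profile.size
    half_s = params.short_window // 2
    half_l = params.long_window // 2
    ma_s = moving_average(profile, params.short_window)
    ma_l = moving_average(profile, params.long_window)
    # center-aligned: valid centers x in [half_l, L - 1 - half_l]
    positions = np.arange(half_l, L - half_l)
    short_at = ma_s[positions - half_s]
    long_at = ma_l  # ma_l[j] is centered at j + half_l == positions[j]
    if np.any(long_at <= 0):
        x = int(positions[np.argwhere(long_at <= 0)[0, 0]])
        raise DegenerateInputError(f"long-window average is nonpositive at pixel {x}")
    quotients = short_at / long_at
    flags = quotients > params.quotient_threshold
    puncta: list[Punctum] = []
    if flags.any():
        padded = np.diff(np.concatenate([[0], flags.astype(int), [0]]))
        starts = np.flatnonzero(padded == 1)
        ends = np.flatnonzero(padded == -1)  # exclusive, in flag-array index
        for a, b in zip(starts, ends):
            if b - a < params.min_run_length:
                continue
            peak = a + int(np.argmax(quotients[a:b]))
            puncta.append(
                Punctum(
                    start=int(positions[a]),
                    end=int(positions[b - 1]) + 1,
                    center=int(positions[peak]),
                    center_quotient=float(quotients[peak]),
                )
            )
    return PunctaSet(
        positions=positions,
        quotients=quotients,
        flags=flags,
        puncta=puncta,
        profile_length=L,
    )


def puncta_density(puncta: "PunctaSet | int", path_length_px: float, pixel_size: float) -> float:
    """Puncta per μm of dendrite: n_puncta / (path length · pixel size).

    ``puncta`` may be a :class:`PunctaSet` or a plain count.
    """
    n = puncta.n_puncta if isinstance(puncta, PunctaSet) else int(puncta)
    if not path_length_px > 0:
        raise ParameterError("path_length_px must be > 0")
    if not pixel_size > 0:
        raise ParameterError("pixel_size must be > 0")
    if n < 0:
        raise ParameterError("punctum count must be >= 0")
    return n / (path_length_px * pixel_size)


def puncta_to_frame(
    puncta_by_frame: Sequence[PunctaSet],
    dendrite_id: str = "d0",
    times: np.ndarray | None = None,
) -> pd.DataFrame:
    """Serialize detections: one row per punctum, BED-like half-open coords."""
    rows = []
    for frame, ps in enumerate(puncta_by_frame):
        t = float(times[frame]) if times is not None else float("nan")
        for p in ps.puncta:
            rows.append(
                {
                    "dendrite_id": dendrite_id,
                    "frame": frame,
                    "time_s": t,
                    "start_px": p.start,
                    "end_px": p.end,
                    "center_px": p.center,
                    "center_quotient": p.center_quotient,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "dendrite_id", "frame", "time_s",
            "start_px", "end_px", "center_px", "center_quotient",
        ],
    )
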