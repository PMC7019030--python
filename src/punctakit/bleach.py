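"""First-frame-ratio photobleaching correction.

Each frame's overall fluorescence is compared to the first frame of the
time series to determine a normalizing ratio: ``ratio[t] = total(frame 0) /
total(frame t)``.  Multiplying frame *t* by its ratio restores every frame
total to the first-frame total exactly, which undoes any bleaching that
acts as a per-frame multiplicative factor.

"Overall fluorescence" is computed over the extracted linescan trace by
default (``scope='trace'``); whole-frame totals can be supplied instead via
``frame_totals`` (``scope='frame'``) when the caller has the full images.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import median_filter

from .errors import DegenerateInputError, ParameterError
from .imaging import LinescanSeries

__all__ = ["BleachCorrection", "bleach_correct", "ratios_to_frame"]


@dataclass
class BleachCorrection:
    """Per-frame normalizing ratios; ``ratios[0] == 1`` exactly."""

    ratios: np.ndarray
    reference_total: float

    def __post_init__(self) -> None:
        self.ratios = np.asarray(self.ratios, dtype=float)
        if self.ratios[0] != 1.0:
            raise ParameterError("ratios[0] must equal 1 exactly")
        if np.any(self.ratios <= 0):
            raise ParameterError("all ratios must be > 0")


def bleach_correct(
    series: LinescanSeries,
    scope: str = "trace",
    frame_totals: np.ndarray | None = None,
    smooth: bool = False,
) -> tuple[LinescanSeries, BleachCorrection]:
    """Normalize each frame to the first-frame total fluorescence.

    Parameters
    ----------
    series : LinescanSeries
        Extracted profiles, one row per frame.
    scope : {'trace', 'frame'}
        Where the "overall fluorescence level" is measured: over the
        extracted trace (default) or over whole-frame totals passed in
        ``frame_totals``.
    frame_totals : ndarray, optional
        Whole-image per-frame totals; required when ``scope='frame'``.
    smooth : bool
        Apply a 3-px median filter along each profile before computing
        totals and in the returned profiles.  Stands in for unspecified
        acquisition-software morphology filtering; off by default.

    Returns
    -------
    (LinescanSeries, BleachCorrection)
        Corrected copy of the series and the audit trail of ratios.

    Raises
    ------
    DegenerateInputError
        If any frame total is nonpositive (no division is attempted).
    """
    profiles = series.profiles
    if smooth:
        profiles = median_filter(profiles, size=(1, 3), mode="nearest")
    if scope == "trace":
        totals = profiles.sum(axis=1)
    elif scope == "frame":
        if frame_totals is None:
            raise ParameterError("scope='frame' requires frame_totals")
        totals = np.asarray(frame_totals, dtype=float)
        if totals.shape != (series.n_frames,):
            raise ParameterError("frame_totals must have one entry per frame")
    else:
        raise ParameterError(f"unknown bleach scope {scope!r} (use 'trace' or 'frame')")
    if np.any(totals <= 0):
        t = int(np.argwhere(totals <= 0)[0, 0])
        raise DegenerateInputError(f"frame {t} has nonpositive total fluorescence")
    ratios = totals[0] / totals
    ratios[0] = 1.0  # exact by contract
    corrected = LinescanSeries(
        profiles=ratios[:, None] * profiles,
        times=series.times,
        pixel_size=series.pixel_size,
        dendrite_id=series.dendrite_id,
        condition=series.condition,
        path=series.path,
    )
    return corrected, BleachCorrection(ratios=ratios, reference_total=float(totals[0]))


def ratios_to_frame(series: LinescanSeries, correction: BleachCorrection) -> pd.DataFrame:
    """Audit table of the correction: frame, time_s, ratio."""
    return pd.DataFrame(
        {
            "dendrite_id": series.dendrite_id,
            "frame": np.arange(series.n_frames),
            "time_s": series.times,
            "ratio": correction.ratios,
        }
    )
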