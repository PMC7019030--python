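"""Relative punctal fluorescence and translocation time series.

Translocation of a GFP-tagged kinase into synaptic puncta is read out as a
rise in *relative punctal fluorescence*: for each frame, the fluorescence
of each detected punctum is divided by the total fluorescence of that
frame (which also cancels per-frame multiplicative factors such as bleach
correction); the dendrite-level value is the mean over puncta; and the
resulting per-dendrite time series is normalized to its initial time
point, so every dendrite starts at 1.0 and a value of 1.5 at 360 s means a
50% rise in the punctal share of fluorescence.  Dendrites — not neurons —
are the unit of observation, and dendrite series are pooled per
experimental condition into a long-format table for the mixed-design
ANOVA.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .detect import PunctaSet
from .errors import AlignmentError, DegenerateInputError, NormalizationError, ParameterError
from .imaging import LinescanSeries

__all__ = [
    "TranslocationSeries",
    "punctal_fluorescence",
    "translocation_series",
    "pool_dendrites",
    "group_summary",
    "timepoint_table",
    "plot_timecourse",
]

logger = logging.getLogger(__name__)


@dataclass
class TranslocationSeries:
    """Per-dendrite relative punctal fluorescence vs time.

    ``rel_fluor[0] == 1`` exactly by construction; later values are the
    punctal fluorescence share relative to the initial frame.
    """

    dendrite_id: str
    times: np.ndarray
    rel_fluor: np.ndarray
    condition: str = "vehicle"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.rel_fluor = np.asarray(self.rel_fluor, dtype=float)
        if self.rel_fluor.shape != self.times.shape:
            raise ParameterError("rel_fluor and times must have equal length")
        if self.rel_fluor[0] != 1.0:
            raise ParameterError("rel_fluor[0] must equal 1 exactly")


def punctal_fluorescence(profile: np.ndarray, puncta: PunctaSet) -> np.ndarray:
    """Relative fluorescence of each punctum in one frame.

    Per punctum: summed profile intensity over its [start, end) region,
    divided by the total fluorescence of the frame.  An empty punctum set
    yields an empty array (not an error).
    """
    profile = np.asarray(profile, dtype=float)
    total = profile.sum()
    if puncta.n_puncta == 0:
        return np.empty(0, dtype=float)
    if not total > 0:
        raise DegenerateInputError("frame total fluorescence must be > 0")
    out = np.empty(puncta.n_puncta, dtype=float)
    for i, p in enumerate(puncta.puncta):
        if p.start < 0 or p.end > profile.size:
            raise ParameterError(f"punctum [{p.start}, {p.end}) exceeds profile bounds")
        out[i] = profile[p.start:p.end].sum() / total
    return out


def translocation_series(
    series: LinescanSeries,
    puncta_by_frame: Sequence[PunctaSet],
    condition: str | None = None,
) -> TranslocationSeries:
    """Dendrite-level translocation read-out from per-frame detections.

    For each frame the dendrite value is the mean relative punctal
    fluorescence over whatever puncta were detected at that frame; the
    series is then normalized to the frame-0 value.  Frames with no
    detected puncta after frame 0 yield NaN (and a debug log entry).

    Raises
    ------
    NormalizationError
        If frame 0 has no puncta — the dendrite cannot be normalized and
        should be excluded by the caller.
    """
    if len(puncta_by_frame) != series.n_frames:
        raise ParameterError("need exactly one PunctaSet per frame")
    values = np.full(series.n_frames, np.nan)
    for t, ps in enumerate(puncta_by_frame):
        rel = punctal_fluorescence(series.profiles[t], ps)
        if rel.size:
            values[t] = rel.mean()
        elif t > 0:
            logger.debug("dendrite %s: no puncta at frame %d", series.dendrite_id, t)
    if not np.isfinite(values[0]):
        raise NormalizationError(
            f"dendrite {series.dendrite_id}: no puncta at the initial frame; "
            "cannot normalize"
        )
    rel_fluor = values / values[0]
    rel_fluor[0] = 1.0  # exact by contract
    return TranslocationSeries(
        dendrite_id=series.dendrite_id,
        times=series.times,
        rel_fluor=rel_fluor,
        condition=condition if condition is not None else series.condition,
    )


def pool_dendrites(series_list: Sequence[TranslocationSeries]) -> pd.DataFrame:
    """Pool dendrite series into a long-format group table.

    Columns: condition, dendrite_id, time_s, rel_fluor.  All series must
    share identical time levels (the acquisition grid); a mismatch raises
    :class:`AlignmentError`.
    """
    if not series_list:
        raise ParameterError("series_list must be non-empty")
    ref = series_list[0].times
    for s in series_list[1:]:
        if s.times.shape != ref.shape or np.any(s.times != ref):
            raise AlignmentError(
                f"dendrite {s.dendrite_id} has a different time grid than "
                f"{series_list[0].dendrite_id}"
            )
    return pd.concat(
        [
            pd.DataFrame(
                {
                    "condition": s.condition,
                    "dendrite_id": s.dendrite_id,
                    "time_s": s.times,
                    "rel_fluor": s.rel_fluor,
                }
            )
            for s in series_list
        ],
        ignore_index=True,
    )


def group_summary(table: pd.DataFrame) -> pd.DataFrame:
    """Per-condition, per-time mean and standard error of rel_fluor."""
    g = table.groupby(["condition", "time_s"])["rel_fluor"]
    out = g.agg(mean="mean", sem=lambda x: x.std(ddof=1) / np.sqrt(len(x)), n="count")
    return out.reset_index()


def timepoint_table(table: pd.DataFrame, timepoints: Sequence[float]) -> pd.DataFrame:
    """Rows of the group table at exactly the requested time points.

    The canonical report read-outs are the early (90 s), mid (240 s) and
    late (360 s) time points.
    """
    times = set(table["time_s"].unique())
    missing = [t for t in timepoints if t not in times]
    if missing:
        raise AlignmentError(f"time points {missing} absent from the table")
    return table[table["time_s"].isin(timepoints)].copy()


def plot_timecourse(summary: pd.DataFrame, dest: str) -> str:
    """Plot mean ± SEM relative punctal fluorescence vs time per condition."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for cond, sub in summary.groupby("condition"):
        sub = sub.sort_values("time_s")
        ax.errorbar(sub["time_s"], sub["mean"], yerr=sub["sem"], label=str(cond),
                    marker="o", capsize=2)
    ax.set_xlabel("time post-stimulation (s)")
    ax.set_ylabel("relative punctal fluorescence")
    ax.axhline(1.0, color="0.7", lw=0.8, zorder=0)
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(dest, dpi=150)
    plt.close(fig)
    return dest
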