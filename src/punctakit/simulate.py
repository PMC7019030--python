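"""Synthetic linescan traces and image stacks with known puncta ground truth.

No raw microscopy from the reference protocol is publicly deposited, so this
module is the pipeline's data source for testing and benchmarking.  It
emulates the acquisition design of a local-glutamate translocation
experiment:

* diffuse dendritic baseline fluorescence,
* ~5-px-wide puncta whose amplitude rises along a sigmoid and plateaus by
  5–6 min post-stimulus (frames every 30 s, 13 frames covering 0–360 s),
* monotone multiplicative photobleaching of the whole frame,
* additive Gaussian pixel noise, clipped at zero.

The punctum amplitude trajectory is

    A(t) = a0 + (a_max - a0) / (1 + exp(-(t - t_half) / tau_rise))

where ``a0`` (``amplitude_init``) is the brightness of puncta already
present at the first post-stimulation capture — real dendrites show
pre-existing puncta that brighten, and the downstream normalization to the
initial frame requires detectable initial puncta — and ``a_max``
(``amplitude_max``) is the plateau fold-over-baseline.  The classic
zero-baseline sigmoid is the special case ``amplitude_init = 0``.

Determinism contract: one :class:`numpy.random.SeedSequence` per dataset;
dendrites consume spawned child streams in index order, so dendrite *i* is
reproducible independently of ``n_dendrites``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .errors import GeometryError, ParameterError
from .imaging import DendritePath, ImageStack, LinescanSeries

__all__ = [
    "SimParams",
    "SyntheticDataset",
    "simulate_linescan_dataset",
    "simulate_image_stack",
    "simulate_group_table",
    "simulate_rm_matrices",
    "sigmoid_amplitude",
    "punctum_shape",
    "traces_to_frame",
    "frame_to_traces",
    "write_traces_csv",
    "read_traces_csv",
]


@dataclass(frozen=True)
class SimParams:
    """Parameters of one simulated acquisition.

    Defaults reproduce the reference design: 13 frames at 30 s (0–360 s),
    puncta of full width 5 px on a 200-px dendrite, kinetics with midpoint
    150 s and slope scale 30 s so the plateau is reached within 5–6 min.

    ``puncta_positions=None`` draws ``n_puncta`` positions per dendrite
    (uniform, respecting edge margins and a minimum separation of 31 px so
    detection windows of neighbouring puncta do not overlap).
    """

    n_frames: int = 13
    frame_interval: float = 30.0
    profile_length: int = 200
    baseline: float = 100.0
    puncta_positions: tuple[int, ...] | None = (40, 100, 160)
    n_puncta: int = 3
    puncta_width: int = 5
    amplitude_init: float = 0.6
    amplitude_max: float = 2.0
    t_half: float = 150.0
    tau_rise: float = 30.0
    bleach_tau: float = math.inf
    noise_sd: float = 0.0
    pixel_size: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_frames < 2:
            raise ParameterError("n_frames must be >= 2")
        if self.profile_length < 31:
            raise ParameterError(
                "profile_length must be >= 31 (the long detection window must fit)"
            )
        if not self.baseline > 0:
            raise ParameterError("baseline must be > 0")
        if self.amplitude_max < 0 or self.amplitude_init < 0:
            raise ParameterError("amplitudes must be >= 0")
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be >= 0")
        if not self.frame_interval > 0:
            raise ParameterError("frame_interval must be > 0")
        if not self.pixel_size > 0:
            raise ParameterError("pixel_size must be > 0")
        if not self.bleach_tau > 0:
            raise ParameterError("bleach_tau must be > 0 (math.inf for no bleaching)")
        if self.puncta_positions is not None:
            object.__setattr__(self, "puncta_positions", tuple(int(p) for p in self.puncta_positions))
            lo, hi = self.puncta_width, self.profile_length - self.puncta_width
            for p in self.puncta_positions:
                if p < lo or p > hi:
                    raise ParameterError(
                        f"puncta position {p} violates edge margin "
                        f"[{lo}, {hi}] for width {self.puncta_width}"
                    )
        elif self.n_puncta < 1:
            raise ParameterError("n_puncta must be >= 1 when puncta_positions is None")

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval

    def bleach_factor(self, times: np.ndarray) -> np.ndarray:
        """Multiplicative whole-frame bleaching, exp(-t / bleach_tau)."""
        if math.isinf(self.bleach_tau):
            return np.ones_like(np.asarray(times, dtype=float))
        return np.exp(-np.asarray(times, dtype=float) / self.bleach_tau)


def sigmoid_amplitude(
    times: np.ndarray,
    amplitude_max: float,
    t_half: float,
    tau_rise: float,
    amplitude_init: float = 0.0,
) -> np.ndarray:
    """Punctum amplitude trajectory A(t), fold-over-baseline.

    Logistic rise from ``amplitude_init`` to ``amplitude_max`` with midpoint
    ``t_half`` and slope scale ``tau_rise`` (both seconds).  Nondecreasing
    for ``tau_rise > 0`` and ``amplitude_max >= amplitude_init``.
    """
    t = np.asarray(times, dtype=float)
    logistic = 1.0 / (1.0 + np.exp(-(t - t_half) / tau_rise))
    return amplitude_init + (amplitude_max - amplitude_init) * logistic


def punctum_shape(length: int, center: float, width: int) -> np.ndarray:
    """Unit-height spatial profile of one punctum.

    Gaussian with FWHM ``width`` px, truncated to zero beyond ±2·FWHM from
    the center.
    """
    x = np.arange(length, dtype=float)
    sigma = width / (2.0 * math.sqrt(2.0 * math.log(2.0)))
    g = np.exp(-0.5 * ((x - center) / sigma) ** 2)
    g[np.abs(x - center) > 2 * width] = 0.0
    return g


@dataclass
class SyntheticDataset:
    """Traces plus ground truth from one simulation run.

    ``truth`` has one row per (dendrite, punctum, frame):
    dendrite_id, condition, punctum_index, position_px, frame, time_s,
    amplitude (true fold-over-baseline A(t)).
    """

    traces: list[LinescanSeries]
    truth: pd.DataFrame
    params: SimParams


def _draw_positions(params: SimParams, rng: np.random.Generator) -> np.ndarray:
    if params.puncta_positions is not None:
        return np.asarray(params.puncta_positions, dtype=int)
    lo, hi = params.puncta_width, params.profile_length - params.puncta_width
    min_sep = 31  # keep detection windows of neighbours disjoint
    for _ in range(1000):
        pos = np.sort(rng.integers(lo, hi + 1, size=params.n_puncta))
        if params.n_puncta == 1 or np.all(np.diff(pos) >= min_sep):
            return pos
    raise ParameterError(
        f"could not place {params.n_puncta} puncta with separation {min_sep} "
        f"on a {params.profile_length}-px profile"
    )


def _noiseless_profiles(params: SimParams, positions: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Return (profiles (n_frames, L), amplitudes A(t)) without noise."""
    times = params.times
    amp = sigmoid_amplitude(
        times, params.amplitude_max, params.t_half, params.tau_rise, params.amplitude_init
    )
    shape = np.zeros(params.profile_length)
    for p in positions:
        shape += punctum_shape(params.profile_length, float(p), params.puncta_width)
    bleach = params.bleach_factor(times)
    profiles = bleach[:, None] * params.baseline * (1.0 + amp[:, None] * shape[None, :])
    return profiles, amp


def simulate_linescan_dataset(
    params: SimParams,
    n_dendrites: int,
    condition: str = "vehicle",
    id_prefix: str | None = None,
) -> SyntheticDataset:
    """Simulate linescan traces for ``n_dendrites`` dendrites.

    Each trace at frame *t* is ``bleach(t) · baseline · (1 + A(t) · shape(x))``
    plus additive Gaussian noise (SD ``noise_sd``), clipped at zero.  The
    truth table records each punctum's position and per-frame amplitude.
    Identical params (including seed) reproduce traces bit-identically.
    """
    if n_dendrites < 1:
        raise ParameterError("n_dendrites must be >= 1")
    prefix = id_prefix if id_prefix is not None else condition
    children = np.random.SeedSequence(params.seed).spawn(n_dendrites)
    traces: list[LinescanSeries] = []
    truth_rows: list[pd.DataFrame] = []
    times = params.times
    for i in range(n_dendrites):
        rng = np.random.default_rng(children[i])
        positions = _draw_positions(params, rng)
        profiles, amp = _noiseless_profiles(params, positions)
        if params.noise_sd > 0:
            profiles = profiles + rng.normal(0.0, params.noise_sd, size=profiles.shape)
            profiles = np.clip(profiles, 0.0, None)
        did = f"{prefix}-{i:03d}"
        traces.append(
            LinescanSeries(
                profiles=profiles,
                times=times,
                pixel_size=params.pixel_size,
                dendrite_id=did,
                condition=condition,
            )
        )
        k = len(positions)
        truth_rows.append(
            pd.DataFrame(
                {
                    "dendrite_id": np.repeat(did, k * params.n_frames),
                    "condition": np.repeat(condition, k * params.n_frames),
                    "punctum_index": np.repeat(np.arange(k), params.n_frames),
                    "position_px": np.repeat(positions, params.n_frames),
                    "frame": np.tile(np.arange(params.n_frames), k),
                    "time_s": np.tile(times, k),
                    "amplitude": np.repeat(amp[None, :], k, axis=0).ravel(),
                }
            )
        )
    truth = pd.concat(truth_rows, ignore_index=True)
    return SyntheticDataset(traces=traces, truth=truth, params=params)


def simulate_image_stack(
    params: SimParams,
    control_points: Sequence[Sequence[float]],
    image_shape: tuple[int, int],
    render_width: int = 18,
    background: float = 0.0,
) -> tuple[ImageStack, DendritePath]:
    """Render the 1D synthetic signal along a polyline into a 2D stack.

    Every pixel within ``render_width / 2`` px of the path takes the profile
    value of its nearest arc-length sample, so the dendrite band is uniform
    across its width; pixels further away hold ``background`` (≪ baseline).
    The same kinetics / bleach / noise model as the 1D traces applies
    (noise is per-pixel on the rendered frame).

    Returns the stack and the ground-truth :class:`DendritePath` (with
    ``width=render_width``) for extraction round-trips.
    """
    H, W = image_shape
    path = DendritePath(np.asarray(control_points, dtype=float), width=render_width,
                        pixel_size=params.pixel_size)
    pts = path.control_points
    half = render_width / 2.0
    if (pts[:, 0].min() < half or pts[:, 0].max() > H - 1 - half
            or pts[:, 1].min() < half or pts[:, 1].max() > W - 1 - half):
        raise GeometryError(
            f"path must stay >= {half} px from the border of a {H}x{W} frame"
        )
    rng = np.random.default_rng(np.random.SeedSequence(params.seed).spawn(1)[0])
    positions = _draw_positions(params, rng)
    # arc-length samples along the path, 1-px spacing, matching extraction
    seg = np.diff(pts, axis=0)
    seg_len = np.linalg.norm(seg, axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])
    n_samples = int(np.floor(cum[-1])) + 1
    s = np.arange(n_samples, dtype=float)
    idx = np.clip(np.searchsorted(cum, s, side="right") - 1, 0, len(seg) - 1)
    centers = pts[idx] + ((s - cum[idx]) / seg_len[idx])[:, None] * seg[idx]

    local_params = replace(params, profile_length=max(n_samples, 31),
                           puncta_positions=tuple(int(p) for p in positions))
    profiles, _ = _noiseless_profiles(local_params, positions)
    profiles = profiles[:, :n_samples]

    tree = cKDTree(centers)
    rr, cc = np.meshgrid(np.arange(H), np.arange(W), indexing="ij")
    pix = np.stack([rr.ravel(), cc.ravel()], axis=1).astype(float)
    dist, nearest = tree.query(pix)
    on_path = dist <= half
    bleach = params.bleach_factor(params.times)
    frames = np.empty((params.n_frames, H, W), dtype=float)
    for t in range(params.n_frames):
        frame = np.full(H * W, background * bleach[t], dtype=float)
        frame[on_path] = profiles[t][nearest[on_path]]
        if params.noise_sd > 0:
            frame = frame + rng.normal(0.0, params.noise_sd, size=frame.shape)
            frame = np.clip(frame, 0.0, None)
        frames[t] = frame.reshape(H, W)
    return ImageStack(frames=frames, frame_interval=params.frame_interval), path


def simulate_rm_matrices(
    n_per_condition: dict[str, int],
    plateaus: dict[str, float],
    n_frames: int = 13,
    frame_interval: float = 30.0,
    t_half: float = 150.0,
    tau_rise: float = 30.0,
    subject_sd: float = 0.15,
    residual_sd: float = 0.15,
    seed: int | np.random.Generator = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Simulate repeated-measures data as a (subjects × times) matrix.

    Subject trajectories follow the normalized sigmoid
    ``m_c(t) = 1 + (plateau_c - 1) · s01(t)`` (``s01(0) = 0`` and
    ``s01(t_max) = 1``) plus a Gaussian subject random intercept
    (SD ``subject_sd``) and i.i.d. residual noise (SD ``residual_sd``) —
    a compound-symmetric repeated-measures model with intraclass
    correlation ``subject_sd² / (subject_sd² + residual_sd²)`` (0.5 at the
    defaults).  The fast path for statistical calibration (type-I error,
    power) without the imaging layers.

    Returns ``(Y, groups, times)`` with condition labels per row.
    """
    if set(n_per_condition) != set(plateaus):
        raise ParameterError("n_per_condition and plateaus must share condition names")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    times = np.arange(n_frames) * frame_interval
    raw = 1.0 / (1.0 + np.exp(-(times - t_half) / tau_rise))
    s01 = (raw - raw[0]) / (raw[-1] - raw[0])
    blocks, labels = [], []
    for cond in sorted(n_per_condition):
        n = n_per_condition[cond]
        mean_traj = 1.0 + (plateaus[cond] - 1.0) * s01
        b = rng.normal(0.0, subject_sd, size=(n, 1))
        e = rng.normal(0.0, residual_sd, size=(n, n_frames))
        blocks.append(mean_traj[None, :] + b + e)
        labels.extend([cond] * n)
    return np.vstack(blocks), np.asarray(labels), times


def simulate_group_table(
    n_per_condition: dict[str, int],
    plateaus: dict[str, float],
    **kwargs,
) -> pd.DataFrame:
    """Long-format group table view of :func:`simulate_rm_matrices`.

    Columns condition, dendrite_id, time_s, rel_fluor — ready for the
    mixed-design ANOVA.
    """
    Y, groups, times = simulate_rm_matrices(n_per_condition, plateaus, **kwargs)
    n_frames = Y.shape[1]
    counters: dict[str, int] = {}
    rows = []
    for y, cond in zip(Y, groups):
        i = counters.get(cond, 0)
        counters[cond] = i + 1
        rows.append(
            pd.DataFrame(
                {
                    "condition": cond,
                    "dendrite_id": f"{cond}-{i:03d}",
                    "time_s": times,
                    "rel_fluor": y,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def traces_to_frame(traces: Sequence[LinescanSeries]) -> pd.DataFrame:
    """Long-format table of many traces (see :func:`imaging.linescan_to_frame`)."""
    from .imaging import linescan_to_frame

    return pd.concat([linescan_to_frame(s) for s in traces], ignore_index=True)


def frame_to_traces(df: pd.DataFrame, pixel_size: float = 0.2) -> list[LinescanSeries]:
    """Rebuild :class:`LinescanSeries` objects from a long-format traces table."""
    traces = []
    for did, sub in df.groupby("dendrite_id", sort=True):
        piv = sub.pivot(index="frame", columns="pixel", values="intensity").sort_index()
        times = sub.drop_duplicates("frame").sort_values("frame")["time_s"].to_numpy()
        condition = str(sub["condition"].iloc[0]) if "condition" in sub else "vehicle"
        traces.append(
            LinescanSeries(
                profiles=piv.to_numpy(),
                times=times,
                pixel_size=pixel_size,
                dendrite_id=str(did),
                condition=condition,
            )
        )
    return traces


def write_traces_csv(traces: Sequence[LinescanSeries], dest: str | Path) -> Path:
    """Write traces in long CSV format (dendrite_id, condition, frame, time_s, pixel, intensity)."""
    dest = Path(dest)
    traces_to_frame(traces).to_csv(dest, index=False)
    return dest


def read_traces_csv(source: str | Path, pixel_size: float = 0.2) -> list[LinescanSeries]:
    """Read traces written by :func:`write_traces_csv`."""
    return frame_to_traces(pd.read_csv(source, comment="#"), pixel_size=pixel_size)
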