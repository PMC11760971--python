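"""Centroid construction, metric calibration, smoothing and speed gating.

The processing order is fixed: confidence cutoff -> centroid -> metric
calibration -> gap interpolation -> low-pass filtering -> speed -> speed
gate.  Filtering is zero-phase (forward-backward) by default, the common
convention in gait analysis: a causal single pass would delay the track by
several frames and bias every speed-timing quantity downstream.  The
effective amplitude response of the zero-phase filter is the *square* of
the single-pass Butterworth response (gain 0.5, not 1/sqrt(2), at the
corner frequency).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal

from .config import PipelineConfig
from .io_pose import PoseFrameSeries, apply_pcutoff

logger = logging.getLogger(__name__)


@dataclass
class ArenaSpec:
    """Arena geometry and the pixel -> mm calibration.

    Scale factors are per-axis (the camera may foreshorten one axis);
    defaults correspond to a 185 x 80 mm arena filling the width of a
    cropped 720p frame (1280 px / 185 mm ~ 0.145 mm per pixel).
    """

    length_mm: float = 185.0
    width_mm: float = 80.0
    scale_x: float = 0.145
    scale_y: float = 0.145
    origin_px: tuple[float, float] = (0.0, 0.0)
    clamp_tolerance_mm: float = 5.0

    def __post_init__(self) -> None:
        if self.length_mm <= 0 or self.width_mm <= 0:
            raise ValueError("arena dimensions must be positive")
        if self.scale_x <= 0 or self.scale_y <= 0:
            raise ValueError("scale factors must be positive")


@dataclass
class Trajectory:
    """Single-animal centroid path with a per-frame validity mask."""

    x_mm: np.ndarray
    y_mm: np.ndarray
    valid: np.ndarray
    fps: float = 30.0

    def __post_init__(self) -> None:
        self.x_mm = np.asarray(self.x_mm, dtype=float)
        self.y_mm = np.asarray(self.y_mm, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if not (self.x_mm.shape == self.y_mm.shape == self.valid.shape):
            raise ValueError("x_mm, y_mm and valid must have identical shape")
        if self.fps <= 0:
            raise ValueError("fps must be > 0")

    @property
    def n_frames(self) -> int:
        return self.x_mm.shape[0]

    def copy(self) -> "Trajectory":
        return Trajectory(self.x_mm.copy(), self.y_mm.copy(), self.valid.copy(), self.fps)


@dataclass
class SpeedSeries:
    """Per-interval scalar speed; interval i spans frames i and i+1."""

    speed_mm_s: np.ndarray
    valid: np.ndarray
    fps: float = 30.0

    def __post_init__(self) -> None:
        self.speed_mm_s = np.asarray(self.speed_mm_s, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.speed_mm_s.shape != self.valid.shape:
            raise ValueError("speed and valid must have identical shape")


def compute_centroid(
    series: PoseFrameSeries, min_valid_landmarks: int = 2
) -> Trajectory:
    """Collapse body landmarks to their per-frame arithmetic mean (pixels).

    Antenna-tip landmarks are excluded.  Frames with fewer than
    ``min_valid_landmarks`` unmasked landmarks are marked invalid.
    """
    body = series.body_landmark_indices()
    if not body:
        raise ValueError("series has no body landmarks")
    x = series.x[:, body]
    y = series.y[:, body]
    ok = np.isfinite(x) & np.isfinite(y)
    count = ok.sum(axis=1)
    valid = count >= max(1, min_valid_landmarks)
    with np.errstate(invalid="ignore"):
        cx = np.where(ok, x, 0.0).sum(axis=1) / np.where(count > 0, count, 1)
        cy = np.where(ok, y, 0.0).sum(axis=1) / np.where(count > 0, count, 1)
    cx[~valid] = np.nan
    cy[~valid] = np.nan
    return Trajectory(x_mm=cx, y_mm=cy, valid=valid, fps=series.fps)


def calibrate(traj: Trajectory, arena: ArenaSpec) -> Trajectory:
    """Map pixel coordinates to arena-frame millimetres.

    ``x_mm = (x_px - origin_x) * scale_x`` (likewise y).  Points outside the
    arena rectangle are clamped to its boundary; excursions beyond
    ``clamp_tolerance_mm`` are logged as a calibration warning.
    """
    ox, oy = arena.origin_px
    x = (traj.x_mm - ox) * arena.scale_x
    y = (traj.y_mm - oy) * arena.scale_y
    with np.errstate(invalid="ignore"):
        over_x = np.clip(np.maximum(-x, x - arena.length_mm), 0, None)
        over_y = np.clip(np.maximum(-y, y - arena.width_mm), 0, None)
        excess = np.nanmax(np.where(traj.valid, np.maximum(over_x, over_y), 0.0), initial=0.0)
    if excess > 0:
        level = logging.WARNING if excess > arena.clamp_tolerance_mm else logging.INFO
        logger.log(
            level,
            "calibrated points up to %.2f mm outside the %g x %g mm arena; "
            "clamped to the boundary (tolerance %g mm)",
            excess, arena.length_mm, arena.width_mm, arena.clamp_tolerance_mm,
        )
        x = np.clip(x, 0.0, arena.length_mm)
        y = np.clip(y, 0.0, arena.width_mm)
    return Trajectory(x_mm=x, y_mm=y, valid=traj.valid.copy(), fps=traj.fps)


from functools import lru_cache


@lru_cache(maxsize=32)
def _butter_design(order: int, cutoff_hz: float, fps: float):
    sos = signal.butter(order, cutoff_hz, btype="low", fs=fps, output="sos")
    ba = signal.butter(order, cutoff_hz, btype="low", fs=fps)
    return sos, ba


def _valid_runs(valid: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, stop) index ranges of contiguous True runs."""
    idx = np.flatnonzero(np.diff(np.concatenate(([False], valid, [False])).astype(int)))
    return list(zip(idx[0::2], idx[1::2]))


def interpolate_gaps(traj: Trajectory, max_gap_frames: int = 15) -> Trajectory:
    """Bridge short invalid runs by linear interpolation.

    Only interior gaps of at most ``max_gap_frames`` frames flanked by valid
    frames on both sides are filled (and marked valid); longer gaps are left
    untouched and later split the track into independent filter segments.
    """
    out = traj.copy()
    if traj.valid.all() or not traj.valid.any():
        return out
    n = traj.n_frames
    starts_stops = _valid_runs(~traj.valid)
    starts = np.array([s for s, _ in starts_stops])
    stops = np.array([e for _, e in starts_stops])
    ok = (stops - starts <= max_gap_frames) & (starts > 0) & (stops < n)
    if not ok.any():
        return out
    # membership mask of all fillable gaps, then one linear interpolation
    # against the valid anchor frames
    edges = np.zeros(n + 1, dtype=int)
    np.add.at(edges, starts[ok], 1)
    np.add.at(edges, stops[ok], -1)
    fill = np.cumsum(edges[:-1]) > 0
    anchors = np.flatnonzero(traj.valid)
    t = np.flatnonzero(fill)
    out.x_mm[t] = np.interp(t, anchors, traj.x_mm[anchors])
    out.y_mm[t] = np.interp(t, anchors, traj.y_mm[anchors])
    out.valid[t] = True
    return out


def butterworth_smooth(
    traj: Trajectory,
    order: int = 2,
    cutoff_hz: float = 6.0,
    zero_phase: bool = True,
) -> Trajectory:
    """Low-pass each coordinate of each contiguous valid segment.

    Zero-phase mode runs the filter forward then backward (`filtfilt` with
    reflected padding of length 3*(2*order + 1)), so the magnitude response
    is the squared single-pass Butterworth response and the output has no
    lag.  Segments too short to filter (<= 3*order frames) pass through
    unchanged.
    """
    nyquist = traj.fps / 2.0
    if cutoff_hz >= nyquist:
        raise ValueError(
            f"filter cutoff {cutoff_hz} Hz must be below the Nyquist "
            f"frequency {nyquist} Hz"
        )
    sos, (b, a) = _butter_design(order, cutoff_hz, traj.fps)
    out = traj.copy()
    padlen = 3 * (2 * order + 1)
    for start, stop in _valid_runs(traj.valid):
        seg = stop - start
        if seg <= 3 * order:
            logger.info("segment of %d frames too short to filter; passed through", seg)
            continue
        for arr in (out.x_mm, out.y_mm):
            if zero_phase:
                arr[start:stop] = signal.filtfilt(
                    b, a, arr[start:stop], padlen=min(padlen, seg - 1)
                )
            else:
                arr[start:stop] = signal.sosfilt(sos, arr[start:stop])
    return out


def compute_speed(traj: Trajectory) -> SpeedSeries:
    """Euclidean inter-frame displacement times fps; valid iff both endpoints are."""
    dx = np.diff(traj.x_mm)
    dy = np.diff(traj.y_mm)
    valid = traj.valid[:-1] & traj.valid[1:]
    with np.errstate(invalid="ignore"):
        speed = np.hypot(dx, dy) * traj.fps
    speed = np.where(valid, speed, np.nan)
    return SpeedSeries(speed_mm_s=speed, valid=valid, fps=traj.fps)


def apply_speed_gate(
    traj: Trajectory, speeds: SpeedSeries, max_speed_mm_s: float = 230.0
) -> Trajectory:
    """Invalidate frames reached faster than the biological speed limit.

    Single pass over the precomputed speeds, strict inequality (exactly the
    threshold is kept); the *later* endpoint of an offending interval is
    removed.  The first frame can never be invalidated.
    """
    out = traj.copy()
    with np.errstate(invalid="ignore"):
        offending = speeds.valid & (speeds.speed_mm_s > max_speed_mm_s)
    out.valid[1:][offending] = False
    out.x_mm[1:][offending] = np.nan
    out.y_mm[1:][offending] = np.nan
    return out


def process_trajectory(
    series: PoseFrameSeries,
    arena: ArenaSpec,
    config: PipelineConfig | None = None,
) -> tuple[Trajectory, SpeedSeries, dict]:
    """Full kinematics chain from a raw pose series to gated speeds.

    Returns the processed trajectory, the speed series recomputed after
    gating (so downstream metrics see gated validity), and a processing log
    with per-stage frame counts.
    """
    cfg = config or PipelineConfig()
    if cfg.trim_start_s > 0:
        n0 = int(round(cfg.trim_start_s * series.fps))
        series = replace(
            series,
            x=series.x[n0:], y=series.y[n0:], likelihood=series.likelihood[n0:],
        )
    masked = apply_pcutoff(series, cfg.p_cutoff)
    traj = compute_centroid(masked, cfg.min_valid_landmarks)
    n_below_cutoff = int(np.sum(~traj.valid))
    traj = calibrate(traj, arena)
    traj = interpolate_gaps(traj, cfg.max_gap_frames)
    n_after_interp = int(np.sum(~traj.valid))
    traj = butterworth_smooth(
        traj, cfg.filter_order, cfg.filter_cutoff_hz, zero_phase=cfg.zero_phase
    )
    speeds = compute_speed(traj)
    traj = apply_speed_gate(traj, speeds, cfg.max_speed_mm_s)
    n_gated = int(np.sum(~traj.valid)) - n_after_interp
    if n_gated:
        speeds = compute_speed(traj)  # gating changed endpoint validity
    log = {
        "n_frames": series.n_frames,
        "n_invalid_after_cutoff": n_below_cutoff,
        "n_invalid_after_interpolation": n_after_interp,
        "n_gated": n_gated,
        "n_valid_final": int(np.sum(traj.valid)),
    }
    return traj, speeds, log
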