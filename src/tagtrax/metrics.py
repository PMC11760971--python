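"""The three behavioral traits of an open-field trial.

* average speed — summed inter-frame displacement divided by the number of
  intervals, expressed in mm/s;
* number of walks — maximal runs of inter-frame speed strictly above
  1 cm/s lasting at least 1 s ("continuous" means a single sub-threshold or
  invalid interval terminates a run);
* exploration — the number of distinct cells of an 18-cell partition of
  the arena floor visited by the centroid.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .io_pose import TrialManifest
from .kinematics import ArenaSpec, SpeedSeries, Trajectory


@dataclass(frozen=True)
class WalkBout:
    """One walk.  ``start`` and ``end`` are *interval* indices (inclusive);
    interval i spans frames i and i+1, so duration is (end - start + 1)/fps."""

    start_frame: int
    end_frame: int
    duration_s: float
    mean_speed_mm_s: float


@dataclass(frozen=True)
class ZoneGrid:
    """Equal-cell partition of the arena floor (rows x cols = n_zones)."""

    rows: int = 3
    cols: int = 6

    @property
    def n_zones(self) -> int:
        return self.rows * self.cols


@dataclass
class BehaviorSummary:
    individual_id: str
    tag_group: str
    tag_type: str
    block: str
    avg_speed_mm_s: float
    n_walks: int
    n_zones_explored: int
    n_valid_frames: int
    flags: str = ""

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def average_speed(
    traj: Trajectory, speeds: SpeedSeries, denominator: str = "valid"
) -> float:
    """Mean per-frame displacement expressed per second.

    ``denominator="valid"`` divides the summed valid displacement by the
    number of valid intervals (default: robust to masked frames);
    ``"total"`` divides by all intervals, the literal reading of "total
    number of frames".  Returns NaN (undefined-metric marker) when no
    interval is valid.
    """
    n_valid = int(speeds.valid.sum())
    if n_valid == 0:
        return float("nan")
    total = float(np.nansum(np.where(speeds.valid, speeds.speed_mm_s, 0.0)))
    n = n_valid if denominator == "valid" else speeds.valid.size
    return total / n


def detect_walks(
    speeds: SpeedSeries,
    walk_speed_mm_s: float = 10.0,
    walk_min_duration_s: float = 1.0,
    dip_tolerance_frames: int = 0,
) -> list[WalkBout]:
    """Maximal runs of supra-threshold movement lasting at least the minimum.

    Strict contiguity and a strict speed threshold by default: an interval
    with speed exactly at the threshold, below it, or invalid, terminates
    the run.  Duration is counted in intervals (a 1 s walk at 30 fps is 30
    intervals).  ``dip_tolerance_frames`` enables optional hysteresis:
    runs of *valid* sub-threshold intervals up to that length are absorbed
    into the surrounding bout (off by default; "continuously" is read
    literally).
    """
    fps = speeds.fps
    with np.errstate(invalid="ignore"):
        above = speeds.valid & (speeds.speed_mm_s > walk_speed_mm_s)
    if dip_tolerance_frames > 0:
        below = speeds.valid & ~above
        edges = np.flatnonzero(
            np.diff(np.concatenate(([False], below, [False])).astype(int))
        )
        for start, stop in zip(edges[0::2], edges[1::2]):
            interior = 0 < start and stop < above.size
            if interior and stop - start <= dip_tolerance_frames \
                    and above[start - 1] and above[stop]:
                above[start:stop] = True
    edges = np.flatnonzero(np.diff(np.concatenate(([False], above, [False])).astype(int)))
    bouts = []
    min_intervals = int(math.ceil(walk_min_duration_s * fps - 1e-9))
    for start, stop in zip(edges[0::2], edges[1::2]):
        n_int = stop - start
        if n_int < min_intervals:
            continue
        seg = speeds.speed_mm_s[start:stop]
        bouts.append(
            WalkBout(
                start_frame=int(start),
                end_frame=int(stop - 1),
                duration_s=n_int / fps,
                mean_speed_mm_s=float(seg.mean()),
            )
        )
    return bouts


def zones_explored(
    traj: Trajectory, arena: ArenaSpec, grid: ZoneGrid = ZoneGrid()
) -> int:
    """Count distinct grid cells visited by valid centroid positions.

    Cell assignment is ``(floor(y / cell_width), floor(x / cell_length))``;
    points on the arena's far edges belong to the last row/column, and
    positions are clipped to the arena rectangle first (filtering may leave
    sub-millimetre excursions past a wall).
    """
    if not traj.valid.any():
        return 0
    x = np.clip(traj.x_mm[traj.valid], 0.0, arena.length_mm)
    y = np.clip(traj.y_mm[traj.valid], 0.0, arena.width_mm)
    cell_len = arena.length_mm / grid.cols
    cell_wid = arena.width_mm / grid.rows
    col = np.minimum((x / cell_len).astype(int), grid.cols - 1)
    row = np.minimum((y / cell_wid).astype(int), grid.rows - 1)
    counts = np.bincount(row * grid.cols + col, minlength=grid.n_zones)
    return int(np.count_nonzero(counts))


def summarize_trial(
    manifest: TrialManifest,
    traj: Trajectory,
    speeds: SpeedSeries,
    arena: ArenaSpec,
    config: PipelineConfig | None = None,
) -> BehaviorSummary:
    """Bundle the three traits plus metadata for one individual's trial."""
    cfg = config or PipelineConfig()
    grid = ZoneGrid(rows=cfg.zone_rows, cols=cfg.zone_cols)
    avg = average_speed(traj, speeds, cfg.avg_speed_denominator)
    walks = detect_walks(speeds, cfg.walk_speed_mm_s, cfg.walk_min_duration_s)
    flags = "" if np.isfinite(avg) else "undefined_avg_speed"
    return BehaviorSummary(
        individual_id=manifest.individual_id,
        tag_group=manifest.tag_group,
        tag_type=manifest.tag_type,
        block=manifest.block,
        avg_speed_mm_s=float(avg),
        n_walks=len(walks),
        n_zones_explored=zones_explored(traj, arena, grid),
        n_valid_frames=int(traj.valid.sum()),
        flags=flags,
    )


def metrics_table(summaries: list[BehaviorSummary]) -> pd.DataFrame:
    """Per-study metrics table, one row per individual."""
    return pd.DataFrame([s.to_dict() for s in summaries])
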