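"""Synthetic open-field trials with known ground truth.

The generator emulates what the downstream pipeline assumes about its
input: a single animal in a 185 x 80 mm arena filmed at 30 fps, alternating
exponentially-distributed pauses and walk bouts, a correlated random walk
with wall-following tendency (thigmotaxis) during bouts, four body
landmarks rendered to pixels with temporally correlated sub-pixel jitter
and occasional likelihood dropout, and a multiplicative tag effect on
movement propensity.

Two generator properties are deliberate so that ground truth is
*identifiable* by the processing chain:

* paths are smooth in time (turning is a correlated, rate-limited process
  rather than white per-frame noise), so the mandated 6 Hz low-pass is
  nearly transparent to the true path;
* bout durations and bout speeds are resampled out of narrow guard bands
  around the walk-definition thresholds (1 s, 10 mm/s), so the
  +/- 1-2 frame threshold-crossing shifts that any smoothing introduces at
  bout edges cannot flip a bout's ground-truth label.

Null-group defaults are calibrated so simulated untagged individuals fall
in the observed range of real untagged animals (~0.6-1.5 mm/s average
speed, ~2-6 walks and ~5-8 zones per 20-min trial).
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal as _signal

from .config import PipelineConfig
from .io_pose import PoseFrameSeries, TrialManifest, write_manifest, write_pose_table
from .kinematics import ArenaSpec, Trajectory, compute_speed, process_trajectory
from .metrics import (
    BehaviorSummary,
    WalkBout,
    ZoneGrid,
    average_speed,
    detect_walks,
    metrics_table,
    summarize_trial,
    zones_explored,
)

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(f):
            return f

        return wrap if not (args and callable(args[0])) else args[0]


DEFAULT_LANDMARKS = (
    "prothorax_left",
    "prothorax_right",
    "cercus_left",
    "cercus_right",
)

#: body-frame landmark offsets (mm), x forward, y left; they sum to zero so
#: the landmark mean is exactly the body centroid
DEFAULT_OFFSETS = ((10.0, 7.0), (10.0, -7.0), (-10.0, 5.0), (-10.0, -5.0))


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic trial.

    Durations are means of exponential distributions; bout speed is gamma
    distributed across bouts (constant within a bout).  ``turning_sd_rad``
    is the heading diffusion in rad per sqrt(second), realised as an AR(1)
    angular-velocity process with correlation time ``turning_tau_s``.
    ``tag_speed_multiplier`` scales expected average speed: sqrt(effect)
    on the walk-initiation rate and sqrt(effect) on bout speed.
    """

    trial_duration_s: float = 1200.0
    fps: float = 30.0
    arena: ArenaSpec = field(default_factory=ArenaSpec)
    pause_duration_s: float = 240.0
    walk_duration_s: float = 8.0
    walk_speed_mm_s: float = 25.0
    walk_speed_shape: float = 4.0
    turning_sd_rad: float = 0.4
    turning_tau_s: float = 0.3
    thigmotaxis_weight: float = 0.7
    wall_zone_mm: float = 15.0
    max_turn_rad: float = 0.15
    wall_margin_mm: float = 1.0
    landmark_names: tuple[str, ...] = DEFAULT_LANDMARKS
    landmark_offsets_mm: tuple[tuple[float, float], ...] = DEFAULT_OFFSETS
    jitter_sd_px: float = 1.0
    jitter_tau_s: float = 1.0
    dropout_prob: float = 0.02
    likelihood_cutoff: float = 0.6
    tag_speed_multiplier: float = 1.0
    return_prob: float = 0.7
    reversal_rate_per_s: float = 0.1
    home_range_min_mm: float = 40.0
    home_range_max_mm: float = 90.0
    walk_threshold_mm_s: float = 10.0
    walk_min_duration_s: float = 1.0
    speed_guard_mm_s: float = 3.0
    duration_guard_s: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("trial_duration_s", "fps", "pause_duration_s",
                     "walk_duration_s", "walk_speed_mm_s", "walk_speed_shape",
                     "tag_speed_multiplier"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not 0.0 <= self.dropout_prob <= 1.0:
            raise ValueError("dropout_prob must be in [0, 1]")
        if not 0.0 <= self.thigmotaxis_weight <= 1.0:
            raise ValueError("thigmotaxis_weight must be in [0, 1]")

    def replace(self, **kwargs) -> "SimulationConfig":
        return dataclasses.replace(self, **kwargs)


@dataclass
class GroundTruth:
    """Noise-free truth for one simulated trial (oracle for recovery tests)."""

    true_path: Trajectory
    heading: np.ndarray
    true_bouts: list[WalkBout]
    true_avg_speed: float
    true_zones: int

    @property
    def true_n_walks(self) -> int:
        return len(self.true_bouts)


def _walk_core(x0, y0, theta0, step_lens, omega, rev, home_range, L, W, zone,
               thigmo, max_turn, margin, xs, ys, thetas):
    """Advance a walk bout step by step (numba-jitted when available).

    Near a wall the heading is steered toward the nearest wall tangent
    (the rotation sense closest to the current heading), with strength
    growing with wall proximity and with the closing component; the steer
    rate is capped at ``max_turn`` per frame so paths stay smooth.  The
    cap and the corner-escape zone scale with the step length, so fast
    bouts start turning earlier and may turn tighter near walls (a tight
    arc is still spectrally far below the smoothing band, unlike the
    instant specular reflection that remains only as a failsafe).

    Pacing: a smooth, rate-limited 180-degree turn is triggered either
    spontaneously (``rev``) or whenever the animal is more than
    ``home_range`` from the bout's start and still heading away — animals
    in these trials shuttle back and forth along a wall section rather
    than lapping the arena.
    """
    x = x0
    y = y0
    theta = theta0
    n = omega.shape[0]
    rev_angle = 0.0
    rev_sign = 1.0
    for i in range(n):
        step_len = step_lens[i]
        theta = theta + omega[i]
        # distances to the walls (used by several rules below)
        ex = x if x < L - x else L - x
        ey = y if y < W - y else W - y
        dmin0 = ex if ex < ey else ey
        # emergency turn cap: tighter turning allowed as clearance shrinks
        cap = 1.6 * step_len / (dmin0 if dmin0 > 0.5 else 0.5)
        if cap < max_turn:
            cap = max_turn
        elif cap > 0.5:
            cap = 0.5
        if rev_angle <= 0.0:
            trigger = rev[i]
            hx = x - x0
            hy = y - y0
            away = hx * math.cos(theta) + hy * math.sin(theta)
            if hx * hx + hy * hy > home_range * home_range and away > 0.0:
                trigger = True
            # corner escape: heading into both walls of a corner leaves no
            # smooth tangent, so U-turn out before the reflection failsafe
            cdx = math.cos(theta)
            cdy = math.sin(theta)
            into_x = cdx < 0.0 if x < L - x else cdx > 0.0
            into_y = cdy < 0.0 if y < W - y else cdy > 0.0
            czone = 22.0 * step_len
            if czone < zone:
                czone = zone
            if ex < czone and ey < czone and into_x and into_y:
                trigger = True
            if trigger:
                rev_angle = math.pi
                # U-turn through the interior: pick the rotation sense whose
                # mid-turn heading points toward the arena centre (works for
                # both wall-adjacent and corner-adjacent turns)
                cx = 0.5 * L - x
                cy = 0.5 * W - y
                s_away = -math.sin(theta) * cx + math.cos(theta) * cy
                rev_sign = 1.0 if s_away > 0.0 else -1.0
        in_reversal = rev_angle > 0.0
        if in_reversal:
            t = cap if cap < rev_angle else rev_angle
            theta += rev_sign * t
            rev_angle -= t
        dx = math.cos(theta)
        dy = math.sin(theta)
        # distance to the nearest wall and unit vector pointing at it
        d_left = x
        d_right = L - x
        d_bot = y
        d_top = W - y
        dmin = d_left
        wx = -1.0
        wy = 0.0
        if d_right < dmin:
            dmin = d_right
            wx = 1.0
            wy = 0.0
        if d_bot < dmin:
            dmin = d_bot
            wx = 0.0
            wy = -1.0
        if d_top < dmin:
            dmin = d_top
            wx = 0.0
            wy = 1.0
        if not in_reversal:  # reversal turn overrides wall steering
            dtheta = 0.0
            if dmin < zone:
                # thigmotaxis: gentle pull toward the nearest wall's tangent
                beta = 1.0 - dmin / zone
                tx = -wy
                ty = wx
                if dx * tx + dy * ty < 0.0:
                    tx = -tx
                    ty = -ty
                delta = math.atan2(ty, tx) - theta
                while delta > math.pi:
                    delta -= 2.0 * math.pi
                while delta < -math.pi:
                    delta += 2.0 * math.pi
                dtheta += beta * thigmo * 0.3 * delta
            # collision avoidance: steer along whichever wall (either axis)
            # is reached soonest, so corners are turned smoothly instead of
            # triggering the sharp reflection failsafe
            tti = 1e18
            awx = 0.0
            awy = 0.0
            if dx > 1e-9 and (L - x) / (step_len * dx) < tti:
                tti = (L - x) / (step_len * dx)
                awx = 1.0
                awy = 0.0
            if dx < -1e-9 and x / (step_len * -dx) < tti:
                tti = x / (step_len * -dx)
                awx = -1.0
                awy = 0.0
            if dy > 1e-9 and (W - y) / (step_len * dy) < tti:
                tti = (W - y) / (step_len * dy)
                awx = 0.0
                awy = 1.0
            if dy < -1e-9 and y / (step_len * -dy) < tti:
                tti = y / (step_len * -dy)
                awx = 0.0
                awy = -1.0
            if tti < 20.0:  # frames until impact
                beta_a = 1.0 - tti / 20.0
                tx = -awy
                ty = awx
                if dx * tx + dy * ty < 0.0:
                    tx = -tx
                    ty = -ty
                delta = math.atan2(ty, tx) - theta
                while delta > math.pi:
                    delta -= 2.0 * math.pi
                while delta < -math.pi:
                    delta += 2.0 * math.pi
                dtheta += beta_a * beta_a * delta
            if dtheta > cap:
                dtheta = cap
            elif dtheta < -cap:
                dtheta = -cap
            theta += dtheta
            dx = math.cos(theta)
            dy = math.sin(theta)
        xn = x + step_len * dx
        yn = y + step_len * dy
        if xn < margin or xn > L - margin:
            theta = math.pi - theta
            xn = x + step_len * math.cos(theta)
        if yn < margin or yn > W - margin:
            theta = -theta
            yn = y + step_len * math.sin(theta)
        if xn < margin:
            xn = margin
        elif xn > L - margin:
            xn = L - margin
        if yn < margin:
            yn = margin
        elif yn > W - margin:
            yn = W - margin
        x = xn
        y = yn
        xs[i] = x
        ys[i] = y
        thetas[i] = theta
    return theta


_walk_kernel = njit(cache=False)(_walk_core) if _HAVE_NUMBA else _walk_core


def _draw_bout_speed(rng: np.random.Generator, cfg: SimulationConfig, mean: float) -> float:
    """Gamma bout speed, resampled out of the threshold guard band."""
    shape = cfg.walk_speed_shape
    scale = mean / shape
    lo = cfg.walk_threshold_mm_s
    hi = lo + cfg.speed_guard_mm_s
    for _ in range(1000):
        v = rng.gamma(shape, scale)
        if not lo <= v < hi:
            return v
    return hi  # pathological configs only


def _draw_bout_duration(rng: np.random.Generator, cfg: SimulationConfig) -> float:
    """Exponential bout duration, resampled out of the 1 s guard band."""
    lo = cfg.walk_min_duration_s - cfg.duration_guard_s
    hi = cfg.walk_min_duration_s + cfg.duration_guard_s
    for _ in range(1000):
        d = rng.exponential(cfg.walk_duration_s)
        if not lo <= d < hi:
            return d
    return hi


def simulate_trajectory(
    config: SimulationConfig | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[Trajectory, GroundTruth]:
    """Generate one noise-free centroid trajectory plus its ground truth.

    The trial alternates pauses (stationary) and walk bouts; the tag
    multiplier scales walk-initiation rate and bout speed by sqrt(effect)
    each.  Ground truth is computed from the realised path with the same
    metric definitions the pipeline uses, so truncated or reflected bouts
    are labelled consistently.
    """
    cfg = config or SimulationConfig()
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    fps = cfg.fps
    n = int(round(cfg.trial_duration_s * fps))
    arena = cfg.arena
    s = math.sqrt(cfg.tag_speed_multiplier)
    pause_mean = cfg.pause_duration_s / s
    speed_mean = cfg.walk_speed_mm_s * s

    rho = math.exp(-1.0 / (fps * cfg.turning_tau_s))
    sd_omega = cfg.turning_sd_rad * math.sqrt((1.0 - rho) / ((1.0 + rho) * fps))

    m = cfg.wall_margin_mm
    x = np.empty(n + 1)
    y = np.empty(n + 1)
    heading = np.empty(n + 1)
    x[0] = rng.uniform(m + 5.0, arena.length_mm - m - 5.0)
    y[0] = rng.uniform(m + 5.0, arena.width_mm - m - 5.0)
    home_range = rng.uniform(cfg.home_range_min_mm, cfg.home_range_max_mm)
    theta = rng.uniform(-math.pi, math.pi)
    heading[0] = theta

    i = 0  # last filled frame index
    walking = False
    while i < n:
        remaining = n - i
        if not walking:
            dur = max(1, int(round(rng.exponential(pause_mean) * fps)))
            dur = min(dur, remaining)
            x[i + 1 : i + 1 + dur] = x[i]
            y[i + 1 : i + 1 + dur] = y[i]
            heading[i + 1 : i + 1 + dur] = theta
            i += dur
            walking = True
        else:
            d_s = _draw_bout_duration(rng, cfg)
            steps = int(round(d_s * fps))
            if steps > remaining:
                steps = remaining
                lo = cfg.walk_min_duration_s - cfg.duration_guard_s
                hi = cfg.walk_min_duration_s + cfg.duration_guard_s
                if lo <= steps / fps < hi:
                    # a truncated bout inside the guard band would have an
                    # ambiguous label; idle out the trial instead
                    x[i + 1 : n + 1] = x[i]
                    y[i + 1 : n + 1] = y[i]
                    heading[i + 1 : n + 1] = theta
                    i = n
                    walking = False
                    continue
            v = _draw_bout_speed(rng, cfg, speed_mean)
            # short acceleration/deceleration ramps keep the speed profile
            # smooth enough that the low-pass filter adds no spurious path
            # length at bout edges
            ramp = min(8, max(1, steps // 3))
            step_lens = np.full(steps, v / fps)
            up = np.arange(1, ramp + 1) / (ramp + 1.0)
            step_lens[:ramp] *= up
            step_lens[steps - ramp:] *= up[::-1]
            # pacing: most walks set off roughly back the way the previous
            # walk ended (edge-dwelling animals retrace the same wall
            # section); the rest strike out in a fresh direction
            if rng.random() < cfg.return_prob:
                theta = theta + math.pi + rng.normal(0.0, 0.5)
            else:
                theta = rng.uniform(-math.pi, math.pi)
            omega = np.empty(steps)
            eps = rng.standard_normal(steps)
            w = sd_omega * math.sqrt(1.0 - rho * rho)
            prev = rng.normal(0.0, sd_omega)
            for k in range(steps):  # short loop; bouts are a few hundred steps
                prev = rho * prev + w * eps[k]
                omega[k] = prev
            rev = rng.random(steps) < cfg.reversal_rate_per_s / fps
            xs = np.empty(steps)
            ys = np.empty(steps)
            thetas = np.empty(steps)
            theta = _walk_kernel(
                x[i], y[i], theta, step_lens, omega, rev, home_range,
                arena.length_mm, arena.width_mm, cfg.wall_zone_mm,
                cfg.thigmotaxis_weight, cfg.max_turn_rad, m, xs, ys, thetas,
            )
            x[i + 1 : i + 1 + steps] = xs
            y[i + 1 : i + 1 + steps] = ys
            heading[i + 1 : i + 1 + steps] = thetas
            i += steps
            walking = False

    traj = Trajectory(x_mm=x, y_mm=y, valid=np.ones(n + 1, dtype=bool), fps=fps)
    speeds = compute_speed(traj)
    bouts = detect_walks(speeds, cfg.walk_threshold_mm_s, cfg.walk_min_duration_s)
    truth = GroundTruth(
        true_path=traj,
        heading=heading,
        true_bouts=bouts,
        true_avg_speed=average_speed(traj, speeds, "valid"),
        true_zones=zones_explored(traj, arena, ZoneGrid()),
    )
    return traj, truth


def render_pose_table(
    traj: Trajectory,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    heading: np.ndarray | None = None,
) -> PoseFrameSeries:
    """Render a trajectory to a noisy multi-landmark pixel pose series.

    Landmarks sit at fixed body-frame offsets rotated by the heading,
    converted to pixels through the arena calibration; each landmark
    coordinate receives AR(1) Gaussian jitter (marginal sd
    ``jitter_sd_px``, correlation time ``jitter_tau_s`` — tracker error on
    near-identical frames is strongly autocorrelated, not white).
    Dropped-out landmarks get a likelihood below the confidence cutoff.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    if heading is None:
        heading = _heading_from_displacement(traj)
    arena = config.arena
    n = traj.n_frames
    offsets = np.asarray(config.landmark_offsets_mm, dtype=float)
    k = offsets.shape[0]
    cos = np.cos(heading)[:, None]
    sin = np.sin(heading)[:, None]
    # landmark = centroid + R(heading) @ offset, in-place to limit temporaries
    px = cos * offsets[:, 0]
    px -= sin * offsets[:, 1]
    px += traj.x_mm[:, None]
    px /= arena.scale_x
    px += arena.origin_px[0]
    py = sin * offsets[:, 0]
    py += cos * offsets[:, 1]
    py += traj.y_mm[:, None]
    py /= arena.scale_y
    py += arena.origin_px[1]
    if config.jitter_sd_px > 0:
        rho = math.exp(-1.0 / (config.fps * config.jitter_tau_s))
        # float32 is ample for sub-pixel noise and halves the cost here
        e = rng.standard_normal((n, 2 * k), dtype=np.float32)
        e *= config.jitter_sd_px * math.sqrt(1.0 - rho * rho)
        e[0] /= math.sqrt(1.0 - rho * rho)  # stationary start
        j = _signal.lfilter([1.0], [1.0, -rho], e, axis=0)
        px = px + j[:, :k]
        py = py + j[:, k:]
    u = rng.random((n, k))
    cut = config.likelihood_cutoff
    lik = cut + (1.0 - cut) * u
    if config.dropout_prob > 0:
        dropped = rng.random((n, k)) < config.dropout_prob
        # reuse the same uniform draw below the cutoff for dropped points
        lik[dropped] = cut * u[dropped]
    return PoseFrameSeries(
        landmark_names=list(config.landmark_names[:k]),
        x=px, y=py, likelihood=lik, fps=config.fps,
    )


def _heading_from_displacement(traj: Trajectory) -> np.ndarray:
    dx = np.diff(traj.x_mm, append=traj.x_mm[-1])
    dy = np.diff(traj.y_mm, append=traj.y_mm[-1])
    heading = np.arctan2(dy, dx)
    moving = np.hypot(dx, dy) > 1e-9
    # hold the last moving heading through pauses
    idx = np.where(moving, np.arange(traj.n_frames), -1)
    idx = np.maximum.accumulate(idx)
    heading = np.where(idx >= 0, heading[np.maximum(idx, 0)], 0.0)
    return heading


def individual_rng(master_seed: int, index: int) -> np.random.Generator:
    """Deterministic per-individual stream, regenerable in isolation."""
    return np.random.default_rng(np.random.SeedSequence((int(master_seed), int(index))))


@dataclass
class StudyTrial:
    manifest: TrialManifest
    series: PoseFrameSeries
    truth: GroundTruth


def _study_manifest(
    n_tagged: int, n_untagged: int, n_blocks: int, tag_type: str
) -> list[TrialManifest]:
    records = []
    groups = []
    for i in range(max(n_tagged, n_untagged)):
        if i < n_tagged:
            groups.append(("tagged", tag_type))
        if i < n_untagged:
            groups.append(("untagged", "none"))
    # per-group round-robin with a half-cycle offset between groups: blocks
    # end up near-equal in size and every block contains both groups (a
    # single interleaved round-robin would confound block with group
    # whenever n_blocks is even)
    counters = {"tagged": 0, "untagged": 0}
    offset = {"tagged": 0, "untagged": n_blocks // 2}
    for i, (group, ttype) in enumerate(groups):
        block = (counters[group] + offset[group]) % n_blocks
        counters[group] += 1
        records.append(
            TrialManifest(
                individual_id=f"ind{i:03d}",
                tag_group=group,
                tag_type=ttype,
                block=f"block{block}",
                pose_path=f"ind{i:03d}.csv",
            )
        )
    return records


def simulate_study(
    n_tagged: int = 15,
    n_untagged: int = 15,
    n_blocks: int = 4,
    effect: float = 1.0,
    config: SimulationConfig | None = None,
    seed: int = 0,
    out_dir: str | Path | None = None,
    tag_type: str = "marker",
):
    """Simulate a full two-group study.

    Individuals are interleaved across groups and assigned to blocks
    round-robin (so every block contains both groups); tagged individuals
    carry the multiplicative movement effect.  Per-individual random
    streams derive deterministically from the master seed.  If ``out_dir``
    is given, pose tables, the manifest and a ground-truth table are
    written there; the trials are returned either way.
    """
    cfg = config or SimulationConfig()
    records = _study_manifest(n_tagged, n_untagged, n_blocks, tag_type)
    trials = []
    truth_rows = []
    for i, rec in enumerate(records):
        mult = effect if rec.tag_group == "tagged" else 1.0
        icfg = cfg.replace(tag_speed_multiplier=cfg.tag_speed_multiplier * mult)
        rng = individual_rng(seed, i)
        traj, truth = simulate_trajectory(icfg, rng)
        series = render_pose_table(traj, icfg, rng, heading=truth.heading)
        trials.append(StudyTrial(manifest=rec, series=series, truth=truth))
        truth_rows.append(
            {
                "individual_id": rec.individual_id,
                "tag_group": rec.tag_group,
                "true_avg_speed_mm_s": truth.true_avg_speed,
                "true_n_walks": truth.true_n_walks,
                "true_n_zones": truth.true_zones,
            }
        )
    truth_df = pd.DataFrame(truth_rows)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for trial in trials:
            write_pose_table(trial.series, out / trial.manifest.pose_path)
        write_manifest([t.manifest for t in trials], out / "manifest.csv")
        truth_df.to_csv(out / "ground_truth.csv", index=False, float_format="%.9g")
    return trials, truth_df


def run_simulated_study(
    n_tagged: int = 15,
    n_untagged: int = 15,
    n_blocks: int = 4,
    effect: float = 1.0,
    config: SimulationConfig | None = None,
    pipeline_config: PipelineConfig | None = None,
    seed: int = 0,
    tag_type: str = "marker",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a study and push every trial through the full measurement
    chain (render -> confidence cutoff -> centroid -> calibration ->
    interpolation -> filter -> speed gate -> traits).

    Memory-lean: trials are processed one at a time and discarded.
    Returns (metrics table, ground-truth table).
    """
    cfg = config or SimulationConfig()
    pcfg = pipeline_config or PipelineConfig(p_cutoff=cfg.likelihood_cutoff)
    records = _study_manifest(n_tagged, n_untagged, n_blocks, tag_type)
    summaries = []
    truth_rows = []
    for i, rec in enumerate(records):
        mult = effect if rec.tag_group == "tagged" else 1.0
        icfg = cfg.replace(tag_speed_multiplier=cfg.tag_speed_multiplier * mult)
        rng = individual_rng(seed, i)
        traj, truth = simulate_trajectory(icfg, rng)
        series = render_pose_table(traj, icfg, rng, heading=truth.heading)
        processed, speeds, _ = process_trajectory(series, icfg.arena, pcfg)
        summaries.append(summarize_trial(rec, processed, speeds, icfg.arena, pcfg))
        truth_rows.append(
            {
                "individual_id": rec.individual_id,
                "tag_group": rec.tag_group,
                "true_avg_speed_mm_s": truth.true_avg_speed,
                "true_n_walks": truth.true_n_walks,
                "true_n_zones": truth.true_zones,
            }
        )
    return metrics_table(summaries), pd.DataFrame(truth_rows)
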