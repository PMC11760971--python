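"""Reading, validation and masking of pose-tracker output.

The on-disk dialect is the three-row-header CSV emitted by DeepLabCut-style
trackers (header rows: scorer / bodyparts / coords, one ``x``, ``y``,
``likelihood`` triple per landmark, one row per video frame).  An HDF5
container with the same logical schema is accepted as an alternate input.
Missing observations are represented as NaN coordinates; the tracker's
likelihoods are always preserved so confidence masking is reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

TAG_GROUPS = ("tagged", "untagged")
TAG_TYPES = ("rfid", "marker", "none")
MANIFEST_COLUMNS = ("individual_id", "tag_group", "tag_type", "block", "pose_path")

#: landmark-name substrings excluded from centroid computation by default
#: (antenna tips may be present in a table but carry no body-position signal)
NON_BODY_LANDMARKS = ("antenna",)


class PoseFormatError(ValueError):
    """Malformed pose table (header or cell contents)."""


@dataclass
class PoseFrameSeries:
    """Per-frame, per-landmark pixel positions with tracker confidence.

    ``x``, ``y`` and ``likelihood`` all have shape (n_frames, n_landmarks);
    image convention (y grows downward).  Masked observations are NaN in
    ``x``/``y`` with their original likelihood retained.
    """

    landmark_names: list[str]
    x: np.ndarray
    y: np.ndarray
    likelihood: np.ndarray
    fps: float = 30.0

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.likelihood = np.asarray(self.likelihood, dtype=float)
        if self.x.ndim == 1:
            self.x = self.x[:, None]
            self.y = self.y[:, None]
            self.likelihood = self.likelihood[:, None]
        if not (self.x.shape == self.y.shape == self.likelihood.shape):
            raise ValueError("x, y and likelihood must have identical shape")
        if self.x.shape[1] != len(self.landmark_names):
            raise ValueError("landmark_names length does not match data width")
        if len(set(self.landmark_names)) != len(self.landmark_names):
            raise ValueError("landmark_names must be unique")
        if self.fps <= 0:
            raise ValueError("fps must be > 0")
        finite = self.likelihood[np.isfinite(self.likelihood)]
        if finite.size and (finite.min() < 0 or finite.max() > 1):
            raise ValueError("likelihood values must lie in [0, 1]")

    @property
    def n_frames(self) -> int:
        return self.x.shape[0]

    @property
    def n_landmarks(self) -> int:
        return self.x.shape[1]

    def body_landmark_indices(self) -> list[int]:
        """Indices of landmarks used for the centroid (antenna tips excluded)."""
        return [
            i
            for i, name in enumerate(self.landmark_names)
            if not any(s in name.lower() for s in NON_BODY_LANDMARKS)
        ]


def read_pose_table(path: str | Path, fps: float = 30.0) -> PoseFrameSeries:
    """Read a DeepLabCut-style pose table (CSV or HDF5).

    The CSV must carry the three header rows (scorer, bodyparts, coords) and
    an ``x``, ``y``, ``likelihood`` column triple for every landmark; frame
    order is preserved.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix in (".h5", ".hdf5"):
        frame = pd.read_hdf(path)
    else:
        try:
            frame = pd.read_csv(
                path, header=[0, 1, 2], index_col=0, float_precision="round_trip"
            )
        except (ValueError, pd.errors.ParserError) as exc:
            raise PoseFormatError(f"{path}: cannot parse 3-row header: {exc}") from exc
    return _series_from_frame(frame, fps, str(path))


def _series_from_frame(frame: pd.DataFrame, fps: float, origin: str) -> PoseFrameSeries:
    if frame.columns.nlevels < 3:
        raise PoseFormatError(f"{origin}: expected 3 header rows (scorer/bodyparts/coords)")
    # drop the scorer level; landmark order follows first appearance
    cols = frame.columns
    bodyparts = list(dict.fromkeys(cols.get_level_values(-2)))
    data = {}
    for part in bodyparts:
        sub = frame.xs(part, axis=1, level=-2)
        sub.columns = sub.columns.get_level_values(-1)
        for coord in ("x", "y", "likelihood"):
            if coord not in sub.columns:
                raise PoseFormatError(
                    f"{origin}: landmark {part!r} is missing its {coord!r} column"
                )
        data[part] = sub
    n = len(frame)
    x = np.empty((n, len(bodyparts)))
    y = np.empty((n, len(bodyparts)))
    lik = np.empty((n, len(bodyparts)))
    for j, part in enumerate(bodyparts):
        for coord, out in (("x", x), ("y", y), ("likelihood", lik)):
            col = pd.to_numeric(data[part][coord], errors="coerce")
            raw = data[part][coord]
            bad = col.isna() & raw.notna()
            if bad.any():
                row = int(np.nonzero(bad.to_numpy())[0][0])
                raise PoseFormatError(
                    f"{origin}: non-numeric value {raw.iloc[row]!r} for "
                    f"{part}/{coord} at row {row}"
                )
            out[:, j] = col.to_numpy()
    return PoseFrameSeries(landmark_names=list(bodyparts), x=x, y=y, likelihood=lik, fps=fps)


def write_pose_table(
    series: PoseFrameSeries, path: str | Path, scorer: str = "tagtrax"
) -> None:
    """Write a series back to the three-row-header CSV dialect (or HDF5)."""
    path = Path(path)
    columns = pd.MultiIndex.from_tuples(
        [
            (scorer, part, coord)
            for part in series.landmark_names
            for coord in ("x", "y", "likelihood")
        ],
        names=["scorer", "bodyparts", "coords"],
    )
    blocks = []
    for j in range(series.n_landmarks):
        blocks.extend([series.x[:, j], series.y[:, j], series.likelihood[:, j]])
    frame = pd.DataFrame(np.column_stack(blocks), columns=columns)
    frame.index.name = None
    if path.suffix in (".h5", ".hdf5"):
        frame.to_hdf(path, key="pose")
    else:
        # %.17g round-trips IEEE doubles exactly
        frame.to_csv(path, float_format="%.17g")


def apply_pcutoff(series: PoseFrameSeries, p_cutoff: float = 0.6) -> PoseFrameSeries:
    """Mask landmark observations whose confidence falls below the cutoff.

    Strictly-below comparison: a likelihood exactly equal to ``p_cutoff`` is
    the minimum confidence *included* in the analysis.  Idempotent, and
    monotone in the cutoff.
    """
    if not 0.0 <= p_cutoff <= 1.0:
        raise ValueError(f"p_cutoff must be in [0, 1], got {p_cutoff}")
    below = series.likelihood < p_cutoff
    x = np.where(below, np.nan, series.x)
    y = np.where(below, np.nan, series.y)
    return replace(series, x=x, y=y, likelihood=series.likelihood.copy())


@dataclass(frozen=True)
class TrialManifest:
    """One experimental trial: who was filmed, with which tag, in which block."""

    individual_id: str
    tag_group: str
    tag_type: str
    block: str
    pose_path: str

    def __post_init__(self) -> None:
        if self.tag_group not in TAG_GROUPS:
            raise ValueError(
                f"unknown tag_group {self.tag_group!r}; allowed: {list(TAG_GROUPS)}"
            )
        if self.tag_type not in TAG_TYPES:
            raise ValueError(
                f"unknown tag_type {self.tag_type!r}; allowed: {list(TAG_TYPES)}"
            )


def read_manifest(path: str | Path) -> list[TrialManifest]:
    """Read a trial manifest CSV (individual_id, tag_group, tag_type, block, pose_path)."""
    table = pd.read_csv(path, dtype=str)
    missing = set(MANIFEST_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"{path}: manifest is missing columns {sorted(missing)}")
    dup = table["individual_id"][table["individual_id"].duplicated()]
    if len(dup):
        raise ValueError(f"{path}: duplicated individual_id {dup.iloc[0]!r}")
    records = [
        TrialManifest(
            individual_id=row.individual_id,
            tag_group=row.tag_group,
            tag_type=row.tag_type,
            block=row.block,
            pose_path=row.pose_path,
        )
        for row in table.itertuples()
    ]
    _check_block_coverage(records)
    return records


def _check_block_coverage(records: list[TrialManifest]) -> None:
    by_block: dict[str, set[str]] = {}
    for r in records:
        by_block.setdefault(r.block, set()).add(r.tag_group)
    for block, groups in by_block.items():
        if len(groups) < 2:
            logger.warning(
                "block %r contains only the %s group; it cannot separate the "
                "tag effect from the block effect",
                block,
                next(iter(groups)),
            )


def write_manifest(records: list[TrialManifest], path: str | Path) -> None:
    pd.DataFrame([r.__dict__ for r in records])[list(MANIFEST_COLUMNS)].to_csv(
        path, index=False
    )


def write_trajectory_csv(traj, path: str | Path) -> None:
    """Write a calibrated trajectory (frame, time_s, x_mm, y_mm, valid)."""
    n = traj.n_frames
    frame = pd.DataFrame(
        {
            "frame": np.arange(n),
            "time_s": np.arange(n) / traj.fps,
            "x_mm": traj.x_mm,
            "y_mm": traj.y_mm,
            "valid": traj.valid.astype(int),
        }
    )
    frame.to_csv(path, index=False, float_format="%.9g")


def read_trajectory_csv(path: str | Path, fps: float | None = None):
    from .kinematics import Trajectory

    table = pd.read_csv(path)
    if fps is None:
        dt = np.diff(table["time_s"].to_numpy())
        fps = 1.0 / float(np.median(dt)) if len(dt) else 30.0
        # time_s is written with finite precision; snap near-integer rates
        if abs(fps - round(fps)) < 0.01:
            fps = float(round(fps))
    return Trajectory(
        x_mm=table["x_mm"].to_numpy(float),
        y_mm=table["y_mm"].to_numpy(float),
        valid=table["valid"].to_numpy() > 0,
        fps=float(fps),
    )
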