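"""End-to-end orchestration: manifest -> trajectories -> metrics -> comparison.

``run_pipeline`` is deterministic for fixed inputs and config: the metrics
and comparison CSVs it writes are byte-identical across runs.  Every
report bundle embeds a RunRecord with the exact resolved configuration and
input checksums that produced it.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd

from . import __version__
from .config import PipelineConfig
from .io_pose import read_manifest, read_pose_table, write_trajectory_csv
from .kinematics import ArenaSpec, process_trajectory
from .metrics import metrics_table, summarize_trial
from .stats import plot_study, run_study

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    pass


@dataclass
class RunRecord:
    config_snapshot: dict
    arena: dict
    input_checksums: dict[str, str]
    version: str
    started_utc: str
    n_trials: int = 0
    failed_trials: list[str] = field(default_factory=list)

    def write(self, path: Path) -> None:
        path.write_text(json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(
    manifest_path: str | Path,
    out_dir: str | Path,
    config: PipelineConfig | None = None,
    arena: ArenaSpec | None = None,
    fps: float = 30.0,
    preset: str = "auto",
    make_figures: bool = False,
) -> dict:
    """Process every trial in a manifest and compare the tag groups.

    Per-trial failures are quarantined (the trial is skipped, the run
    continues) and reported at exit; a missing pose file is named in the
    error.  Returns a summary dict with output paths and the failure list.
    """
    manifest_path = Path(manifest_path)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "trajectories").mkdir(exist_ok=True)
    cfg = config or PipelineConfig()
    arena = arena or ArenaSpec()

    records = read_manifest(manifest_path)
    if not records:
        raise PipelineError("no trials: manifest is empty")
    checksums = {str(manifest_path): _sha256(manifest_path)}
    record = RunRecord(
        config_snapshot=cfg.to_dict(),
        arena=dataclasses.asdict(arena),
        input_checksums=checksums,
        version=__version__,
        started_utc=datetime.now(timezone.utc).isoformat(timespec="seconds"),
        n_trials=len(records),
    )

    summaries = []
    logs = {}
    for rec in records:
        pose_path = Path(rec.pose_path)
        if not pose_path.is_absolute():
            pose_path = manifest_path.parent / pose_path
        if not pose_path.exists():
            raise PipelineError(f"pose file not found: {pose_path}")
        try:
            checksums[str(pose_path)] = _sha256(pose_path)
            series = read_pose_table(pose_path, fps=fps)
            traj, speeds, log = process_trajectory(series, arena, cfg)
            write_trajectory_csv(traj, out / "trajectories" / f"{rec.individual_id}.csv")
            summaries.append(summarize_trial(rec, traj, speeds, arena, cfg))
            logs[rec.individual_id] = log
        except Exception as exc:  # quarantine, keep going
            logger.error("trial %s failed: %s", rec.individual_id, exc)
            record.failed_trials.append(rec.individual_id)

    if not summaries:
        raise PipelineError("every trial failed; nothing to compare")
    metrics = metrics_table(summaries)
    metrics_path = out / "metrics.csv"
    metrics.to_csv(metrics_path, index=False, float_format="%.9g")
    pd.DataFrame(logs).T.rename_axis("individual_id").to_csv(out / "processing_log.csv")

    comparisons, report = run_study(metrics, preset=preset, alpha=cfg.alpha)
    comparison_path = out / "comparison.csv"
    report.to_csv(comparison_path, index=False, float_format="%.9g")
    if make_figures:
        plot_study(metrics, out / "group_comparison.png")
    record.write(out / "run_record.json")

    return {
        "metrics": metrics_path,
        "comparison": comparison_path,
        "n_trials": len(records),
        "failed_trials": record.failed_trials,
        "comparisons": comparisons,
    }
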