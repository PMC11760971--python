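import numpy as np
import pandas as pd
import pytest

from tagtrax.config import PipelineConfig
from tagtrax.io_pose import PoseFrameSeries, write_pose_table
from tagtrax.kinematics import ArenaSpec, SpeedSeries, Trajectory


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def arena():
    return ArenaSpec()


def make_series(x, y, likelihood=None, names=None, fps=30.0):
    x = np.atleast_2d(np.asarray(x, float))
    y = np.atleast_2d(np.asarray(y, float))
    if x.shape[0] == 1 and x.shape[1] > 1 and names is None:
        pass
    if likelihood is None:
        likelihood = np.ones_like(x)
    if names is None:
        names = [f"lm{i}" for i in range(x.shape[1])]
    return PoseFrameSeries(landmark_names=list(names), x=x, y=y,
                           likelihood=np.asarray(likelihood, float), fps=fps)


def make_trajectory(x, y=None, valid=None, fps=30.0):
    x = np.asarray(x, float)
    if y is None:
        y = np.zeros_like(x)
    if valid is None:
        valid = np.ones_like(x, dtype=bool)
    return Trajectory(x_mm=x, y_mm=np.asarray(y, float), valid=np.asarray(valid, bool), fps=fps)


def make_speeds(values, valid=None, fps=30.0):
    values = np.asarray(values, float)
    if valid is None:
        valid = np.ones_like(values, dtype=bool)
    return SpeedSeries(speed_mm_s=values, valid=np.asarray(valid, bool), fps=fps)


def make_metrics_table(rng, n_tagged=10, n_untagged=10, n_blocks=2,
                       tag_shift=0.0, base=5.0, sd=1.0):
    """Random balanced metrics table for regression tests."""
    rows = []
    for i in range(n_tagged + n_untagged):
        group = "tagged" if i % 2 == 0 else "untagged"
        shift = tag_shift if group == "tagged" else 0.0
        rows.append({
            "individual_id": f"ind{i:03d}",
            "tag_group": group,
            "tag_type": "marker" if group == "tagged" else "none",
            "block": f"block{(i // 2) % n_blocks}",
            "avg_speed_mm_s": max(0.05, base + shift + rng.normal(0, sd)),
            "n_walks": int(rng.poisson(max(0.2, 4 + shift))),
            "n_zones_explored": int(np.clip(rng.poisson(max(0.2, 8 + shift)), 1, 18)),
            "n_valid_frames": 36000,
        })
    return pd.DataFrame(rows)


@pytest.fixture
def pose_csv(tmp_path, rng):
    """A small on-disk DeepLabCut-style table with two landmarks."""
    n = 40
    series = make_series(
        rng.uniform(100, 300, (n, 2)),
        rng.uniform(100, 300, (n, 2)),
        rng.uniform(0.2, 1.0, (n, 2)),
        names=["head", "tail"],
    )
    path = tmp_path / "pose.csv"
    write_pose_table(series, path)
    return path, series
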