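"""Pipeline configuration.

All thresholds of the processing chain live in one place so a run can be
reproduced from its config snapshot alone.  Defaults encode the standard
open-field tagging protocol: tracker confidence cutoff 0.6, second
order 6 Hz low-pass Butterworth on centroid coordinates, a 23 cm/s
biological speed gate, walks defined as >= 1 s of continuous movement above
1 cm/s, and an 18-zone partition of the arena floor.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import yaml


@dataclass
class PipelineConfig:
    """Tunable parameters of the full ingest -> metrics -> stats chain.

    Parameters
    ----------
    p_cutoff:
        Minimum per-landmark tracker confidence for a point to enter the
        analysis.  A likelihood exactly equal to the cutoff is kept.
    filter_order, filter_cutoff_hz:
        Order and corner frequency of the low-pass Butterworth applied to
        centroid coordinates (zero-phase by default, see kinematics).
    max_speed_mm_s:
        Biological speed gate: frames reached faster than this are removed
        (230 mm/s, the species' maximum recorded moving speed).
    walk_speed_mm_s, walk_min_duration_s:
        A walk bout is a maximal run of inter-frame speeds strictly above
        ``walk_speed_mm_s`` lasting at least ``walk_min_duration_s``.
    n_zones, zone_rows, zone_cols:
        Exploration grid.  ``zone_rows * zone_cols`` must equal ``n_zones``;
        3 x 6 best matches the 185:80 arena aspect ratio.
    max_gap_frames:
        Longest run of invalid frames bridged by linear interpolation
        (0.5 s at 30 fps); longer gaps split the track into independent
        filter segments.
    min_valid_landmarks:
        Minimum number of above-cutoff landmarks for a frame's centroid to
        be considered valid.  The default (4) requires every body landmark:
        a centroid averaged over a varying landmark subset jumps by roughly
        a third of the dropped landmark's body-frame offset whenever the
        tracker loses a point, which inflates path length enormously;
        frames with partial landmark loss are instead treated as gaps and
        bridged by interpolation.  Set to 2 to accept subset centroids.
    avg_speed_denominator:
        "valid" divides summed displacement by the number of valid
        intervals (default; robust to masked frames), "total" by all
        intervals.
    zero_phase:
        Forward-backward filtering (no lag, squared magnitude response).
    """

    p_cutoff: float = 0.6
    filter_order: int = 2
    filter_cutoff_hz: float = 6.0
    max_speed_mm_s: float = 230.0
    walk_speed_mm_s: float = 10.0
    walk_min_duration_s: float = 1.0
    n_zones: int = 18
    zone_rows: int = 3
    zone_cols: int = 6
    alpha: float = 0.05
    max_gap_frames: int = 15
    min_valid_landmarks: int = 4
    avg_speed_denominator: str = "valid"
    zero_phase: bool = True
    trim_start_s: float = 0.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_cutoff <= 1.0:
            raise ValueError(f"p_cutoff must be in [0, 1], got {self.p_cutoff}")
        if self.zone_rows * self.zone_cols != self.n_zones:
            raise ValueError(
                f"zone grid {self.zone_rows}x{self.zone_cols} does not tile "
                f"{self.n_zones} zones"
            )
        for name in ("filter_cutoff_hz", "max_speed_mm_s", "walk_speed_mm_s",
                     "walk_min_duration_s", "alpha"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.avg_speed_denominator not in ("valid", "total"):
            raise ValueError("avg_speed_denominator must be 'valid' or 'total'")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: Mapping[str, Any]) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def replace(self, **kwargs: Any) -> "PipelineConfig":
        """New config with ``kwargs`` overriding; None values are ignored."""
        updates = {k: v for k, v in kwargs.items() if v is not None}
        return dataclasses.replace(self, **updates)

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)


def resolve_config(
    config_file: str | Path | None = None, **overrides: Any
) -> PipelineConfig:
    """Built-in defaults < config file < explicit overrides."""
    cfg = PipelineConfig() if config_file is None else PipelineConfig.from_yaml(config_file)
    return cfg.replace(**overrides)
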