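"""Pipeline configuration.

All tunable thresholds and search ranges live here so that the CLI, the
library API and the tests share one source of defaults.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import yaml


@dataclass
class PipelineConfig:
    # Row-sum threshold for locating the torso start (raw sensor units).
    tv: float = 7000.0
    # Row-sum threshold used to anchor the caudal imprint edge at the last row.
    tv_bottom: float = 7000.0
    # Width (px) of the central band averaged into the sagittal profile z(j);
    # must be even, the band holds delta_iz + 1 columns.
    delta_iz: int = 30
    # Exhaustive alignment search: rotation in [-alpha_range, alpha_range]
    # degrees and translation in [-t_range, t_range] px, integer steps.
    alpha_range: int = 15
    t_range: int = 30
    # ROI template scale grid, coarse-to-fine.
    scale_min: float = 0.6
    scale_max: float = 1.4
    scale_step: float = 0.02
    scale_coarse_step: float = 0.1
    # Half-arc (rows) of the discrete-curvature window for the lateral
    # reference positions.
    curvature_window: int = 5
    # Parabolic sub-pixel refinement of the per-row canal minima.
    refine_canal_subpixel: bool = True
    # Start row of the centre-of-pressure deviation sum: "jts" or "jt".
    ts1_start: str = "jts"

    def __post_init__(self) -> None:
        if self.delta_iz % 2 != 0:
            raise ValueError("delta_iz must be even")
        if self.ts1_start not in ("jts", "jt"):
            raise ValueError("ts1_start must be 'jts' or 'jt'")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


DEFAULT_CONFIG = PipelineConfig()
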