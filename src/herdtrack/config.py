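"""Tracker configuration: one flat dataclass, YAML round-trippable.

Defaults follow the reference operating point of the system: a 350 px
motion gate at the native working resolution, 30-frame probation age,
30 crops per animal before the appearance classifier bootstraps, and a
30-frame (30 s at 1 fps) retrain interval.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .lifecycle import Thresholds

__all__ = ["TrackerConfig"]


@dataclass
class TrackerConfig:
    # association
    r_px: float = 350.0
    weights: dict = field(default_factory=lambda: {
        "location": 0.25, "color": 0.25, "texture": 0.25, "posterior": 0.25})
    max_cost: float = 0.8
    matcher: str = "hungarian"          # hungarian | greedy
    normalization: str = "frame_minmax"
    # lifecycle
    th_color: float = 4.5e-5
    th_texture: float = 0.011
    th_posterior: float = 17.0
    age_temp_frames: int = 30
    r_missing: float = 700.0            # 2 * r_px by convention
    max_missing_frames: int = 600
    # appearance model
    embedder: str = "stub"
    min_per_class: int = 30
    retrain_interval_frames: int = 30
    buffer_capacity: int = 200
    buffer_admit_max_cost: float = 0.5
    # texture
    cm_levels: int = 8
    cm_distance: int = 1
    cm_symmetric: bool = True
    color_space_moments: str = "cielab"
    color_space_texture: str = "ycbcr"
    # misc
    seed: int = 0

    def __post_init__(self):
        for name in ("r_px", "max_cost", "th_color", "th_texture",
                     "th_posterior", "age_temp_frames", "r_missing",
                     "min_per_class", "retrain_interval_frames"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def thresholds(self) -> Thresholds:
        return Thresholds(color=self.th_color, texture=self.th_texture,
                          posterior=self.th_posterior)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "TrackerConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
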