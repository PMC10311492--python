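"""Pipeline configuration: the tunable thresholds with their defaults, plus
lossless YAML round-tripping."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml


@dataclass
class PipelineConfig:
    """All knobs of the mapping pipeline.

    The two clinically fixed constants are the comminution volume threshold
    (fragments strictly below 1 cm^3 count as comminution) and the registration
    quality gate (maximum model-to-template surface distance of 5 mm,
    inclusive). The rest are numerical/plumbing parameters.
    """

    comminution_threshold: float = 1.0   # cm^3, strict <
    spacing_tolerance: float = 5.0       # mm, inclusive gate
    projection_cutoff: float = 5.0       # mm, discard radius for projection
    dilation_radius: float = 2.0         # mm, per-case line widening on surface
    connectivity: int = 26               # fragment labeling connectivity (6 or 26)
    alpha: float = 0.05                  # significance / normality gate level
    noise_floor: float = 0.01            # cm^3, discard specks below this
    seed: int = 7
    n_33A: int = 53
    n_33C: int = 21
    out_dir: str = "fracmap_out"
    # phantom geometry (mm); voxel spacing isotropic
    total_length: float = 439.0
    condylar_width: float = 82.0
    shaft_radius: float = 16.0
    voxel_spacing: float = 1.0
    notch_depth: float = 10.0

    def __post_init__(self) -> None:
        for name in ("comminution_threshold", "spacing_tolerance",
                     "projection_cutoff", "dilation_radius", "noise_floor",
                     "total_length", "condylar_width", "shaft_radius",
                     "voxel_spacing", "notch_depth"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.connectivity not in (6, 26):
            raise ValueError("connectivity must be 6 or 26")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")


def config_to_yaml(config: PipelineConfig) -> str:
    return yaml.safe_dump(dataclasses.asdict(config), sort_keys=True)


def save_config(config: PipelineConfig, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(config_to_yaml(config))
    return path


def load_config(path: str | Path) -> PipelineConfig:
    data = yaml.safe_load(Path(path).read_text()) or {}
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return PipelineConfig(**data)
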