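"""Pipeline configuration: dataclass schema with YAML round-tripping."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import ParameterError
from .flow import SolverConfig
from .marking import MaterialParams, WT_PARAMS
from .mesh import InjurySpec
from .segment import SegmentationParams


@dataclass
class GeometryParams:
    degree: int = 3
    n_rays: int = 180
    n_sub: int = 11
    smooth_window: int = 5


@dataclass
class MeshParams:
    length: float = 100.0
    diameter: float = 50.0
    h: float = 2.5
    L_ref: float = 3.0
    injury_center_x: float = 50.0
    injury_half_width: float = 10.0
    injury_depth: float = 4.0

    def injury(self) -> InjurySpec:
        return InjurySpec(center_x=self.injury_center_x,
                          half_width=self.injury_half_width,
                          depth=self.injury_depth)


@dataclass
class SceneParams:
    """Synthetic-scene defaults used when no real TIFF input is supplied."""

    image_shape: tuple[int, int] = (100, 200)   # 50 x 100 um at 0.5 um/px
    pixel_size: float = 0.5
    frame_interval: float = 0.55
    n_frames: int = 30
    base_axes: tuple[float, float] = (10.0, 8.0)
    growth_rate: float = 0.35
    saturation_frames: float | None = 20.0
    aspect_drift: float = 0.15
    core_fraction: float = 0.5
    center: tuple[float, float] | None = None
    rotation: float = 0.3
    mode: str = "growth"
    embolize_frame: int | None = None
    embolize_fraction: float = 0.5


@dataclass
class QuantParams:
    smooth_window: int = 5
    min_consecutive: int = 3
    peak_gap: int = 5
    lhs_samples: int = 30


@dataclass
class PipelineConfig:
    """Fully reproducible description of one pipeline run."""

    output_dir: str = "clotflow_out"
    input_tiffs: dict = field(default_factory=dict)   # channel -> path
    seed: int = 0
    scene: SceneParams = field(default_factory=SceneParams)
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    geometry: GeometryParams = field(default_factory=GeometryParams)
    mesh: MeshParams = field(default_factory=MeshParams)
    solver: SolverConfig = field(default_factory=SolverConfig)
    materials: MaterialParams = field(default_factory=lambda: WT_PARAMS)
    quant: QuantParams = field(default_factory=QuantParams)

    def validate(self) -> None:
        if self.mesh.length <= 0 or self.mesh.diameter <= 0 or self.mesh.h <= 0:
            raise ParameterError("mesh dimensions must be positive")
        if self.mesh.L_ref <= 0:
            raise ParameterError("L_ref must be positive")
        if self.geometry.n_sub < 1 or self.geometry.n_rays < 8:
            raise ParameterError("n_sub >= 1 and n_rays >= 8 required")
        if self.scene.n_frames < 2:
            raise ParameterError("scene must have at least 2 frames")
        # solver/material dataclasses validate themselves on construction

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
        return path

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)

        def _sub(key, klass):
            if key in d and isinstance(d[key], dict):
                sub = dict(d[key])
                for f in dataclasses.fields(klass):
                    if f.name in sub and isinstance(sub[f.name], list):
                        sub[f.name] = tuple(sub[f.name])
                d[key] = klass(**sub)

        _sub("scene", SceneParams)
        _sub("segmentation", SegmentationParams)
        _sub("geometry", GeometryParams)
        _sub("mesh", MeshParams)
        _sub("solver", SolverConfig)
        _sub("materials", MaterialParams)
        _sub("quant", QuantParams)
        cfg = cls(**d)
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def content_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]
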