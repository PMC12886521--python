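"""Pipeline configuration with lossless YAML round-tripping."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .protocol import StimulusProtocol
from .segmentation import SegmentationParams
from .synthetic import GroupSpec, NoiseModel, SessionDesign

__all__ = ["PipelineConfig", "load_config", "save_config"]


@dataclass
class PipelineConfig:
    """Everything a full synthetic-study run needs.

    The stimulation protocol, rendering noise, hierarchical session
    design, segmentation parameters, statistics factors, the global seed
    and the rendered frame size.  Serializes to YAML and back without
    loss, and hashes stably for the run manifest.
    """

    protocol: StimulusProtocol = field(default_factory=StimulusProtocol)
    noise: NoiseModel = field(default_factory=NoiseModel)
    design: SessionDesign = field(default_factory=SessionDesign)
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    stats_metric: str = "amplitude_pct"
    stats_factors: tuple[str, ...] = ("group",)
    frame_shape: tuple[int, int] = (160, 160)
    pixel_size_um: float = 0.4
    seed: int = 0

    def to_dict(self) -> dict:
        d = asdict(self)
        d["design"]["groups"] = [asdict(g) for g in self.design.groups]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        design = dict(d.get("design", {}))
        if "groups" in design:
            design["groups"] = tuple(GroupSpec(**g) for g in design["groups"])
        for tup_key in ("pas_per_mouse", "timepoints"):
            if tup_key in design:
                design[tup_key] = tuple(design[tup_key])
        kwargs = {
            "protocol": StimulusProtocol(**d.get("protocol", {})),
            "noise": NoiseModel(**d.get("noise", {})),
            "design": SessionDesign(**design),
            "segmentation": SegmentationParams(**d.get("segmentation", {})),
        }
        for f in fields(cls):
            if f.name in kwargs:
                continue
            if f.name in d:
                val = d[f.name]
                if f.name in ("stats_factors", "frame_shape"):
                    val = tuple(val)
                kwargs[f.name] = val
        return cls(**kwargs)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def save_config(config: PipelineConfig, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(yaml.safe_dump(config.to_dict(), sort_keys=True))
    return path


def load_config(path: str | Path) -> PipelineConfig:
    data = yaml.safe_load(Path(path).read_text()) or {}
    return PipelineConfig.from_dict(data)
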