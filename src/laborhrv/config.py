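"""Pipeline configuration with lossless YAML round-trip."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path
from typing import Optional

import yaml


@dataclass
class FilterConfig:
    cutoff_ehg: float = 5.0     # Hz
    cutoff_ecg: float = 0.5     # Hz
    order: int = 4

    def cutoff(self, modality: str) -> float:
        return self.cutoff_ehg if modality == "EHG" else self.cutoff_ecg


@dataclass
class DetectionConfig:
    min_height: float = 0.4     # fraction of normalized max
    refractory: float = 250.0   # ms


@dataclass
class SegmentConfig:
    duration: float = 300.0     # s
    quality_threshold: float = 0.05
    min_beats: int = 150


@dataclass
class EctopicConfig:
    dev_threshold: float = 0.2
    rri_min: float = 250.0      # ms
    rri_max: float = 2000.0     # ms


@dataclass
class SpectralConfig:
    fs_interp: float = 4.0      # Hz
    segment_s: float = 150.0
    overlap: float = 0.5
    detrend: str = "linear"


@dataclass
class StatsConfig:
    alpha: float = 0.05
    n_mc: int = 10_000
    bh_correct: bool = False


@dataclass
class PipelineConfig:
    """All tunables of the end-to-end pipeline, with a single seed."""

    filter: FilterConfig = field(default_factory=FilterConfig)
    detection: DetectionConfig = field(default_factory=DetectionConfig)
    segment: SegmentConfig = field(default_factory=SegmentConfig)
    ectopic: EctopicConfig = field(default_factory=EctopicConfig)
    spectral: SpectralConfig = field(default_factory=SpectralConfig)
    stats: StatsConfig = field(default_factory=StatsConfig)
    seed: int = 0

    def validate(self) -> None:
        if not (0 < self.detection.min_height <= 1):
            raise ValueError("min_height must lie in (0, 1]")
        if self.detection.refractory <= 0:
            raise ValueError("refractory must be positive")
        if self.segment.duration <= 0:
            raise ValueError("segment duration must be positive")
        if not (0 <= self.segment.quality_threshold <= 1):
            raise ValueError("quality_threshold must lie in [0, 1]")
        if not (0 < self.spectral.overlap < 1):
            raise ValueError("overlap must lie in (0, 1)")
        if not (0 < self.stats.alpha < 1):
            raise ValueError("alpha must lie in (0, 1)")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        kwargs = {}
        for f in fields(cls):
            if f.name not in d:
                continue
            if f.name == "seed":
                kwargs["seed"] = int(d["seed"])
            else:
                sub_cls = f.default_factory  # type: ignore[union-attr]
                kwargs[f.name] = sub_cls(**d[f.name])
        cfg = cls(**kwargs)
        cfg.validate()
        return cfg

    def to_yaml(self, path: Optional[str | Path] = None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, source: str | Path) -> "PipelineConfig":
        p = Path(source)
        text = p.read_text() if p.exists() else str(source)
        return cls.from_dict(yaml.safe_load(text))
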