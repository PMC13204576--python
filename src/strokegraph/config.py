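"""Pipeline configuration: nested dataclasses with exact YAML round-tripping."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, fields

import yaml

from .errors import ConfigurationError
from .model import ModelConfig, TrainConfig
from .preprocess import PreprocessConfig

__all__ = ["GraphConfig", "EvalConfig", "PathsConfig", "PipelineConfig"]


@dataclass
class GraphConfig:
    """Graph-construction block: ~100 zones, adaptive Gaussian bandwidth."""

    n_zones: int = 100
    compactness: float = 0.3
    sigma: float | None = None  # None = mean neighbor centroid distance
    label_threshold: float = 0.5
    feature_mode: str = "hist16"


@dataclass
class EvalConfig:
    k: int = 10
    snr_grid: tuple[float, ...] = (-4, -3, -2, -1, 0, 1, 2, 3, 4, 5)
    run_sweep: bool = False


@dataclass
class PathsConfig:
    data_manifest: str = ""   # empty = generate a phantom cohort on the fly
    out_dir: str = "artifacts"


@dataclass
class PipelineConfig:
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    graph: GraphConfig = field(default_factory=GraphConfig)
    model: ModelConfig = field(default_factory=ModelConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    eval: EvalConfig = field(default_factory=EvalConfig)
    paths: PathsConfig = field(default_factory=PathsConfig)
    seed: int = 0
    phantom_patients: int = 10  # used only when no data manifest is given

    def to_dict(self) -> dict:
        def convert(obj):
            if isinstance(obj, dict):
                return {k: convert(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [convert(v) for v in obj]
            return obj

        return convert(asdict(self))

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        def build(klass, sub):
            kwargs = {}
            for f in fields(klass):
                if f.name not in sub:
                    continue
                v = sub[f.name]
                if isinstance(v, list):
                    v = tuple(v)
                kwargs[f.name] = v
            return klass(**kwargs)

        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        sub_types = {"preprocess": PreprocessConfig, "graph": GraphConfig,
                     "model": ModelConfig, "train": TrainConfig,
                     "eval": EvalConfig, "paths": PathsConfig}
        kwargs = {}
        for key, val in d.items():
            if key in sub_types:
                kwargs[key] = build(sub_types[key], val)
            else:
                kwargs[key] = val
        return cls(**kwargs)

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))
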