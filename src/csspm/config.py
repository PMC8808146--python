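"""Structured run configuration with lossless YAML round-tripping."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .benchmark import BenchmarkConfig
from .evaluation import AlarmConfig, ScoringConfig
from .network import ModelConfig
from .preprocessing import LabelingRules, StftConfig
from .synthetic import SyntheticConfig
from .trainer import TrainConfig

__all__ = ["RunConfig", "load_config", "save_config"]

_SECTIONS = {
    "synthetic": SyntheticConfig,
    "rules": LabelingRules,
    "stft": StftConfig,
    "model": ModelConfig,
    "train": TrainConfig,
    "alarm": AlarmConfig,
    "scoring": ScoringConfig,
}


def _coerce(cls, data: dict):
    """Rebuild a config dataclass from plain YAML types (lists -> tuples
    where the field default is a tuple)."""
    kwargs = {}
    for f in dataclasses.fields(cls):
        if f.name not in data:
            continue
        v = data[f.name]
        default = (f.default if f.default is not dataclasses.MISSING
                   else f.default_factory() if f.default_factory is not dataclasses.MISSING
                   else None)
        if isinstance(default, tuple) and isinstance(v, list):
            v = tuple(v)
        elif isinstance(default, list) and v and isinstance(v[0], list):
            v = [tuple(e) for e in v]
        kwargs[f.name] = v
    return cls(**kwargs)


def _plain(obj):
    if dataclasses.is_dataclass(obj):
        return {f.name: _plain(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    return obj


@dataclass
class RunConfig:
    """All pipeline sections plus the global seed and output directory.

    Section defaults equal the reference settings (sigma=0.15, lr 5e-4,
    omega_max=30, tau=30, alpha=0.6, k=8/n=10, SOP 30 min, SPH 5 min, ...).
    """

    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    rules: LabelingRules = field(default_factory=LabelingRules)
    stft: StftConfig = field(default_factory=StftConfig)
    model: ModelConfig = field(default_factory=ModelConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    alarm: AlarmConfig = field(default_factory=AlarmConfig)
    scoring: ScoringConfig = field(default_factory=ScoringConfig)
    seed: int = 0
    output_dir: str = "runs"

    def to_dict(self) -> dict:
        out = {name: _plain(getattr(self, name)) for name in _SECTIONS}
        out["seed"] = self.seed
        out["output_dir"] = self.output_dir
        return out

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        kwargs = {}
        for name, scls in _SECTIONS.items():
            if name in data:
                kwargs[name] = _coerce(scls, data[name])
        for key in ("seed", "output_dir"):
            if key in data:
                kwargs[key] = data[key]
        return cls(**kwargs)


def save_config(path: str | Path, cfg: RunConfig) -> None:
    Path(path).write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=True))


def load_config(path: str | Path) -> RunConfig:
    return RunConfig.from_dict(yaml.safe_load(Path(path).read_text()))


def benchmark_config_from_run(cfg: RunConfig) -> BenchmarkConfig:
    """Benchmark conditions derived from a run config (model picked per data)."""
    return BenchmarkConfig(
        synthetic=cfg.synthetic, rules=cfg.rules, stft=cfg.stft,
        model=None, train=cfg.train, alarm=cfg.alarm, scoring=cfg.scoring,
    )
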