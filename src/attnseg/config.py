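"""Run configuration: a strict YAML/JSON-backed view over the per-module
dataclass configs.  Unknown keys are rejected with the offending field named;
an empty file yields all defaults; dump(load(cfg)) is a fixed point."""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field, fields
from pathlib import Path

import yaml

from .nn.model import NetworkCfg
from .phantom import PhantomSpec
from .postprocess import PostprocessCfg
from .preprocess import AugmentCfg, PreprocessCfg
from .training import TrainCfg


@dataclass
class DataCfg:
    """Phantom dataset generation settings for a run."""

    n_patients: int = 10
    slices_per_patient: int = 4
    image_size: int = 64
    scenario: str = "default"
    n_lesions: int = 1
    lesion_radius_min: int = 6
    lesion_radius_max: int = 14
    contrast: float = 0.4
    noise_sd: float = 0.03
    seed: int = 0

    def to_spec(self) -> PhantomSpec:
        """Explicit fields here override the scenario preset."""
        return PhantomSpec.for_scenario(
            self.scenario,
            image_size=self.image_size,
            n_lesions=self.n_lesions,
            lesion_radius_range=(self.lesion_radius_min, self.lesion_radius_max),
            contrast=self.contrast,
            noise_sd=self.noise_sd,
            seed=self.seed,
        )


@dataclass
class RunConfig:
    data: DataCfg = field(default_factory=DataCfg)
    preprocess: PreprocessCfg = field(default_factory=PreprocessCfg)
    network: NetworkCfg = field(default_factory=NetworkCfg)
    train: TrainCfg = field(default_factory=TrainCfg)
    postprocess: PostprocessCfg = field(default_factory=PostprocessCfg)


def _build(cls, data: dict, path: str):
    if not isinstance(data, dict):
        raise ValueError(f"config section '{path}' must be a mapping")
    valid = {f.name: f for f in fields(cls)}
    kwargs = {}
    for key, value in data.items():
        if key not in valid:
            raise ValueError(f"unknown config field '{path}.{key}'")
        ftype = valid[key].type
        if key == "augment" and isinstance(value, dict):
            value = _build(AugmentCfg, value, f"{path}.{key}")
        if isinstance(value, list):
            value = tuple(value)
        kwargs[key] = value
    try:
        return cls(**kwargs)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"invalid config section '{path}': {exc}") from exc


_SECTIONS = {
    "data": DataCfg,
    "preprocess": PreprocessCfg,
    "network": NetworkCfg,
    "train": TrainCfg,
    "postprocess": PostprocessCfg,
}


def config_from_dict(data: dict | None) -> RunConfig:
    data = data or {}
    if not isinstance(data, dict):
        raise ValueError("top-level config must be a mapping")
    unknown = set(data) - set(_SECTIONS)
    if unknown:
        raise ValueError(f"unknown config section(s): {sorted(unknown)}")
    return RunConfig(
        **{name: _build(cls, data.get(name, {}), name) for name, cls in _SECTIONS.items()}
    )


def load_config(path) -> RunConfig:
    """Load a YAML (or JSON) run config; empty file -> all defaults."""
    text = Path(path).read_text()
    data = yaml.safe_load(text) if text.strip() else {}
    return config_from_dict(data)


def config_to_dict(cfg: RunConfig) -> dict:
    def clean(obj):
        if dataclasses.is_dataclass(obj):
            return {f.name: clean(getattr(obj, f.name)) for f in fields(obj)}
        if isinstance(obj, tuple):
            return [clean(v) for v in obj]
        return obj

    return clean(cfg)


def dump_config(cfg: RunConfig, path) -> None:
    path = Path(path)
    data = config_to_dict(cfg)
    if path.suffix == ".json":
        path.write_text(json.dumps(data, indent=2))
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=False))
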