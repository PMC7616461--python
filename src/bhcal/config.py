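"""Run configuration: YAML/JSON round-trippable bundle of all settings."""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .oxymodel import ModelConstants
from .pipeline import AcquisitionSpec, CalibrationSpec, PipelineOptions
from .synthdata import ParadigmSpec

__all__ = ["RunConfig"]

_SECTIONS = {
    "acquisition": AcquisitionSpec,
    "constants": ModelConstants,
    "calibration": CalibrationSpec,
    "options": PipelineOptions,
    "paradigm": ParadigmSpec,
}
_SCALARS = ("Hb", "PaO2_0", "PaO2_bh", "seed")


def _build(cls, data: dict):
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown keys for {cls.__name__}: {sorted(unknown)}")
    # YAML deserialises tuples as lists; coerce back
    kwargs = {}
    for f in dataclasses.fields(cls):
        if f.name in data:
            v = data[f.name]
            kwargs[f.name] = tuple(v) if isinstance(v, list) else v
    return cls(**kwargs)


@dataclass
class RunConfig:
    """All settings for a simulate/map run; serialises losslessly."""

    acquisition: AcquisitionSpec = field(default_factory=AcquisitionSpec)
    constants: ModelConstants = field(default_factory=ModelConstants)
    calibration: CalibrationSpec = field(default_factory=CalibrationSpec)
    options: PipelineOptions = field(default_factory=PipelineOptions)
    paradigm: ParadigmSpec = field(default_factory=ParadigmSpec)
    Hb: float = 15.0
    PaO2_0: float = 127.0
    PaO2_bh: float = 104.0
    seed: int | None = None

    def to_dict(self) -> dict:
        out = {name: dataclasses.asdict(getattr(self, name))
               for name in _SECTIONS}
        for name in _SCALARS:
            out[name] = getattr(self, name)
        return out

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        unknown = set(data) - set(_SECTIONS) - set(_SCALARS)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        kwargs = {}
        for name, section_cls in _SECTIONS.items():
            if name in data:
                kwargs[name] = _build(section_cls, data[name] or {})
        for name in _SCALARS:
            if name in data:
                kwargs[name] = data[name]
        return cls(**kwargs)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump(json.loads(json.dumps(self.to_dict())),
                           sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})
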