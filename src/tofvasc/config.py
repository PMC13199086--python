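"""Pipeline configuration: nested parameter sections with strict YAML schema.

Configs are frozen, versioned artifacts: every default is materialized and
echoed into the run manifest, and unknown keys are rejected rather than
ignored.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .enhance import FusionParams, VesselnessParams
from .errors import ParameterError
from .evaluate import DEFAULT_TOLERANCE_MM
from .preprocess import PreprocessParams
from .segment import SegmentParams


@dataclass(frozen=True)
class EvaluateParams:
    tolerance_mm: float = DEFAULT_TOLERANCE_MM

    def __post_init__(self) -> None:
        if self.tolerance_mm < 0:
            raise ParameterError("tolerance_mm must be >= 0")


@dataclass(frozen=True)
class PipelineConfig:
    preprocess: PreprocessParams = field(default_factory=PreprocessParams)
    vesselness: VesselnessParams = field(default_factory=VesselnessParams)
    fusion: FusionParams = field(default_factory=FusionParams)
    segment: SegmentParams = field(default_factory=SegmentParams)
    evaluate: EvaluateParams = field(default_factory=EvaluateParams)
    seed: int = 0
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


_SECTIONS = {
    "preprocess": PreprocessParams,
    "vesselness": VesselnessParams,
    "fusion": FusionParams,
    "segment": SegmentParams,
    "evaluate": EvaluateParams,
}
_SCALARS = {"seed": int, "log_level": str}

# fields where YAML lists must become tuples for the frozen dataclasses
_TUPLE_FIELDS = {"robust_percentiles", "scales_mm", "weights", "branch_angle_mean_deg",
                 "length_ratio", "radius_ratio"}


def _build_section(cls, mapping: dict, name: str):
    allowed = {f.name for f in dataclasses.fields(cls)}
    unknown = set(mapping) - allowed
    if unknown:
        raise ParameterError(f"unknown key(s) in section {name!r}: {sorted(unknown)}")
    kwargs = {
        k: tuple(v) if k in _TUPLE_FIELDS and isinstance(v, list) else v
        for k, v in mapping.items()
    }
    return cls(**kwargs)


def config_from_dict(raw: dict) -> PipelineConfig:
    raw = dict(raw or {})
    unknown = set(raw) - set(_SECTIONS) - set(_SCALARS)
    if unknown:
        raise ParameterError(f"unknown top-level config key(s): {sorted(unknown)}")
    kwargs: dict = {}
    for name, cls in _SECTIONS.items():
        section = raw.get(name, {})
        if not isinstance(section, dict):
            raise ParameterError(f"config section {name!r} must be a mapping")
        kwargs[name] = _build_section(cls, section, name)
    for name, typ in _SCALARS.items():
        if name in raw:
            kwargs[name] = typ(raw[name])
    return PipelineConfig(**kwargs)


def load_config(path: str | Path | None) -> PipelineConfig:
    """Load a YAML config; ``None`` gives all defaults."""
    if path is None:
        return PipelineConfig()
    raw = yaml.safe_load(Path(path).read_text())
    return config_from_dict(raw or {})
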