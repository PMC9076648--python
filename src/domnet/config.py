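"""Pipeline configuration: one flat, typed record covering every stage
parameter, round-tripping losslessly through YAML with unknown keys
rejected."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, fields

import yaml

from .features import ElementRanges, PlausibilityFilters
from .network import NetworkParams
from .synthetic import Block, PlantedStructure, StudyDesign


@dataclass
class PipelineConfig:
    """Every tunable of the end-to-end pipeline, with the defaults the
    package treats as its standard study conditions."""

    seed: int = 0
    design: StudyDesign = field(default_factory=StudyDesign)
    structure: PlantedStructure = field(default_factory=PlantedStructure)
    include_day0: bool = False

    # peak-list simulation
    ppm_jitter: float = 0.2
    sn_low_fraction: float = 0.05
    n_blank_masses: int = 3

    # peak filtering / formula assignment
    sn_threshold: float = 4.0
    mz_window: tuple[float, float] = (175.0, 1000.0)
    blank_ppm_tolerance: float = 2.0
    ppm_tolerance: float = 2.0
    element_ranges: ElementRanges = field(default_factory=ElementRanges)
    filters: PlausibilityFilters = field(default_factory=PlausibilityFilters)
    normalization: str = "sum"

    # network / embedding
    network: NetworkParams = field(default_factory=NetworkParams)
    edge_threshold: float = 0.1
    embedding_k: int = 3

    # coverage / trend / overlay
    coverage_count: str = "compounds"
    coverage_threshold: float = 0.2
    coverage_detection_factor: float = 1.0  # detection threshold, in units of 1/n_features
    trend_mode: str = "full"
    trend_group: str = "litter"
    ubiquity_threshold: float = 0.5
    enrichment: bool = False

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(_plain(self.to_dict()), fh, sort_keys=False)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        return _build(cls, data, context="config")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)


def _plain(obj):
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    return obj


_NESTED = {
    StudyDesign,
    PlantedStructure,
    Block,
    ElementRanges,
    PlausibilityFilters,
    NetworkParams,
}


def _build(cls, data, context: str):
    """Construct a (possibly nested) dataclass, rejecting unknown keys."""
    if not isinstance(data, dict):
        raise ValueError(f"{context}: expected a mapping, got {type(data).__name__}")
    known = {f.name: f for f in fields(cls)}
    unknown = set(data) - set(known)
    if unknown:
        raise ValueError(f"{context}: unknown key(s) {sorted(unknown)}")
    kwargs = {}
    for name, value in data.items():
        ftype = known[name].type
        target = _nested_class(cls, name)
        if target is not None and isinstance(value, dict):
            kwargs[name] = _build(target, value, context=f"{context}.{name}")
        elif name == "blocks" and isinstance(value, list):
            kwargs[name] = tuple(
                _build(Block, b, context=f"{context}.blocks[{i}]")
                if isinstance(b, dict)
                else Block(*b)
                for i, b in enumerate(value)
            )
        elif isinstance(value, list):
            kwargs[name] = tuple(tuple(v) if isinstance(v, list) else v for v in value)
        else:
            kwargs[name] = value
    return cls(**kwargs)


def _nested_class(cls, field_name: str):
    defaults = {
        "design": StudyDesign,
        "structure": PlantedStructure,
        "element_ranges": ElementRanges,
        "filters": PlausibilityFilters,
        "network": NetworkParams,
    }
    return defaults.get(field_name)
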