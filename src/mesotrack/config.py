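"""Pipeline configuration: defaults, YAML loading, validation, manifests.

Defaults reproduce the study settings: 30-min treatment windows, 3 px blob /
quality 15 detector, initial linking gates d_g = 30 px / t_g = 5 s, trajectory
rebuild gates d_g = 50 px / t_g = 10 s, 35 px edge buffer and the 6.82 px/cm
calibration.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field, asdict

import yaml

from .detect import DetectorConfig, LinkConfig
from .synthetic import ArenaGeometry

__all__ = ["PipelineConfig", "load_config", "manifest"]


@dataclass(frozen=True)
class ArenaSection:
    width_px: int = 682
    height_px: int = 682
    px_per_cm: float = 6.82
    edge_buffer_px: int = 35

    def geometry(self) -> ArenaGeometry:
        return ArenaGeometry(self.width_px, self.height_px, self.px_per_cm, self.edge_buffer_px)


@dataclass(frozen=True)
class PreprocessSection:
    window_s: int = 1800


@dataclass(frozen=True)
class DetectorSection:
    blob_diameter_px: float = 3.0
    quality_threshold: float = 15.0

    def detector(self) -> DetectorConfig:
        return DetectorConfig(self.blob_diameter_px, self.quality_threshold)


@dataclass(frozen=True)
class LinkerSection:
    d_g_px: float = 30.0
    t_g_s: int = 5

    def linker(self) -> LinkConfig:
        return LinkConfig(self.d_g_px, self.t_g_s)


@dataclass(frozen=True)
class CleaningSection:
    max_auto_points: int = 10
    mutual_delete_cm: float = 5.0
    exclusion_list: tuple = ()


@dataclass(frozen=True)
class JunctionSection:
    """Rebuild gates applied after cleaning (less restrictive than linking)."""

    d_g_px: float = 50.0
    t_g_s: int = 10


@dataclass(frozen=True)
class StatsSection:
    n_permutations: int = 1000
    min_individuals: int = 10
    min_records: int = 10
    seed: int = 0


@dataclass(frozen=True)
class SimulateSection:
    n_individuals_per_type: int = 2
    duration_s: int = 600
    seed: int = 0
    noise_sd: float = 5.0
    blob_sigma_px: float = 1.5
    blob_peak: float = 150.0
    residue_unit_size_cm: float = 3.0
    residue_spacing_cm: float = 6.0


@dataclass(frozen=True)
class PipelineConfig:
    arena: ArenaSection = field(default_factory=ArenaSection)
    preprocess: PreprocessSection = field(default_factory=PreprocessSection)
    detector: DetectorSection = field(default_factory=DetectorSection)
    linker: LinkerSection = field(default_factory=LinkerSection)
    cleaning: CleaningSection = field(default_factory=CleaningSection)
    junction: JunctionSection = field(default_factory=JunctionSection)
    stats: StatsSection = field(default_factory=StatsSection)
    simulate: SimulateSection = field(default_factory=SimulateSection)

    def to_dict(self) -> dict:
        return asdict(self)


def _build_section(cls, data: dict, path: str):
    valid = {f.name: f for f in dataclasses.fields(cls)}
    kwargs = {}
    for key, value in data.items():
        if key not in valid:
            raise ValueError(f"unknown config key {path}.{key}")
        if key == "exclusion_list":
            value = tuple(str(v) for v in value)
        kwargs[key] = value
    return cls(**kwargs)


def load_config(path=None, overrides: dict | None = None) -> PipelineConfig:
    """Load a YAML config; missing keys fall back to study defaults."""
    data: dict = {}
    if path is not None:
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
    if overrides:
        for section, vals in overrides.items():
            data.setdefault(section, {}).update(vals)
    sections = {}
    section_types = {f.name: globals()[f.type.split(".")[-1]] if isinstance(f.type, str) else f.type
                     for f in dataclasses.fields(PipelineConfig)}
    for name, payload in data.items():
        if name not in section_types:
            raise ValueError(f"unknown config section {name!r}")
        if not isinstance(payload, dict):
            raise ValueError(f"config section {name!r} must be a mapping")
        sections[name] = _build_section(section_types[name], payload, name)
    return PipelineConfig(**sections)


def manifest(config: PipelineConfig, seeds: dict | None = None, extra: dict | None = None) -> dict:
    """Reproducibility manifest: config, seeds, versions and a content hash."""
    import numpy
    import scipy

    from . import __version__

    doc = {
        "config": config.to_dict(),
        "seeds": seeds or {},
        "versions": {
            "mesotrack": __version__,
            "numpy": numpy.__version__,
            "scipy": scipy.__version__,
        },
    }
    if extra:
        doc.update(extra)
    blob = json.dumps(doc, sort_keys=True, default=str).encode()
    doc["manifest_sha256"] = hashlib.sha256(blob).hexdigest()
    return doc
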