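"""Flat YAML configuration for the pipeline, with unknown keys rejected."""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path

import yaml

from .selection import SelectionParams


@dataclass
class LoessConfig:
    span: float = 0.3
    min_usable_bins: int = 100
    clamp_floor: float = 0.01


@dataclass
class ScoringConfig:
    min_panel_size: int = 30
    outlier_threshold: float = 3.0
    moderation_df: float = 60.0


@dataclass
class CallingConfig:
    mode: str = "single"   # "single" (z > 3) or "dual" (2 / 4 gray zone)
    z_positive: float | None = None
    z_negative: float | None = None


@dataclass
class PipelineConfig:
    loess: LoessConfig = field(default_factory=LoessConfig)
    scoring: ScoringConfig = field(default_factory=ScoringConfig)
    selection: SelectionParams = field(default_factory=SelectionParams)
    calling: CallingConfig = field(default_factory=CallingConfig)
    targets: tuple[int, ...] = (13, 18, 21)


def _fill(cls, mapping: dict, section: str):
    known = {f.name for f in fields(cls)}
    unknown = set(mapping) - known
    if unknown:
        raise ValueError(f"unknown config keys in '{section}': {sorted(unknown)}")
    return cls(**mapping)


def load_config(path: str | Path | None) -> PipelineConfig:
    """Load a pipeline config from YAML; None gives defaults."""
    if path is None:
        return PipelineConfig()
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError(f"{path}: config must be a mapping")
    sections = {
        "loess": LoessConfig,
        "scoring": ScoringConfig,
        "selection": SelectionParams,
        "calling": CallingConfig,
    }
    unknown = set(data) - set(sections) - {"targets"}
    if unknown:
        raise ValueError(f"{path}: unknown config sections {sorted(unknown)}")
    kwargs = {}
    for name, cls in sections.items():
        kwargs[name] = _fill(cls, data.get(name, {}) or {}, name)
    if "targets" in data:
        kwargs["targets"] = tuple(int(c) for c in data["targets"])
    return PipelineConfig(**kwargs)
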