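"""Flat YAML run configuration.

A run is parameterized by the stain thresholds (:class:`StainConfig`) and
the pipeline settings below.  Precedence is CLI flag > config file >
documented default; the CLI logs the effective value of every parameter.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from pathlib import Path
from typing import Any

import yaml

from ._exceptions import ConfigurationError
from .stains import StainConfig


@dataclass
class PipelineConfig:
    """Settings of the section-analysis pipeline around the color rule.

    Parameters
    ----------
    white_floor:
        Background threshold: a pixel with ``min(R, G, B)`` at or above it
        is unstained slide glass.
    min_object_px:
        Connected components of the tissue mask smaller than this are
        dropped as debris.
    closing_radius:
        Disk radius of the morphological closing applied to the raw
        tissue mask.
    fill_holes:
        Whether interior holes (pale infarct core, bubbles, cavities)
        count as tissue.
    dilation_radius:
        Disk radius applied to the infarct mask before quantification;
        0 (default) quantifies the raw color-rule mask.
    px_um:
        Pixel edge length in micrometres (square pixels assumed).
    """

    white_floor: int = 235
    min_object_px: int = 64
    closing_radius: int = 3
    fill_holes: bool = True
    dilation_radius: int = 0
    px_um: float = 1.0

    def __post_init__(self):
        if not 0 < self.white_floor <= 255:
            raise ConfigurationError("white_floor must be in (0, 255]")
        if self.min_object_px < 0 or self.closing_radius < 0 or self.dilation_radius < 0:
            raise ConfigurationError("morphology sizes must be >= 0")
        if self.px_um <= 0:
            raise ConfigurationError("px_um must be > 0")


_STAIN_KEYS = {f.name for f in fields(StainConfig)}
_PIPELINE_KEYS = {f.name for f in fields(PipelineConfig)}


def load_config(
    path: str | Path | None = None, overrides: dict[str, Any] | None = None
) -> tuple[StainConfig, PipelineConfig]:
    """Build configs from an optional YAML file plus override mapping.

    The YAML file is a flat key-value mapping; keys are routed to the
    stain or pipeline config by name, and unknown keys are rejected so
    typos fail loudly.
    """
    values: dict[str, Any] = {}
    if path is not None:
        loaded = yaml.safe_load(Path(path).read_text())
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ConfigurationError(f"{path} must contain a flat key-value mapping")
        values.update(loaded)
    for key, val in (overrides or {}).items():
        if val is not None:
            values[key] = val
    unknown = set(values) - _STAIN_KEYS - _PIPELINE_KEYS
    if unknown:
        raise ConfigurationError(
            f"unknown configuration key(s) {sorted(unknown)}; valid keys: "
            f"{sorted(_STAIN_KEYS | _PIPELINE_KEYS)}"
        )
    stain_cfg = StainConfig(**{k: v for k, v in values.items() if k in _STAIN_KEYS})
    pipe_cfg = PipelineConfig(**{k: v for k, v in values.items() if k in _PIPELINE_KEYS})
    return stain_cfg, pipe_cfg


def config_record(stain_cfg: StainConfig, pipe_cfg: PipelineConfig) -> dict[str, Any]:
    """Flat dict of every effective parameter, for run records and logs."""
    rec = {f.name: getattr(stain_cfg, f.name) for f in fields(StainConfig)}
    rec.update({f.name: getattr(pipe_cfg, f.name) for f in fields(PipelineConfig)})
    return rec
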