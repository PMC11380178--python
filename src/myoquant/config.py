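"""YAML configuration loading for simulation and pipeline parameters.

A config file may contain any of three top-level sections::

    simulation:        # SimulationConfig keys
      n_nuclei: 150
      target_mdi: 0.5
    pipeline:          # PipelineParams keys
      blur_sigma_px: 1.0
      mfi_min_nuclei: 2
    channel_roles:
      nuclei: 0
      myotubes: 1

Unknown keys raise, so typos fail loudly.  See docs/config_template.yaml
for the fully annotated template.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Any, Mapping

import yaml

from .segmentation import PipelineParams
from .simulate import SimulationConfig

__all__ = ["load_config", "simulation_config", "pipeline_params", "channel_roles"]


def load_config(path: str | Path | None) -> dict:
    """Load a YAML config file; ``None`` gives an empty config."""
    if path is None:
        return {}
    text = Path(path).read_text()
    data = yaml.safe_load(text) or {}
    if not isinstance(data, dict):
        raise ValueError(f"config root must be a mapping, got {type(data).__name__}")
    return data


def _build(cls, section: Mapping[str, Any], name: str):
    valid = {f.name for f in dataclasses.fields(cls)}
    unknown = set(section) - valid
    if unknown:
        raise ValueError(f"unknown {name} keys: {sorted(unknown)}")
    return cls(**section)


def simulation_config(config: Mapping[str, Any], **overrides) -> SimulationConfig:
    section = dict(config.get("simulation", {}))
    section.update(overrides)
    return _build(SimulationConfig, section, "simulation")


def pipeline_params(config: Mapping[str, Any], **overrides) -> PipelineParams:
    section = dict(config.get("pipeline", {}))
    section.update(overrides)
    return _build(PipelineParams, section, "pipeline")


def channel_roles(config: Mapping[str, Any]) -> dict:
    roles = dict(config.get("channel_roles", {"nuclei": 0, "myotubes": 1}))
    if set(roles) != {"nuclei", "myotubes"}:
        raise ValueError("channel_roles must map exactly 'nuclei' and 'myotubes'")
    return roles
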