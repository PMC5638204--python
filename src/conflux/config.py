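"""YAML configuration loading for the command-line interface.

A config file groups parameters by block::

    network_prior:
      tau: 0.0025
      ceiling: 0.02
    model:
      p_pen: 0.7
    inference:
      alpha: 0.5
    simulation:
      n_genes: 1000
      n: 800
      p: 10
      topology: neighbourhood

Unknown keys are rejected to catch typos early.
"""

from __future__ import annotations

from dataclasses import fields
from pathlib import Path

import yaml

from .inference_engine import InferenceConfig
from .model_core import ModelConfig
from .network_prior import PriorConfig
from .simulator import PopulationConfig

__all__ = ["load_config", "dump_config"]

_BLOCKS = {
    "network_prior": PriorConfig,
    "model": ModelConfig,
    "inference": InferenceConfig,
    "population": PopulationConfig,
}

_SIMULATION_KEYS = {"n_genes", "n", "p", "topology", "top_k", "clique_fraction",
                    "star_center", "seed"}


def _build(cls, mapping: dict):
    allowed = {f.name for f in fields(cls)}
    unknown = set(mapping) - allowed
    if unknown:
        raise ValueError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    return cls(**mapping)


def load_config(path: str | Path | None) -> dict:
    """Parse a YAML config into typed config objects (defaults when absent)."""
    raw = {}
    if path is not None:
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
    unknown = set(raw) - set(_BLOCKS) - {"simulation"}
    if unknown:
        raise ValueError(f"unknown config blocks: {sorted(unknown)}")
    out = {name: _build(cls, raw.get(name, {}) or {})
           for name, cls in _BLOCKS.items()}
    sim = raw.get("simulation", {}) or {}
    bad = set(sim) - _SIMULATION_KEYS
    if bad:
        raise ValueError(f"unknown simulation keys: {sorted(bad)}")
    out["simulation"] = sim
    return out


def dump_config(config: dict, path: str | Path) -> None:
    """Write the effective configuration back out as YAML."""
    serializable = {}
    for name in _BLOCKS:
        obj = config[name]
        serializable[name] = {f.name: getattr(obj, f.name)
                              for f in fields(type(obj))}
    serializable["simulation"] = dict(config.get("simulation", {}))
    with open(path, "w") as fh:
        yaml.safe_dump(serializable, fh, sort_keys=True)
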