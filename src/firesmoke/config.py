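"""Declarative pipeline configuration (YAML) with strict key handling.

A config file may override any subset of the defaults; every key not
supplied is resolved from package defaults and its provenance ("default" or
"file") is recorded. Unknown keys and duplicate keys are hard errors — a
typo must never be silently ignored in an exposure analysis.
"""
from __future__ import annotations

import dataclasses
import datetime as dt
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from .biomarker import DEFAULT_LOD_UG_L, DEFAULT_LOQ_UG_L
from .exposure import DEFAULT_TASK_WEIGHTS
from .protection import DEFAULT_CHANGE_FREQUENCY_MAP, DEFAULT_PF_TABLE
from .simulate import SimConfig
from .types import ConfigurationError, Device

__all__ = ["PipelineConfig", "load_config"]


class _StrictLoader(yaml.SafeLoader):
    """SafeLoader that rejects duplicate mapping keys."""


def _strict_construct_mapping(loader, node, deep=False):
    mapping = {}
    for key_node, value_node in node.value:
        key = loader.construct_object(key_node, deep=deep)
        if key in mapping:
            raise ConfigurationError(
                f"duplicate key {key!r} at line {key_node.start_mark.line + 1}"
            )
        mapping[key] = loader.construct_object(value_node, deep=deep)
    return mapping


_StrictLoader.add_constructor(
    yaml.resolver.BaseResolver.DEFAULT_MAPPING_TAG, _strict_construct_mapping
)


@dataclass
class PipelineConfig:
    """Fully resolved configuration for the whole pipeline."""

    simulation: SimConfig = field(default_factory=SimConfig)
    task_weights: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_TASK_WEIGHTS)
    )
    pf_table: dict[Device, float] = field(
        default_factory=lambda: dict(DEFAULT_PF_TABLE)
    )
    change_frequency_map: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CHANGE_FREQUENCY_MAP)
    )
    lod: float = DEFAULT_LOD_UG_L
    loq: float = DEFAULT_LOQ_UG_L
    seed: int = 0
    provenance: dict[str, str] = field(default_factory=dict)


_SIM_FIELDS = {f.name: f for f in dataclasses.fields(SimConfig)}
_TOP_KEYS = {
    "simulation",
    "task_weights",
    "pf_table",
    "change_frequency_map",
    "lod",
    "loq",
    "seed",
}


def _coerce_sim_value(name: str, value: Any) -> Any:
    if name in ("date_start", "date_end") and isinstance(value, str):
        return dt.date.fromisoformat(value)
    if name == "areas" and isinstance(value, list):
        return tuple(value)
    return value


def load_config(path: str | Path | None = None) -> PipelineConfig:
    """Load a YAML config; missing file/keys fall back to package defaults.

    Every resolved key's provenance is recorded in ``config.provenance`` as
    ``"default"`` or ``"file"``.
    """
    data: dict[str, Any] = {}
    if path is not None:
        text = Path(path).read_text(encoding="utf-8")
        loaded = yaml.load(text, Loader=_StrictLoader)
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ConfigurationError(f"{path}: top level must be a mapping")
        data = loaded

    unknown = sorted(set(data) - _TOP_KEYS)
    if unknown:
        raise ConfigurationError(
            f"unknown configuration key(s): {unknown}; known keys: {sorted(_TOP_KEYS)}"
        )

    provenance = {k: "default" for k in _TOP_KEYS}
    cfg = PipelineConfig()

    sim_over = data.get("simulation", {})
    if sim_over:
        if not isinstance(sim_over, dict):
            raise ConfigurationError("'simulation' must be a mapping")
        bad = sorted(set(sim_over) - set(_SIM_FIELDS))
        if bad:
            raise ConfigurationError(
                f"unknown simulation key(s): {bad}; known: {sorted(_SIM_FIELDS)}"
            )
        kwargs = {k: _coerce_sim_value(k, v) for k, v in sim_over.items()}
        cfg.simulation = dataclasses.replace(cfg.simulation, **kwargs)
        provenance["simulation"] = "file"
        for k in sim_over:
            provenance[f"simulation.{k}"] = "file"

    if "task_weights" in data:
        tw = {str(k): float(v) for k, v in data["task_weights"].items()}
        cfg.task_weights = tw
        cfg.simulation = dataclasses.replace(cfg.simulation, task_weight_table=tw)
        provenance["task_weights"] = "file"
    if "pf_table" in data:
        table = {}
        for k, v in data["pf_table"].items():
            pf = math.inf if v in ("inf", ".inf") else float(v)
            table[Device(k)] = pf
        cfg.pf_table = table
        provenance["pf_table"] = "file"
    if "change_frequency_map" in data:
        cfg.change_frequency_map = {
            str(k): float(v) for k, v in data["change_frequency_map"].items()
        }
        provenance["change_frequency_map"] = "file"
    for scalar in ("lod", "loq"):
        if scalar in data:
            setattr(cfg, scalar, float(data[scalar]))
            cfg.simulation = dataclasses.replace(
                cfg.simulation, **{scalar: float(data[scalar])}
            )
            provenance[scalar] = "file"
    if "seed" in data:
        cfg.seed = int(data["seed"])
        cfg.simulation = dataclasses.replace(cfg.simulation, seed=cfg.seed)
        provenance["seed"] = "file"

    if cfg.lod <= 0 or cfg.loq < cfg.lod:
        raise ConfigurationError(f"need 0 < lod <= loq, got {cfg.lod}, {cfg.loq}")
    cfg.provenance = provenance
    return cfg
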