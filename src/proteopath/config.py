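"""Structured JSON/YAML configuration for models and analyses.

Schema (all blocks optional, unknown keys rejected)::

    profile:  "default" | {k_fold, K_fold, k_mis, K_mis, k_ag, c_crit}
    levels:   {ribosomes, trigger_factor, dnak, dnaj, grpe, groel, groes,
               lon, clpb}
    options:  {ribosome_activation_rate, n_max, binding_factor,
               capacity_factor, enabled_systems, double_occupancy,
               enable_aggregation, lon_binds_misfolded, null_floor}
    overrides: {rate-constant name: value}
    analysis: {t_eval, rtol, atol, n_points}
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import yaml

from .kinetics import AnalysisConfig
from .model import (
    BiophysicalProfile,
    ChaperoneLevels,
    ModelOptions,
    PROFILES,
    System,
)

__all__ = ["load_config", "parse_config", "resolved_config"]

_TOP_KEYS = {"profile", "levels", "options", "overrides", "analysis"}


def _fields(cls) -> set[str]:
    return {f.name for f in dataclasses.fields(cls)}


def _make(cls, block: dict, what: str):
    unknown = set(block) - _fields(cls)
    if unknown:
        raise KeyError(f"unknown {what} key(s): {sorted(unknown)}")
    return cls(**block)


def parse_config(data: dict):
    """Parse a config mapping into (profile, levels, options, overrides, analysis)."""
    unknown = set(data) - _TOP_KEYS
    if unknown:
        raise KeyError(f"unknown config block(s): {sorted(unknown)}")
    prof = data.get("profile", "default")
    if isinstance(prof, str):
        if prof not in PROFILES:
            raise KeyError(f"unknown profile name {prof!r}; choose from {sorted(PROFILES)}")
        profile = PROFILES[prof]
    else:
        profile = _make(BiophysicalProfile, dict(prof), "profile")
    levels = _make(ChaperoneLevels, dict(data.get("levels", {})), "levels")
    opts = dict(data.get("options", {}))
    if "enabled_systems" in opts:
        opts["enabled_systems"] = frozenset(System(s) for s in opts["enabled_systems"])
    options = _make(ModelOptions, opts, "options")
    overrides = dict(data.get("overrides", {}))
    analysis = _make(AnalysisConfig, dict(data.get("analysis", {})), "analysis")
    return profile, levels, options, overrides, analysis


def load_config(path):
    """Load a JSON or YAML config file (dispatch on extension)."""
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    return parse_config(data or {})


def resolved_config(profile, levels, options, overrides, analysis) -> dict:
    """Materialise every default into a plain dict (for run provenance)."""
    return {
        "profile": dataclasses.asdict(profile),
        "levels": dataclasses.asdict(levels),
        "options": {
            **{
                k: (sorted(s.value for s in v) if isinstance(v, frozenset) else v)
                for k, v in dataclasses.asdict(options).items()
            }
        },
        "overrides": dict(overrides or {}),
        "analysis": dataclasses.asdict(analysis),
    }
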