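"""Run configuration with a versioned, strict schema.

Configs are flat YAML/JSON mappings of named parameter blocks; unknown
keys are rejected so typos cannot silently fall back to defaults.  Every
CLI run writes the fully resolved config next to its outputs.
"""

from __future__ import annotations

from dataclasses import fields
from typing import Any

from .mobility import MobilityClassBins, StateSegmenter
from .sfm import MonomerReference
from .simulate import FociSimParams, SFMSimParams, SPTSimParams
from .tracking import LinkingParams

SCHEMA_VERSION = 1

_BLOCK_FIELDS: dict[str, set[str]] = {
    "spt_sim": {f.name for f in fields(SPTSimParams)},
    "sfm_sim": {f.name for f in fields(SFMSimParams)},
    "foci_sim": {f.name for f in fields(FociSimParams)},
    "linking": {f.name for f in fields(LinkingParams)},
    "detection": {"intensity_threshold", "threshold_k", "psf_sigma_px", "pixel_size"},
    "segmenter": {"frame_interval", "loc_sigma", "D_refs", "p_stay", "min_segment_length"},
    "bins": {f.name for f in fields(MobilityClassBins)},
    "monomer_reference": {f.name for f in fields(MonomerReference)},
    "sfm_analysis": {"height_threshold", "min_area"},
    "foci_analysis": {"edu_threshold", "k", "min_focus_area", "min_nucleus_area", "max_nucleus_area", "channel_map"},
}
_TOP_LEVEL = {"schema_version", "seed", "log_level", "input", "outdir", "condition", "cell_id"} | set(_BLOCK_FIELDS)

__all__ = ["SCHEMA_VERSION", "validate_config", "build_params"]


class ConfigError(ValueError):
    """Raised for schema violations in a run config."""


def validate_config(config: dict[str, Any]) -> dict[str, Any]:
    """Validate a run config against the schema; returns it unchanged.

    Raises :class:`ConfigError` on unknown top-level or block keys or on
    a schema-version mismatch.
    """
    if not isinstance(config, dict):
        raise ConfigError("config must be a mapping")
    unknown = set(config) - _TOP_LEVEL
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    version = config.get("schema_version", SCHEMA_VERSION)
    if version != SCHEMA_VERSION:
        raise ConfigError(f"unsupported schema_version {version!r} (expected {SCHEMA_VERSION})")
    for block, allowed in _BLOCK_FIELDS.items():
        sub = config.get(block)
        if sub is None:
            continue
        if not isinstance(sub, dict):
            raise ConfigError(f"config block {block!r} must be a mapping")
        bad = set(sub) - allowed
        if bad:
            raise ConfigError(f"unknown keys in {block!r}: {sorted(bad)}")
    return config


def build_params(config: dict[str, Any], block: str, cls, **overrides):
    """Instantiate a params dataclass from a config block plus overrides."""
    kwargs = dict(config.get(block) or {})
    kwargs.update({k: v for k, v in overrides.items() if v is not None})
    return cls(**kwargs)
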