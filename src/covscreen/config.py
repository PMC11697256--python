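"""Structured run configuration.

One nested YAML document holds every threshold used across the pipeline;
unknown keys are rejected so typos cannot silently fall back to defaults.
CLI flags override config keys (flag > config > built-in default).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import yaml

from .aggregate import AggregationPolicy
from .competition import CompetitionParams
from .dose_response import QualityParams
from .simulate import DetectionModel, SimConfig, SpikeSpec

__all__ = ["RunConfig", "ConfigError", "load_config", "config_hash"]


class ConfigError(ValueError):
    """The configuration document is malformed or violates an invariant."""


def _build(cls, data: Mapping[str, Any], where: str):
    if not isinstance(data, Mapping):
        raise ConfigError(f"{where}: expected a mapping, got {type(data).__name__}")
    allowed = {f.name for f in dataclasses.fields(cls)}
    unknown = sorted(set(data) - allowed)
    if unknown:
        raise ConfigError(f"{where}: unknown key(s) {', '.join(unknown)}")
    try:
        return cls(**data)
    except (ValueError, TypeError) as exc:
        raise ConfigError(f"{where}: {exc}") from exc


@dataclass
class RunConfig:
    seed: int = 0
    outdir: str = "covscreen_out"
    sim: SimConfig = field(default_factory=SimConfig)
    competition: CompetitionParams = field(default_factory=CompetitionParams)
    quality: QualityParams = field(default_factory=QualityParams)
    aggregation: AggregationPolicy = field(default_factory=AggregationPolicy)
    sample_dialect: dict = field(default_factory=dict)
    report_dialect: dict = field(default_factory=dict)
    off_target_window: float = 0.5
    median_normalize: bool = False  # cross-run median normalization (off)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def load_config(path: str | Path | None, overrides: Mapping[str, Any] | None = None
                ) -> RunConfig:
    """Load and validate a nested YAML run configuration.

    ``overrides`` is a flat mapping of top-level keys (e.g. from CLI flags)
    that take precedence over the file.
    """
    data: dict[str, Any] = {}
    if path is not None:
        with open(path) as fh:
            loaded = yaml.safe_load(fh) or {}
        if not isinstance(loaded, dict):
            raise ConfigError(f"{path}: top level must be a mapping")
        data.update(loaded)
    if overrides:
        data.update({k: v for k, v in overrides.items() if v is not None})

    allowed = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = sorted(set(data) - allowed)
    if unknown:
        raise ConfigError(f"unknown top-level key(s): {', '.join(unknown)}")

    kwargs: dict[str, Any] = {}
    for key in ("seed", "outdir", "off_target_window", "median_normalize",
                "sample_dialect", "report_dialect"):
        if key in data:
            kwargs[key] = data[key]
    if "sim" in data:
        sim_data = dict(data["sim"])
        spikes = sim_data.pop("spikes", [])
        detection = sim_data.pop("detection", None)
        sim = _build(SimConfig, sim_data, "sim")
        if detection is not None:
            sim.detection = _build(DetectionModel, detection, "sim.detection")
        sim.spikes = [_build(SpikeSpec, sp, f"sim.spikes[{i}]")
                      for i, sp in enumerate(spikes)]
        # re-validate with spikes attached
        sim.__post_init__()
        kwargs["sim"] = sim
    if "competition" in data:
        kwargs["competition"] = _build(
            CompetitionParams, data["competition"], "competition"
        )
    if "quality" in data:
        kwargs["quality"] = _build(QualityParams, data["quality"], "quality")
    if "aggregation" in data:
        kwargs["aggregation"] = _build(
            AggregationPolicy, data["aggregation"], "aggregation"
        )
    try:
        return RunConfig(**kwargs)
    except (ValueError, TypeError) as exc:
        raise ConfigError(str(exc)) from exc


def config_hash(config: RunConfig) -> str:
    """Stable digest of the fully resolved configuration (provenance)."""
    def default(o):
        if isinstance(o, float) and o != o:
            return "nan"
        return str(o)

    blob = json.dumps(config.to_dict(), sort_keys=True, default=default)
    return hashlib.sha256(blob.encode()).hexdigest()
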