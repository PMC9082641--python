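"""Experiment configuration: structured YAML in, validated dataclasses out.

One file with sections ``region``, ``travel``, ``delays``, ``des``,
``stats``, ``output`` and a ``master_seed``. Unknown keys are rejected so
typos fail loudly, and a configuration round-trips unchanged through
``dump_config``/``parse_config``.

Reproducibility: the master seed is split into named per-stage streams
(``region``, ``addresses``, ``demand``, ``missions``, ``des``,
``dispatch``) via ``numpy`` seed sequences with a fixed name→index map, so
any stage can be rerun in isolation and still match a full pipeline run.
"""

from __future__ import annotations

import dataclasses
import hashlib
from dataclasses import dataclass, field

import numpy as np
import yaml

from .region import ConfigurationError, RegionSpec
from .timechain import DelayTable
from .travel import AirModel, GroundModel, Period, TravelModels

__all__ = [
    "ExperimentConfig",
    "DESSettings",
    "StatsSettings",
    "OutputSettings",
    "parse_config",
    "load_config",
    "dump_config",
    "config_hash",
    "seed_stream",
]

#: fixed name → spawn-key index map for the per-stage random streams
_STREAMS = {"region": 0, "addresses": 1, "demand": 2, "missions": 3, "des": 4, "dispatch": 5}


def seed_stream(master_seed: int, name: str) -> np.random.SeedSequence:
    """Named child seed of the master seed (documented, stable derivation)."""
    return np.random.SeedSequence(entropy=master_seed, spawn_key=(_STREAMS[name],))


@dataclass(frozen=True)
class DESSettings:
    queue_threshold: float = 15.0
    reject_threshold: float = 60.0
    availability: float = 0.90
    service_mode: str = "FIXED_AVERAGE"
    fixed_mission_minutes: float = 165.0
    handover_minutes: float = 15.0
    other_acute_rate: float | None = None  # missions/day; None → 1.4 per base
    demand_multiplier: float | None = None  # None → calibrate to 2.8/heli/day
    n_reps: int = 1000
    horizon_days: float = 28.0


@dataclass(frozen=True)
class StatsSettings:
    addresses_per_municipality: int = 10
    base_stroke_rate: float = 0.004  # stroke codes / person / year
    distance_gradient: float = 0.5  # per-capita incidence uplift at max distance
    grid_resolution_km: float = 10.0
    dispatch_horizon_days: float = 365.0


@dataclass(frozen=True)
class OutputSettings:
    directory: str = "results"
    float_format: str = "%.6g"


@dataclass(frozen=True)
class ExperimentConfig:
    region: RegionSpec = field(default_factory=RegionSpec)
    travel: TravelModels = field(default_factory=TravelModels)
    delays: DelayTable = field(default_factory=DelayTable)
    des: DESSettings = field(default_factory=DESSettings)
    stats: StatsSettings = field(default_factory=StatsSettings)
    output: OutputSettings = field(default_factory=OutputSettings)
    master_seed: int = 0


# ---------------------------------------------------------------------------
# parsing / serialization

def _build(cls, data: dict, where: str):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ConfigurationError(f"unknown key(s) in section '{where}': {sorted(unknown)}")
    return cls(**data)


def _parse_travel(data: dict) -> TravelModels:
    unknown = set(data) - {"ground", "air"}
    if unknown:
        raise ConfigurationError(f"unknown key(s) in section 'travel': {sorted(unknown)}")
    ground_data = dict(data.get("ground", {}))
    mult = ground_data.pop("period_multipliers", None)
    if mult is not None:
        try:
            ground_data["period_multipliers"] = {Period(k): float(v) for k, v in mult.items()}
        except ValueError as e:
            raise ConfigurationError(f"bad period name in travel.ground: {e}") from e
    ground = _build(GroundModel, ground_data, "travel.ground")
    air = _build(AirModel, dict(data.get("air", {})), "travel.air")
    return TravelModels(ground=ground, air=air)


def parse_config(data: dict) -> ExperimentConfig:
    data = dict(data or {})
    known = {"region", "travel", "delays", "des", "stats", "output", "master_seed"}
    unknown = set(data) - known
    if unknown:
        raise ConfigurationError(f"unknown top-level key(s): {sorted(unknown)}")
    try:
        return ExperimentConfig(
            region=_build(RegionSpec, dict(data.get("region", {})), "region"),
            travel=_parse_travel(dict(data.get("travel", {}))),
            delays=_build(DelayTable, dict(data.get("delays", {})), "delays"),
            des=_build(DESSettings, dict(data.get("des", {})), "des"),
            stats=_build(StatsSettings, dict(data.get("stats", {})), "stats"),
            output=_build(OutputSettings, dict(data.get("output", {})), "output"),
            master_seed=int(data.get("master_seed", 0)),
        )
    except TypeError as e:
        raise ConfigurationError(str(e)) from e


def load_config(path) -> ExperimentConfig:
    with open(path, encoding="utf-8") as fh:
        return parse_config(yaml.safe_load(fh))


def dump_config(config: ExperimentConfig) -> dict:
    """Plain-dict form that parses back to an identical configuration."""
    travel = {
        "ground": {
            "base_speed": config.travel.ground.base_speed,
            "detour_factor": config.travel.ground.detour_factor,
            "period_multipliers": {
                p.value: m for p, m in config.travel.ground.period_multipliers.items()
            },
        },
        "air": {"cruise_speed": config.travel.air.cruise_speed},
    }
    return {
        "region": dataclasses.asdict(config.region),
        "travel": travel,
        "delays": dataclasses.asdict(config.delays),
        "des": dataclasses.asdict(config.des),
        "stats": dataclasses.asdict(config.stats),
        "output": dataclasses.asdict(config.output),
        "master_seed": config.master_seed,
    }


def config_hash(config: ExperimentConfig) -> str:
    """Short stable hash of the full configuration (for output provenance)."""
    text = yaml.safe_dump(dump_config(config), sort_keys=True)
    return hashlib.sha256(text.encode()).hexdigest()[:12]
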