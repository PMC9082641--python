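"""Ground and air travel-time models with time-of-day effects.

Ground times follow a detour-factor law — Euclidean distance × detour
(road/straight-line ratio) at a base cruise speed, scaled by a per-period
congestion multiplier. Air times are straight-line at a constant helicopter
speed of 240 km/h that already absorbs take-off and landing. Both are
deliberately simple, monotone-in-distance surrogates for routed travel
times; the national medians they produce are calibratable through
``base_speed`` and ``detour_factor``.

Facility lookup is period-aware: the hybrid center counts as a CSC during
working hours (morning peak, midday) and as a PSC otherwise, so nighttime
CSC lookups fall back to the three full-time comprehensive centers.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Iterable

import pandas as pd

from .region import Facility, FacilityRole, Region

__all__ = [
    "Period",
    "AirModel",
    "GroundModel",
    "TravelModels",
    "LookupError_",
    "air_time",
    "ground_time",
    "nearest_facility",
    "travel_matrix",
]


class LookupError_(ValueError):
    """No facility of the requested role is open/available."""


class Period(enum.Enum):
    MORNING_PEAK = "morning_peak"
    MIDDAY = "midday"
    AFTERNOON_PEAK = "afternoon_peak"
    NIGHT = "night"

    @property
    def working_hours(self) -> bool:
        return self in (Period.MORNING_PEAK, Period.MIDDAY)


@dataclass(frozen=True)
class AirModel:
    #: km/h, inclusive of take-off and landing
    cruise_speed: float = 240.0

    def __post_init__(self):
        if self.cruise_speed <= 0:
            raise ValueError("cruise_speed must be > 0")


def _default_multipliers() -> dict[Period, float]:
    return {
        Period.MORNING_PEAK: 1.0,
        Period.MIDDAY: 1.0,
        Period.AFTERNOON_PEAK: 1.1,
        Period.NIGHT: 1.0,
    }


@dataclass(frozen=True)
class GroundModel:
    base_speed: float = 80.0  # km/h
    detour_factor: float = 1.3  # road distance / straight-line distance
    period_multipliers: dict[Period, float] = field(default_factory=_default_multipliers)

    def __post_init__(self):
        if self.base_speed <= 0:
            raise ValueError("base_speed must be > 0")
        if self.detour_factor < 1:
            raise ValueError("detour_factor must be >= 1")
        if any(m < 1 for m in self.period_multipliers.values()):
            raise ValueError("period multipliers must be >= 1")


@dataclass(frozen=True)
class TravelModels:
    ground: GroundModel = field(default_factory=GroundModel)
    air: AirModel = field(default_factory=AirModel)


def air_time(a, b, model: AirModel) -> float:
    """Helicopter minutes between planar points (straight line, constant speed)."""
    return math.dist(a, b) / model.cruise_speed * 60.0


def ground_time(a, b, model: GroundModel, period: Period) -> float:
    """Ambulance minutes between planar points for a given time of day."""
    mult = model.period_multipliers.get(period, 1.0)
    return math.dist(a, b) * model.detour_factor / model.base_speed * 60.0 * mult


def _effective_role(f: Facility, period: Period) -> FacilityRole:
    if f.role is FacilityRole.HYBRID_PSC:
        return FacilityRole.CSC if period.working_hours else FacilityRole.PSC
    return f.role


def _matches(f: Facility, roles: frozenset | set, period: Period) -> bool:
    # HYBRID_PSC requested explicitly → match it regardless of period
    # (used for SHS lookups, where trauma/PCI run around the clock);
    # otherwise resolve the hybrid to its period-dependent stroke role.
    if f.role in roles:
        return True
    return _effective_role(f, period) in roles


def _travel(a, b, model, period: Period) -> float:
    if isinstance(model, AirModel):
        return air_time(a, b, model)
    return ground_time(a, b, model, period)


def nearest_facility(
    p,
    roles: Iterable[FacilityRole],
    region: Region,
    model: GroundModel | AirModel,
    period: Period,
) -> tuple[Facility, float]:
    """Open facility of one of ``roles`` minimizing travel time from ``p``.

    Ties are broken by the lowest facility id. Raises :class:`LookupError_`
    when no matching facility is open in the given period.
    """
    roles = set(roles)
    best: tuple[float, int, Facility] | None = None
    for f in region.facilities:
        if not _matches(f, roles, period):
            continue
        t = _travel(p, f.location, model, period)
        key = (t, f.id)
        if best is None or key < (best[0], best[1]):
            best = (t, f.id, f)
    if best is None:
        raise LookupError_(f"no open facility with role in {sorted(r.value for r in roles)}")
    return best[2], best[0]


def travel_matrix(
    origins: dict[str, tuple[float, float]],
    destinations: dict[str, tuple[float, float]],
    model: GroundModel | AirModel,
    period: Period = Period.MIDDAY,
) -> pd.DataFrame:
    """Origin × destination travel-time table in minutes."""
    data = {
        dname: [_travel(o, d, model, period) for o in origins.values()]
        for dname, d in destinations.items()
    }
    return pd.DataFrame(data, index=list(origins.keys()))
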