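"""Discrete-event simulation of helicopter fleet capacity.

Stochastic transport requests (stroke codes plus other acute missions such
as PCI and trauma) arrive as superposed Poisson streams from the
municipalities whose ground time to specialized hospital services (SHS)
exceeds a catchment-zone cutoff. Each request seizes the nearest base with
an idle, in-service helicopter; helicopters are only operational a fraction
of the time (weather), modelled as an independent per-dispatch refusal.
Requests wait in FIFO order; a wait beyond ``queue_threshold`` (15 min)
marks the patient as *queued*, and at ``reject_threshold`` (60 min) the
patient is *rejected* and diverted to ground transport. A rejected patient
was necessarily queued first, so the two counts overlap.

The event engine is a plain priority-queue loop: at equal timestamps
helicopter releases are processed before arrivals, and arrivals before
rejection timeouts, so a patient whose wait ends exactly at the rejection
threshold is still served. Availability draws are indexed by
(request, base, helicopter slot), which couples runs that differ only in
fleet size and makes capacity comparisons well-defined seed by seed.
"""

from __future__ import annotations

import enum
import heapq
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .region import Facility, FacilityRole, Region, SHS_ROLES
from .timechain import DelayTable
from .travel import AirModel, GroundModel, Period, TravelModels, air_time, ground_time, nearest_facility

logger = logging.getLogger(__name__)

__all__ = [
    "CatchmentZone",
    "MissionKind",
    "MissionRequest",
    "FleetConfig",
    "QueuePolicy",
    "DESResult",
    "generate_missions",
    "mission_duration",
    "simulate",
    "scenario_sweep",
    "summarize_sweep",
    "eligible_municipalities",
    "daily_request_rate",
    "calibrate_demand_multiplier",
]


class CatchmentZone(enum.Enum):
    """Helicopter catchment zones, by ground-to-SHS cutoff in minutes.

    LARGE helicopter zone = helicopters serve everyone beyond 28 ground
    minutes from an SHS center (the call-to-air floor); MIDDLE and SMALL
    push the cutoff to 38 and 48 min, shrinking helicopter demand.
    """

    LARGE = 28.0
    MIDDLE = 38.0
    SMALL = 48.0

    @property
    def cutoff_minutes(self) -> float:
        return self.value


class MissionKind(str, enum.Enum):
    STROKE_CODE = "STROKE_CODE"
    OTHER_ACUTE = "OTHER_ACUTE"


@dataclass(frozen=True)
class MissionRequest:
    arrival_time: float  # minutes since simulation start
    origin: tuple[float, float]
    origin_municipality: int
    destination_shs: Facility
    kind: MissionKind


@dataclass(frozen=True)
class FleetConfig:
    bases: tuple[Facility, ...]
    helicopters_per_base: int = 1
    availability: float = 0.90  # operational fraction (weather etc.)
    service_mode: str = "FIXED_AVERAGE"  # FIXED_AVERAGE | COMPUTED | EXPONENTIAL
    fixed_mission_minutes: float = 165.0  # base-out to base-return
    handover_minutes: float = 15.0  # patient handover at the SHS (COMPUTED mode)

    def __post_init__(self):
        if not (0.0 < self.availability <= 1.0):
            raise ValueError("availability must be in (0, 1]")
        if self.helicopters_per_base < 1:
            raise ValueError("helicopters_per_base must be >= 1")
        if self.service_mode not in ("FIXED_AVERAGE", "COMPUTED", "EXPONENTIAL"):
            raise ValueError(f"unknown service_mode {self.service_mode!r}")
        if not self.bases:
            raise ValueError("fleet needs at least one base")


@dataclass(frozen=True)
class QueuePolicy:
    queue_threshold: float = 15.0  # min; longer waits count as "queued"
    reject_threshold: float = 60.0  # min; divert to ground transport

    def __post_init__(self):
        if not (0 <= self.queue_threshold < self.reject_threshold):
            raise ValueError("need 0 <= queue_threshold < reject_threshold")


@dataclass
class DESResult:
    n_requests: int
    n_served: int
    n_queued: int
    n_rejected: int
    waits: np.ndarray  # final wait of every request, minutes
    utilization: dict[int, float]  # base id -> busy fraction

    @property
    def queued_fraction(self) -> float:
        return self.n_queued / self.n_requests if self.n_requests else 0.0

    @property
    def rejected_fraction(self) -> float:
        return self.n_rejected / self.n_requests if self.n_requests else 0.0


# ---------------------------------------------------------------------------
# Demand generation

def eligible_municipalities(
    region: Region, zone: CatchmentZone, ground: GroundModel, period: Period = Period.MIDDAY
) -> list[int]:
    """Municipalities whose centroid is at/over the zone's ground-to-SHS cutoff."""
    out = []
    for m in region.municipalities:
        _, t = nearest_facility(m.centroid, SHS_ROLES, region, ground, period)
        if t >= zone.cutoff_minutes:
            out.append(m.id)
    return out


def daily_request_rate(
    region: Region,
    zone: CatchmentZone,
    ground: GroundModel,
    other_acute_rate: float,
    demand_multiplier: float = 1.0,
) -> float:
    """Expected helicopter requests/day for a zone (stroke codes + other acute).

    The other-acute stream is region-wide with population-weighted origins,
    of which only missions arising beyond the zone cutoff fly, so its
    delivered rate is scaled by the eligible population share.
    """
    elig = eligible_municipalities(region, zone, ground)
    stroke = sum(region.municipality(i).annual_stroke_codes for i in elig) / 365.0
    total_pop = sum(m.population for m in region.municipalities)
    elig_pop = sum(region.municipality(i).population for i in elig)
    share = elig_pop / total_pop if total_pop > 0 else 0.0
    return stroke * demand_multiplier + other_acute_rate * share


def calibrate_demand_multiplier(
    region: Region,
    ground: GroundModel,
    target_missions_per_day: float,
    other_acute_rate: float,
    zone: CatchmentZone = CatchmentZone.LARGE,
) -> float:
    """Multiplier making the zone's total request rate hit a daily target.

    Used to pin the synthetic workload to the observed fleet tempo
    (2.8 missions per helicopter-day) since the true per-municipality
    demand magnitude is a free parameter of the model.
    """
    elig = eligible_municipalities(region, zone, ground)
    stroke_daily = sum(region.municipality(i).annual_stroke_codes for i in elig) / 365.0
    if stroke_daily <= 0:
        raise ValueError("region has no eligible stroke demand to calibrate")
    total_pop = sum(m.population for m in region.municipalities)
    elig_pop = sum(region.municipality(i).population for i in elig)
    share = elig_pop / total_pop if total_pop > 0 else 0.0
    need = target_missions_per_day - other_acute_rate * share
    if need <= 0:
        raise ValueError("other-acute missions already exceed the daily target")
    return need / stroke_daily


def generate_missions(
    region: Region,
    zone: CatchmentZone,
    horizon_days: float,
    other_acute_rate: float,
    seed,
    models: TravelModels | None = None,
    demand_multiplier: float = 1.0,
) -> list[MissionRequest]:
    """Superposed Poisson mission streams over ``horizon_days``.

    Per-municipality homogeneous streams at ``annual_stroke_codes/365 ×
    demand_multiplier`` per day, restricted to municipalities beyond the
    zone cutoff, plus one region-wide OTHER_ACUTE stream of
    ``other_acute_rate``/day (population-weighted origins) of which only
    missions originating beyond the cutoff fly. Destination is the nearest
    SHS center by air. Returns a time-sorted list.

    Each municipality's draws come from a seed child keyed by municipality
    id, so for a shared seed the SMALL-zone stream is an exact subset of
    the MIDDLE- and LARGE-zone streams: zone comparisons are paired.
    """
    from .region import _sample_in_polygon  # uniform point-in-polygon sampler

    if horizon_days <= 0:
        raise ValueError("horizon_days must be > 0")
    models = models or TravelModels()
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)

    def child_rng(*key: int) -> np.random.Generator:
        return np.random.default_rng(
            np.random.SeedSequence(entropy=ss.entropy, spawn_key=tuple(ss.spawn_key) + key)
        )

    elig = eligible_municipalities(region, zone, models.ground)
    if not elig:
        logger.warning("no municipality beyond the %s zone cutoff; no missions", zone.name)
        return []
    elig_set = set(elig)

    horizon_min = horizon_days * 1440.0
    raw: list[tuple[float, int, MissionKind]] = []
    for mid in elig:
        m = region.municipality(mid)
        rng_m = child_rng(11, mid)
        lam = m.annual_stroke_codes / 365.0 * demand_multiplier * horizon_days
        k = rng_m.poisson(lam)
        for t in rng_m.uniform(0.0, horizon_min, size=k):
            raw.append((float(t), mid, MissionKind.STROKE_CODE))

    pops = np.array([m.population for m in region.municipalities], dtype=float)
    if pops.sum() > 0 and other_acute_rate > 0:
        rng_o = child_rng(13)
        k = rng_o.poisson(other_acute_rate * horizon_days)
        picks = rng_o.choice(len(pops), size=k, p=pops / pops.sum())
        for t, j in zip(rng_o.uniform(0.0, horizon_min, size=k), picks):
            if int(j) in elig_set:
                raw.append((float(t), int(j), MissionKind.OTHER_ACUTE))

    raw.sort(key=lambda r: r[0])
    point_rng: dict[int, np.random.Generator] = {}
    missions: list[MissionRequest] = []
    for t, mid, kind in raw:
        poly = region.municipality(mid).polygon
        rng_p = point_rng.setdefault(mid, child_rng(17, mid))
        xy = _sample_in_polygon(poly, 1, rng_p)[0]
        origin = (float(xy[0]), float(xy[1]))
        dest, _ = nearest_facility(origin, SHS_ROLES, region, models.air, Period.MIDDAY)
        missions.append(MissionRequest(t, origin, mid, dest, kind))
    return missions


# ---------------------------------------------------------------------------
# Service times

def mission_duration(
    req: MissionRequest,
    base: Facility,
    fleet: FleetConfig,
    delays: DelayTable | None = None,
    air: AirModel | None = None,
) -> float:
    """Base-out to base-return duration of one mission, minutes."""
    if fleet.service_mode == "FIXED_AVERAGE":
        return fleet.fixed_mission_minutes
    delays = delays or DelayTable()
    air = air or AirModel()
    shs = req.destination_shs.location
    return (
        delays.heli_dispatch
        + air_time(base.location, req.origin, air)
        + delays.heli_loading
        + air_time(req.origin, shs, air)
        + fleet.handover_minutes
        + air_time(shs, base.location, air)
    )


# ---------------------------------------------------------------------------
# Event-driven simulation

_PRIO_FREE, _PRIO_ARRIVAL, _PRIO_TIMEOUT = 0, 1, 2


def simulate(
    missions: list[MissionRequest],
    fleet: FleetConfig,
    policy: QueuePolicy,
    seed=0,
    delays: DelayTable | None = None,
    air: AirModel | None = None,
) -> DESResult:
    """Run the fleet through a time-sorted mission list.

    Deterministic for a fixed seed. See the module docstring for the
    dispatch, availability and queue/rejection semantics.
    """
    n = len(missions)
    times = [m.arrival_time for m in missions]
    if any(b > a for a, b in zip(times[1:], times)):
        raise ValueError("missions must be time-sorted")

    bases = fleet.bases
    slots = fleet.helicopters_per_base
    units: list[tuple[int, int]] = [(bi, s) for bi in range(len(bases)) for s in range(slots)]
    free_time = np.zeros(len(units))
    busy = np.zeros(len(bases))

    # one availability column per (base, slot), independent of fleet size,
    # so runs differing only in helicopters_per_base share their draws
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    avail_draws = np.empty((max(n, 1), len(units)))
    for ui, (bi, s) in enumerate(units):
        child = np.random.SeedSequence(
            entropy=ss.entropy, spawn_key=tuple(ss.spawn_key) + (7, bases[bi].id, s)
        )
        avail_draws[:, ui] = np.random.default_rng(child).random(max(n, 1))
    service_rng = np.random.default_rng(
        np.random.SeedSequence(entropy=ss.entropy, spawn_key=tuple(ss.spawn_key) + (1_000_003,))
    )
    exp_service = (
        service_rng.exponential(fleet.fixed_mission_minutes, size=max(n, 1))
        if fleet.service_mode == "EXPONENTIAL"
        else None
    )

    heap: list[tuple[float, int, int, int]] = []  # (time, prio, seq, payload)
    seq = len(missions)
    for i, m in enumerate(missions):
        heap.append((m.arrival_time, _PRIO_ARRIVAL, i, i))
    heapq.heapify(heap)

    waiting: list[int] = []  # FIFO of request indices
    blocked: dict[int, set[int]] = {}
    waits = np.full(n, np.nan)
    served = np.zeros(n, dtype=bool)
    rejected = np.zeros(n, dtype=bool)
    makespan = 0.0

    base_dist = {
        i: [math.dist(missions[i].origin, b.location) for b in bases] for i in range(n)
    }

    def try_assign(i: int, now: float) -> bool:
        blk = blocked.setdefault(i, set())
        cands = [
            (base_dist[i][bi], bases[bi].id, s, ui)
            for ui, (bi, s) in enumerate(units)
            if free_time[ui] <= now + 1e-9 and ui not in blk
        ]
        cands.sort()
        for _, _, _, ui in cands:
            if avail_draws[i, ui] < fleet.availability:
                bi, _s = units[ui]
                if fleet.service_mode == "EXPONENTIAL":
                    dur = exp_service[i]
                else:
                    dur = mission_duration(missions[i], bases[bi], fleet, delays, air)
                nonlocal seq
                seq += 1
                free_time[ui] = now + dur
                busy[bi] += dur
                heapq.heappush(heap, (now + dur, _PRIO_FREE, seq, -1))
                waits[i] = now - missions[i].arrival_time
                served[i] = True
                return True
            blk.add(ui)
        return False

    def sweep(now: float) -> None:
        still = []
        for i in waiting:
            if not try_assign(i, now):
                still.append(i)
        waiting[:] = still

    while heap:
        now, prio, _, payload = heapq.heappop(heap)
        makespan = max(makespan, now)
        if prio == _PRIO_FREE:
            sweep(now)
        elif prio == _PRIO_ARRIVAL:
            i = payload
            waiting.append(i)
            if math.isfinite(policy.reject_threshold):
                heapq.heappush(heap, (now + policy.reject_threshold, _PRIO_TIMEOUT, i, i))
            sweep(now)
        else:  # timeout
            i = payload
            if i in waiting:
                waiting.remove(i)
                rejected[i] = True
                waits[i] = policy.reject_threshold

    makespan = max(makespan, float(free_time.max(initial=0.0)))
    n_served = int(served.sum())
    n_rejected = int(rejected.sum())
    n_queued = int((waits > policy.queue_threshold).sum())
    util = {
        bases[bi].id: (busy[bi] / (slots * makespan) if makespan > 0 else 0.0)
        for bi in range(len(bases))
    }
    assert n_served + n_rejected == n, "conservation violated"
    return DESResult(n, n_served, n_queued, n_rejected, waits, util)


# ---------------------------------------------------------------------------
# Scenario sweep (zone × fleet size grid, replicated)

def scenario_sweep(
    region: Region,
    models: TravelModels,
    delays: DelayTable,
    *,
    zones: tuple[CatchmentZone, ...] = (CatchmentZone.LARGE, CatchmentZone.MIDDLE, CatchmentZone.SMALL),
    heli_options: tuple[int, ...] = (1, 2),
    n_reps: int = 1000,
    horizon_days: float = 28.0,
    other_acute_rate: float | None = None,
    demand_multiplier: float | None = None,
    policy: QueuePolicy | None = None,
    availability: float = 0.90,
    service_mode: str = "FIXED_AVERAGE",
    fixed_mission_minutes: float = 165.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Replicated DES over the zone × helicopters-per-base grid.

    Mission streams are shared between fleet sizes within a (zone,
    replicate) pair, so fleet comparisons are paired by construction. When
    ``demand_multiplier`` is None it is calibrated so that the LARGE zone
    sees 2.8 requests per helicopter-day across the bases; when
    ``other_acute_rate`` is None, non-stroke missions take half of that
    tempo (1.4 per base-day).
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    policy = policy or QueuePolicy()
    bases = tuple(region.heli_bases)
    if not bases:
        raise ValueError("region has no helicopter bases")
    if other_acute_rate is None:
        other_acute_rate = 1.4 * len(bases)
    if demand_multiplier is None:
        demand_multiplier = calibrate_demand_multiplier(
            region, models.ground, 2.8 * len(bases), other_acute_rate
        )

    rows = []
    for zi, zone in enumerate(zones):
        for rep in range(n_reps):
            # seeds shared across zones and fleet sizes: comparisons are paired
            m_seed = np.random.SeedSequence(entropy=seed, spawn_key=(rep, 0))
            s_seed = np.random.SeedSequence(entropy=seed, spawn_key=(rep, 1))
            missions = generate_missions(
                region, zone, horizon_days, other_acute_rate, m_seed, models, demand_multiplier
            )
            for h in heli_options:
                fleet = FleetConfig(
                    bases=bases,
                    helicopters_per_base=h,
                    availability=availability,
                    service_mode=service_mode,
                    fixed_mission_minutes=fixed_mission_minutes,
                )
                res = simulate(missions, fleet, policy, seed=s_seed, delays=delays, air=models.air)
                rows.append(
                    {
                        "zone": zone.name,
                        "helicopters_per_base": h,
                        "replicate": rep,
                        "n_requests": res.n_requests,
                        "n_queued": res.n_queued,
                        "n_rejected": res.n_rejected,
                        "queued_fraction": res.queued_fraction,
                        "rejected_fraction": res.rejected_fraction,
                    }
                )
    return pd.DataFrame(rows)


def summarize_sweep(df: pd.DataFrame) -> pd.DataFrame:
    """Mean and IQR of queued/rejected fractions per grid cell."""
    def q1(s):
        return s.quantile(0.25)

    def q3(s):
        return s.quantile(0.75)

    return (
        df.groupby(["zone", "helicopters_per_base"])
        .agg(
            queued_mean=("queued_fraction", "mean"),
            queued_q1=("queued_fraction", q1),
            queued_q3=("queued_fraction", q3),
            rejected_mean=("rejected_fraction", "mean"),
            rejected_q1=("rejected_fraction", q1),
            rejected_q3=("rejected_fraction", q3),
        )
        .reset_index()
    )
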