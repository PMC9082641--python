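"""Onset-to-treatment time chains for the four transport strategies.

Composes the prehospital chain — symptom onset → emergency call → dispatch →
ambulance response → on-scene care → transport → in-hospital treatment — for
each of four configurations:

* ``DRIP_SHIP_GROUND``: ground to the nearest primary stroke center (PSC)
  for thrombolysis (IVT, "needle"), then interhospital transfer by ground to
  a comprehensive center (CSC) for thrombectomy (EVT, "groin").
* ``DRIP_SHIP_HELI_TRANSFER``: same, but the PSC→CSC transfer flies
  (helicopter dispatch + base→PSC + PSC→CSC legs).
* ``BYPASS_GROUND``: ground directly to the nearest CSC.
* ``BYPASS_HELI``: simultaneous ambulance and helicopter dispatch; the
  ambulance crew prepares the patient so that air transport can never start
  earlier than ``min_call_to_air`` (28 min = 8 min response + 20 min on
  scene) after the call; the helicopter then loads (11 min) and flies the
  patient to the nearest CSC.

All delay constants default to the registry-derived medians of the Danish
setting (see :class:`DelayTable`). Times are real-valued minutes; rounding
to whole minutes is a reporting concern.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

from .region import AddressPoint, Facility, FacilityRole, Region, SHS_ROLES
from .travel import AirModel, Period, TravelModels, air_time, ground_time, nearest_facility

__all__ = [
    "DelayTable",
    "TransportConfig",
    "TimeBreakdown",
    "ground_chain",
    "heli_pickup",
    "bypass_heli_chain",
    "dripship_chain",
    "evaluate_chain",
    "helicopter_viable",
    "aha_bypass_rule",
]


@dataclass(frozen=True)
class DelayTable:
    """Fixed components of the prehospital chain, minutes.

    Defaults are the Danish registry medians: 30 min onset-to-call, 1 min
    ambulance dispatch, 8 min response, 20 min on scene, 5 min helicopter
    dispatch-to-airborne, 11 min helicopter loading, a 28-min floor on
    call-to-air-transport (response + scene preparation), 27 min
    door-to-needle, 68 min door-to-groin under bypass, 41 min door-to-groin
    after a drip-and-ship transfer, and 60 min door-in-door-out at the PSC.
    """

    onset_to_call: float = 30.0
    ambulance_dispatch: float = 1.0
    ambulance_response: float = 8.0
    on_scene: float = 20.0
    heli_dispatch: float = 5.0
    heli_loading: float = 11.0
    min_call_to_air: float = 28.0
    door_to_needle: float = 27.0
    door_to_groin_bypass: float = 68.0
    door_to_groin_dripship: float = 41.0
    door_in_door_out: float = 60.0

    def __post_init__(self):
        for name, v in self.__dict__.items():
            if v < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.door_to_groin_bypass <= self.door_to_needle:
            raise ValueError("door_to_groin_bypass must exceed door_to_needle")


class TransportConfig(str, enum.Enum):
    DRIP_SHIP_GROUND = "DRIP_SHIP_GROUND"
    DRIP_SHIP_HELI_TRANSFER = "DRIP_SHIP_HELI_TRANSFER"
    BYPASS_GROUND = "BYPASS_GROUND"
    BYPASS_HELI = "BYPASS_HELI"


@dataclass
class TimeBreakdown:
    """Ordered component times for one patient under one configuration."""

    config: TransportConfig
    needle_components: list[tuple[str, float]]
    groin_components: list[tuple[str, float]]
    needle_site: FacilityRole
    groin_site: FacilityRole

    @property
    def onset_to_needle_total(self) -> float:
        return sum(v for _, v in self.needle_components)

    @property
    def onset_to_groin_total(self) -> float:
        return sum(v for _, v in self.groin_components)


def _prehospital_prefix(delays: DelayTable) -> list[tuple[str, float]]:
    return [
        ("onset_to_call", delays.onset_to_call),
        ("ambulance_dispatch", delays.ambulance_dispatch),
        ("ambulance_response", delays.ambulance_response),
        ("on_scene", delays.on_scene),
    ]


def ground_chain(
    p: AddressPoint | tuple,
    target_role: FacilityRole,
    region: Region,
    models: TravelModels,
    delays: DelayTable,
    period: Period,
) -> TimeBreakdown:
    """Ground transport chain to the nearest PSC or CSC.

    With ``target_role=CSC`` this is the bypass-ground configuration.
    With ``target_role=PSC`` it is drip-and-ship with a ground transfer
    (delegates to :func:`dripship_chain`).
    """
    if target_role is FacilityRole.PSC:
        return dripship_chain(p, region, models, delays, period, transfer_mode="GROUND")
    if target_role is not FacilityRole.CSC:
        raise ValueError("target_role must be PSC or CSC")
    loc = p.location if isinstance(p, AddressPoint) else p
    csc, t_csc = nearest_facility(loc, {FacilityRole.CSC}, region, models.ground, period)
    prefix = _prehospital_prefix(delays) + [("ground_transport_to_csc", t_csc)]
    return TimeBreakdown(
        config=TransportConfig.BYPASS_GROUND,
        needle_components=prefix + [("door_to_needle", delays.door_to_needle)],
        groin_components=prefix + [("door_to_groin_bypass", delays.door_to_groin_bypass)],
        needle_site=FacilityRole.CSC,
        groin_site=FacilityRole.CSC,
    )


def heli_pickup(
    p: AddressPoint | tuple,
    base: Facility,
    delays: DelayTable,
    air: AirModel,
) -> tuple[float, list[tuple[str, float]]]:
    """Scene departure time (minutes after the call) under simultaneous dispatch.

    The helicopter is airborne ``heli_dispatch`` minutes after the call and
    flies to the scene; the ground crew needs ``min_call_to_air`` minutes to
    have the patient ready. Departure is the later of the two plus the
    loading time — loading does not overlap the preparation floor.
    """
    loc = p.location if isinstance(p, AddressPoint) else p
    heli_arrival = delays.heli_dispatch + air_time(base.location, loc, air)
    wait_at_scene = max(heli_arrival, delays.min_call_to_air)
    departure = wait_at_scene + delays.heli_loading
    components = [
        ("call_to_ready_or_heli_arrival", wait_at_scene),
        ("heli_loading", delays.heli_loading),
    ]
    return departure, components


def bypass_heli_chain(
    p: AddressPoint | tuple,
    region: Region,
    models: TravelModels,
    delays: DelayTable,
    period: Period,
) -> TimeBreakdown:
    """Helicopter bypass: fly from the scene to the nearest CSC."""
    loc = p.location if isinstance(p, AddressPoint) else p
    base, _ = nearest_facility(loc, {FacilityRole.HELI_BASE}, region, models.air, period)
    csc, t_fly = nearest_facility(loc, {FacilityRole.CSC}, region, models.air, period)
    departure, pickup_components = heli_pickup(p, base, delays, models.air)
    prefix = (
        [("onset_to_call", delays.onset_to_call)]
        + pickup_components
        + [("air_transport_to_csc", t_fly)]
    )
    return TimeBreakdown(
        config=TransportConfig.BYPASS_HELI,
        needle_components=prefix + [("door_to_needle", delays.door_to_needle)],
        groin_components=prefix + [("door_to_groin_bypass", delays.door_to_groin_bypass)],
        needle_site=FacilityRole.CSC,
        groin_site=FacilityRole.CSC,
    )


def dripship_chain(
    p: AddressPoint | tuple,
    region: Region,
    models: TravelModels,
    delays: DelayTable,
    period: Period,
    transfer_mode: str = "GROUND",
) -> TimeBreakdown:
    """Drip-and-ship: thrombolysis at the nearest PSC, transfer to a CSC.

    The groin chain replaces door-to-needle with door-in-door-out at the
    PSC, the interhospital transfer (ground, or helicopter dispatch +
    base→PSC + PSC→CSC flight legs), and the post-transfer door-to-groin.
    """
    if transfer_mode not in ("GROUND", "HELI"):
        raise ValueError("transfer_mode must be GROUND or HELI")
    loc = p.location if isinstance(p, AddressPoint) else p
    psc, t_psc = nearest_facility(loc, {FacilityRole.PSC}, region, models.ground, period)
    prefix = _prehospital_prefix(delays) + [("ground_transport_to_psc", t_psc)]
    needle = prefix + [("door_to_needle", delays.door_to_needle)]

    if transfer_mode == "GROUND":
        csc, t_transfer = nearest_facility(
            psc.location, {FacilityRole.CSC}, region, models.ground, period
        )
        transfer = [("ground_transfer_psc_to_csc", t_transfer)]
        cfg = TransportConfig.DRIP_SHIP_GROUND
    else:
        base, _ = nearest_facility(
            psc.location, {FacilityRole.HELI_BASE}, region, models.air, period
        )
        csc, t_leg = nearest_facility(psc.location, {FacilityRole.CSC}, region, models.air, period)
        transfer = [
            ("heli_dispatch", delays.heli_dispatch),
            ("air_base_to_psc", air_time(base.location, psc.location, models.air)),
            ("air_psc_to_csc", t_leg),
        ]
        cfg = TransportConfig.DRIP_SHIP_HELI_TRANSFER

    groin = (
        prefix
        + [("door_in_door_out", delays.door_in_door_out)]
        + transfer
        + [("door_to_groin_dripship", delays.door_to_groin_dripship)]
    )
    return TimeBreakdown(
        config=cfg,
        needle_components=needle,
        groin_components=groin,
        needle_site=FacilityRole.PSC,
        groin_site=FacilityRole.CSC,
    )


def evaluate_chain(
    p: AddressPoint | tuple,
    config: TransportConfig,
    region: Region,
    models: TravelModels,
    delays: DelayTable,
    period: Period,
) -> TimeBreakdown:
    """Dispatch to the chain builder for one of the four configurations."""
    if config is TransportConfig.DRIP_SHIP_GROUND:
        return dripship_chain(p, region, models, delays, period, "GROUND")
    if config is TransportConfig.DRIP_SHIP_HELI_TRANSFER:
        return dripship_chain(p, region, models, delays, period, "HELI")
    if config is TransportConfig.BYPASS_GROUND:
        return ground_chain(p, FacilityRole.CSC, region, models, delays, period)
    return bypass_heli_chain(p, region, models, delays, period)


def helicopter_viable(
    p: AddressPoint | tuple,
    region: Region,
    models: TravelModels,
    delays: DelayTable,
    period: Period,
    cutoff: float | None = None,
) -> bool:
    """Whether helicopter dispatch makes sense for this location.

    Close to a specialized center, ground transport beats air retrieval:
    when the ground time to the nearest SHS is strictly below the cutoff
    (default: the 28-min call-to-air floor), only ground transport is used.
    At exactly the cutoff the helicopter is allowed.
    """
    cutoff = delays.min_call_to_air if cutoff is None else cutoff
    loc = p.location if isinstance(p, AddressPoint) else p
    _, t = nearest_facility(loc, SHS_ROLES, region, models.ground, period)
    return not (t < cutoff)


def aha_bypass_rule(
    p: AddressPoint | tuple,
    region: Region,
    models: TravelModels,
    period: Period,
    threshold: float = 15.0,
) -> bool:
    """Guideline bypass rule: go direct to the CSC when the extra ground
    time over the nearest PSC is strictly less than ``threshold`` minutes."""
    loc = p.location if isinstance(p, AddressPoint) else p
    _, t_csc = nearest_facility(loc, {FacilityRole.CSC}, region, models.ground, period)
    _, t_psc = nearest_facility(loc, {FacilityRole.PSC}, region, models.ground, period)
    return (t_csc - t_psc) < threshold
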