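import pytest
from shapely.geometry import box

import helistroke as hs
from helistroke.region import Facility, FacilityRole, Municipality, Region, RegionSpec


@pytest.fixture(scope="session")
def default_region():
    """Danish-default synthetic region with demand attached (seed 1)."""
    region = hs.generate_region(RegionSpec(seed=1))
    return hs.assign_demand(region, base_rate=0.004, distance_gradient=0.5)


@pytest.fixture(scope="session")
def models():
    return hs.TravelModels()


@pytest.fixture(scope="session")
def delays():
    return hs.DelayTable()


def make_line_region(
    psc_x=100.0, csc_x=200.0, base_x=50.0, width=400.0, height=100.0, hybrid_x=None
):
    """Hand-built single-municipality region with facilities on a line at y=50.

    Gives exact control over distances for worked-example tests.
    """
    outline = box(0.0, 0.0, width, height)
    muni = Municipality(
        id=0, centroid=(width / 2, height / 2), polygon=outline, area=width * height,
        population=1000, annual_stroke_codes=100, distance_to_nearest_csc=0.0,
    )
    facs = [
        Facility(0, FacilityRole.CSC, (csc_x, 50.0)),
        Facility(1, FacilityRole.PSC, (psc_x, 50.0)),
        Facility(2, FacilityRole.HELI_BASE, (base_x, 50.0)),
    ]
    if hybrid_x is not None:
        facs.append(Facility(3, FacilityRole.HYBRID_PSC, (hybrid_x, 50.0)))
    spec = RegionSpec(
        total_area=width * height, n_municipalities=1, n_psc=1, n_csc_fulltime=1,
        n_hybrid_psc=1 if hybrid_x is not None else 0, n_heli_bases=1,
        population_total=1000,
    )
    return Region(spec=spec, outline=outline, municipalities=[muni], facilities=facs)


@pytest.fixture
def line_region():
    return make_line_region()


@pytest.fixture
def plain_models():
    """Unit-friendly travel law: 60 km/h, no detour, flat multipliers."""
    ground = hs.GroundModel(
        base_speed=60.0, detour_factor=1.0,
        period_multipliers={p: 1.0 for p in hs.Period},
    )
    return hs.TravelModels(ground=ground, air=hs.AirModel(cruise_speed=240.0))
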