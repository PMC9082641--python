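"""Synthetic intermediate-density geographies.

Generates country-scale planar regions — municipalities tiling a rectangular
outline, stroke facilities and helicopter bases — with the statistical
structure of the Danish setting: ~98 municipalities over 43,000 km², 5.8 M
inhabitants, an *intermediate density* settlement mix (less than half the
population in rural municipalities below 300 persons/km² AND less than half
in urban municipalities above 1,500 persons/km²), comprehensive stroke
centers (CSCs) in the densest municipalities and spatially dispersed
helicopter bases.

Coordinates are planar kilometres; distances are Euclidean. At the spatial
scale modelled here the distortion relative to geodesic computation is
negligible, and dropping map projections keeps the generator dependency-free.
Islands without bridge connections are deliberately not generated.
"""

from __future__ import annotations

import dataclasses
import enum
import json
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import shapely
from scipy.spatial import Voronoi
from shapely.geometry import Point, Polygon, box, mapping, shape

logger = logging.getLogger(__name__)

__all__ = [
    "ConfigurationError",
    "FacilityRole",
    "SHS_ROLES",
    "RegionSpec",
    "Municipality",
    "Facility",
    "AddressPoint",
    "Region",
    "generate_region",
    "sample_addresses",
    "assign_demand",
    "is_intermediate_density",
    "region_to_geojson",
    "region_from_geojson",
]


class ConfigurationError(ValueError):
    """Raised when a region/experiment specification is infeasible or invalid."""


class FacilityRole(str, enum.Enum):
    PSC = "PSC"  # primary stroke center (thrombolysis only)
    CSC = "CSC"  # comprehensive stroke center (thrombolysis + thrombectomy)
    HYBRID_PSC = "HYBRID_PSC"  # PSC that functions as a CSC during working hours
    HELI_BASE = "HELI_BASE"


#: Specialized hospital services: the centers co-locating trauma/PCI/EVT.
#: The hybrid center belongs here around the clock; its *stroke* role is
#: period-dependent and resolved in :mod:`helistroke.travel`.
SHS_ROLES = frozenset({FacilityRole.CSC, FacilityRole.HYBRID_PSC})


@dataclass(frozen=True)
class RegionSpec:
    """Parameters of a synthetic region.

    Defaults mirror the Danish setting: 43,000 km², 98 municipalities,
    5.8 M inhabitants, 7 PSCs, 3 full-time CSCs, one hybrid PSC/CSC and
    4 helicopter bases. ``rural_density_max`` / ``urban_density_min`` are the
    300 and 1,500 persons/km² bounds of the intermediate-density definition.
    """

    total_area: float = 43_000.0  # km²
    n_municipalities: int = 98
    n_psc: int = 7
    n_csc_fulltime: int = 3
    n_hybrid_psc: int = 1
    n_heli_bases: int = 4
    population_total: float = 5_800_000.0
    rural_density_max: float = 300.0  # persons/km²
    urban_density_min: float = 1_500.0  # persons/km²
    seed: int = 0
    aspect_ratio: float = 1.45  # outline width/height

    def validate(self) -> None:
        if self.n_municipalities < 1:
            raise ConfigurationError("n_municipalities must be >= 1")
        for name in ("n_psc", "n_csc_fulltime", "n_hybrid_psc", "n_heli_bases"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if self.total_area <= 0:
            raise ConfigurationError("total_area must be > 0")
        if self.population_total < 0:
            raise ConfigurationError("population_total must be >= 0")
        if self.rural_density_max >= self.urban_density_min:
            raise ConfigurationError("rural_density_max must be < urban_density_min")
        n_hospitals = self.n_psc + self.n_csc_fulltime + self.n_hybrid_psc
        if n_hospitals > self.n_municipalities:
            raise ConfigurationError(
                f"{n_hospitals} stroke facilities cannot be placed in "
                f"{self.n_municipalities} municipalities (one per municipality)"
            )


@dataclass
class Municipality:
    id: int
    centroid: tuple[float, float]  # km
    polygon: Polygon
    area: float  # km²
    population: int = 0
    annual_stroke_codes: int = 0
    distance_to_nearest_csc: float = float("nan")  # km, to nearest SHS center

    @property
    def density(self) -> float:
        return self.population / self.area


@dataclass(frozen=True)
class Facility:
    id: int
    role: FacilityRole
    location: tuple[float, float]  # km


@dataclass(frozen=True)
class AddressPoint:
    municipality_id: int
    location: tuple[float, float]  # km


@dataclass
class Region:
    spec: RegionSpec
    outline: Polygon
    municipalities: list[Municipality]
    facilities: list[Facility]

    def facilities_with_role(self, role: FacilityRole) -> list[Facility]:
        return [f for f in self.facilities if f.role == role]

    @property
    def shs_facilities(self) -> list[Facility]:
        return [f for f in self.facilities if f.role in SHS_ROLES]

    @property
    def heli_bases(self) -> list[Facility]:
        return self.facilities_with_role(FacilityRole.HELI_BASE)

    def municipality(self, mid: int) -> Municipality:
        return self.municipalities[mid]


# ---------------------------------------------------------------------------
# Voronoi tiling

def _bounded_voronoi(points: np.ndarray, width: float, height: float) -> list[Polygon]:
    """Voronoi cells of `points` clipped to [0,width]×[0,height].

    Points are mirrored across the four rectangle edges, which makes every
    interior cell finite and exactly tiling the rectangle.
    """
    pts = np.asarray(points, dtype=float)
    mirrors = [
        pts,
        np.column_stack([-pts[:, 0], pts[:, 1]]),
        np.column_stack([2 * width - pts[:, 0], pts[:, 1]]),
        np.column_stack([pts[:, 0], -pts[:, 1]]),
        np.column_stack([pts[:, 0], 2 * height - pts[:, 1]]),
    ]
    vor = Voronoi(np.vstack(mirrors))
    rect = box(0.0, 0.0, width, height)
    polys = []
    for i in range(len(pts)):
        verts = vor.vertices[vor.regions[vor.point_region[i]]]
        poly = Polygon(verts).intersection(rect)
        polys.append(poly)
    return polys


# ---------------------------------------------------------------------------
# Population assignment under the intermediate-density constraint

def _waterfill(targets: float, lo: np.ndarray, hi: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Allocate `targets` across cells as clip(lam*w, lo, hi) with sum == targets."""
    if targets < lo.sum() - 1e-6 or targets > hi.sum() + 1e-6:
        raise ConfigurationError("population bucket infeasible")
    lam_lo, lam_hi = 0.0, 1.0
    while np.clip(lam_hi * w, lo, hi).sum() < targets:
        lam_hi *= 2.0
        if lam_hi > 1e18:
            break
    for _ in range(200):
        lam = 0.5 * (lam_lo + lam_hi)
        if np.clip(lam * w, lo, hi).sum() < targets:
            lam_lo = lam
        else:
            lam_hi = lam
    out = np.clip(lam_hi * w, lo, hi)
    # distribute the residual over unclipped cells
    resid = targets - out.sum()
    free = (out > lo + 1e-9) & (out < hi - 1e-9)
    if free.any():
        out[free] += resid / free.sum()
        out = np.clip(out, lo, hi)
    return out


def _assign_population(
    areas: np.ndarray, spec: RegionSpec, rng: np.random.Generator
) -> np.ndarray:
    """Population per municipality honouring the intermediate-density mix.

    Three density buckets are filled: *urban* (> urban_density_min), *middle*
    (between the bounds) and *rural* (< rural_density_max), with population
    shares 0.30/0.40/0.30 so that neither the rural nor the urban share
    reaches one half. Smallest-area cells become urban (dense townships),
    the next smallest the middle band, the large cells rural. Within a
    bucket, lognormal weights give realistic size heterogeneity and a
    water-filling step keeps each municipality inside its density band.

    Falls back to an area-proportional allocation when the bucket scheme is
    infeasible (tiny or degenerate specs), in which case the density
    constraint may not hold.
    """
    n = len(areas)
    P = spec.population_total
    if P <= 0:
        return np.zeros(n)
    try:
        return _assign_population_buckets(areas, spec, rng)
    except ConfigurationError:
        logger.warning(
            "intermediate-density bucket allocation infeasible for this spec; "
            "falling back to area-proportional population"
        )
        w = areas * rng.lognormal(0.0, 0.3, size=n)
        return P * w / w.sum()


def _assign_population_buckets(
    areas: np.ndarray, spec: RegionSpec, rng: np.random.Generator
) -> np.ndarray:
    n = len(areas)
    P = spec.population_total
    d_rural, d_urban = spec.rural_density_max, spec.urban_density_min
    shares = {"urban": 0.30, "middle": 0.40, "rural": 0.30}
    order = np.argsort(areas)  # ascending area

    # density bands with safety margins so rounding cannot flip a bucket
    bands = {
        "urban": (1.05 * d_urban, 25.0 * d_urban),
        "middle": (1.05 * d_rural, 0.95 * d_urban),
        "rural": (0.0, 0.95 * d_rural),
    }

    # greedy cell assignment, smallest cells first: urban, then middle
    idx_urban: list[int] = []
    idx_middle: list[int] = []
    cursor = 0
    while cursor < n and bands["urban"][1] * areas[order[:cursor]].sum() < 1.3 * shares["urban"] * P:
        idx_urban.append(int(order[cursor]))
        cursor += 1
    start_mid = cursor
    while (
        cursor < n
        and bands["middle"][1] * areas[order[start_mid:cursor]].sum() < 1.3 * shares["middle"] * P
    ):
        idx_middle.append(int(order[cursor]))
        cursor += 1
    idx_rural = [int(i) for i in order[cursor:]]
    if not idx_rural or not idx_middle or not idx_urban:
        raise ConfigurationError("too few municipalities for a density mix")

    pop = np.zeros(n)
    for name, idx in (("urban", idx_urban), ("middle", idx_middle), ("rural", idx_rural)):
        idx_a = np.asarray(idx)
        a = areas[idx_a]
        lo = bands[name][0] * a
        hi = bands[name][1] * a
        w = a * rng.lognormal(0.0, 0.6, size=len(idx_a))
        pop[idx_a] = _waterfill(shares[name] * P, lo, hi, w)
    return pop


def is_intermediate_density(region: Region) -> bool:
    """True iff <50% of the population is rural AND <50% is urban."""
    spec = region.spec
    total = sum(m.population for m in region.municipalities)
    if total == 0:
        return False
    rural = sum(m.population for m in region.municipalities if m.density < spec.rural_density_max)
    urban = sum(m.population for m in region.municipalities if m.density > spec.urban_density_min)
    return rural / total < 0.5 and urban / total < 0.5


# ---------------------------------------------------------------------------
# Facility placement

def _greedy_dispersed(
    candidates: np.ndarray, k: int, anchors: np.ndarray | None
) -> list[int]:
    """Greedy max-min-distance selection of k candidate indices."""
    chosen: list[int] = []
    pts = [tuple(a) for a in anchors] if anchors is not None and len(anchors) else []
    for _ in range(k):
        best, best_d = None, -1.0
        for i in range(len(candidates)):
            if i in chosen:
                continue
            if pts:
                d = min(math.dist(candidates[i], p) for p in pts)
            else:
                d = math.dist(candidates[i], candidates.mean(axis=0))
            if d > best_d:
                best, best_d = i, d
        if best is None:  # fewer candidates than k: reuse (bases may share sites)
            best = len(chosen) % len(candidates)
        chosen.append(best)
        pts.append(tuple(candidates[best]))
    return chosen


def _place_facilities(
    spec: RegionSpec, municipalities: list[Municipality]
) -> list[Facility]:
    centroids = np.array([m.centroid for m in municipalities])
    by_pop = sorted(range(len(municipalities)), key=lambda i: -municipalities[i].population)

    facilities: list[Facility] = []
    fid = 0
    used: set[int] = set()

    def take_next_populous() -> int:
        for i in by_pop:
            if i not in used:
                used.add(i)
                return i
        raise ConfigurationError("ran out of municipalities for facilities")

    # CSCs in the highest-population municipalities, then the hybrid
    for _ in range(spec.n_csc_fulltime):
        i = take_next_populous()
        facilities.append(Facility(fid, FacilityRole.CSC, municipalities[i].centroid))
        fid += 1
    for _ in range(spec.n_hybrid_psc):
        i = take_next_populous()
        facilities.append(Facility(fid, FacilityRole.HYBRID_PSC, municipalities[i].centroid))
        fid += 1

    # PSCs: dispersed among the more populous half, away from existing hospitals
    half = by_pop[: max(len(by_pop) // 2, spec.n_psc)]
    cand_idx = [i for i in half if i not in used]
    if len(cand_idx) < spec.n_psc:
        cand_idx = [i for i in range(len(municipalities)) if i not in used]
    if len(cand_idx) < spec.n_psc:
        raise ConfigurationError("not enough municipalities for PSCs")
    anchors = np.array([f.location for f in facilities]) if facilities else None
    picks = _greedy_dispersed(centroids[cand_idx], spec.n_psc, anchors)
    for p in picks:
        i = cand_idx[p]
        used.add(i)
        facilities.append(Facility(fid, FacilityRole.PSC, municipalities[i].centroid))
        fid += 1

    # Helicopter bases: dispersed over the whole region (may share municipalities)
    picks = _greedy_dispersed(centroids, spec.n_heli_bases, None)
    for p in picks:
        facilities.append(Facility(fid, FacilityRole.HELI_BASE, municipalities[p].centroid))
        fid += 1
    return facilities


def _refresh_csc_distances(region: Region) -> None:
    shs = region.shs_facilities
    for m in region.municipalities:
        if shs:
            m.distance_to_nearest_csc = min(math.dist(m.centroid, f.location) for f in shs)
        else:
            m.distance_to_nearest_csc = float("nan")


# ---------------------------------------------------------------------------
# Public operations

def generate_region(spec: RegionSpec) -> Region:
    """Generate a reproducible synthetic region from ``spec``.

    Municipalities are the Voronoi cells of uniformly seeded centroids
    clipped to a rectangular outline of ``total_area``; population follows
    the intermediate-density bucket scheme; CSCs sit in the most populous
    municipalities and helicopter bases are spatially dispersed. Identical
    specs (including ``spec.seed``) yield identical regions.
    """
    spec.validate()
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    width = math.sqrt(spec.total_area * spec.aspect_ratio)
    height = spec.total_area / width
    outline = box(0.0, 0.0, width, height)

    n = spec.n_municipalities
    if n == 1:
        polys = [outline]
        seeds = np.array([[width / 2, height / 2]])
    else:
        # keep seeds off the boundary so mirrored Voronoi cells stay valid
        seeds = np.column_stack(
            [
                rng.uniform(0.02 * width, 0.98 * width, size=n),
                rng.uniform(0.02 * height, 0.98 * height, size=n),
            ]
        )
        polys = _bounded_voronoi(seeds, width, height)

    areas = np.array([p.area for p in polys])
    pops = _assign_population(areas, spec, rng)
    pops_int = np.round(pops).astype(int)

    municipalities = [
        Municipality(
            id=i,
            centroid=(float(polys[i].centroid.x), float(polys[i].centroid.y)),
            polygon=polys[i],
            area=float(areas[i]),
            population=int(pops_int[i]),
        )
        for i in range(n)
    ]
    facilities = _place_facilities(spec, municipalities)
    region = Region(spec=spec, outline=outline, municipalities=municipalities, facilities=facilities)
    _refresh_csc_distances(region)
    logger.info(
        "generated region: %d municipalities, %d facilities, population %d",
        n, len(facilities), int(pops_int.sum()),
    )
    return region


def _sample_in_polygon(poly: Polygon, k: int, rng: np.random.Generator) -> np.ndarray:
    """k uniform points inside poly (rejection sampling over the bbox)."""
    minx, miny, maxx, maxy = poly.bounds
    out = np.empty((k, 2))
    got = 0
    while got < k:
        m = max(2 * (k - got), 16)
        xs = rng.uniform(minx, maxx, size=m)
        ys = rng.uniform(miny, maxy, size=m)
        ok = shapely.contains_xy(poly, xs, ys)
        take = min(int(ok.sum()), k - got)
        out[got : got + take, 0] = xs[ok][:take]
        out[got : got + take, 1] = ys[ok][:take]
        got += take
    return out


def sample_addresses(region: Region, n_per_municipality: int, seed: int) -> list[AddressPoint]:
    """Uniform address points, exactly ``n_per_municipality`` per municipality."""
    if n_per_municipality < 1:
        raise ConfigurationError("n_per_municipality must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    points: list[AddressPoint] = []
    for m in region.municipalities:
        xy = _sample_in_polygon(m.polygon, n_per_municipality, rng)
        points.extend(AddressPoint(m.id, (float(x), float(y))) for x, y in xy)
    return points


def assign_demand(
    region: Region, base_rate: float, distance_gradient: float, seed: int = 0
) -> Region:
    """Attach annual stroke-code counts with a distance-to-CSC gradient.

    Per-municipality codes are ``population × base_rate ×
    (1 + gradient × d/d_max)`` rounded to integer, where ``d`` is the
    centroid distance to the nearest comprehensive center. A positive
    gradient yields the empirically observed pattern of higher per-capita
    stroke-code incidence far from the CSCs. The formula is deterministic;
    ``seed`` is accepted for interface symmetry only.
    """
    if base_rate < 0:
        raise ConfigurationError("base_rate must be >= 0")
    dmax = max((m.distance_to_nearest_csc for m in region.municipalities), default=0.0)
    new_munis = []
    for m in region.municipalities:
        nd = (m.distance_to_nearest_csc / dmax) if dmax > 0 else 0.0
        rate = base_rate * (1.0 + distance_gradient * nd)
        if rate < 0:
            raise ConfigurationError(
                f"distance_gradient {distance_gradient} yields a negative rate"
            )
        codes = int(round(m.population * rate))
        new_munis.append(dataclasses.replace(m, annual_stroke_codes=codes))
    return Region(
        spec=region.spec,
        outline=region.outline,
        municipalities=new_munis,
        facilities=list(region.facilities),
    )


# ---------------------------------------------------------------------------
# GeoJSON serialization

def region_to_geojson(region: Region) -> dict:
    features = []
    for m in region.municipalities:
        features.append(
            {
                "type": "Feature",
                "geometry": mapping(m.polygon),
                "properties": {
                    "kind": "municipality",
                    "id": m.id,
                    "population": m.population,
                    "annual_stroke_codes": m.annual_stroke_codes,
                    "area_km2": m.area,
                    "distance_to_nearest_csc_km": m.distance_to_nearest_csc,
                    "centroid": list(m.centroid),
                },
            }
        )
    for f in region.facilities:
        features.append(
            {
                "type": "Feature",
                "geometry": mapping(Point(f.location)),
                "properties": {"kind": "facility", "id": f.id, "role": f.role.value},
            }
        )
    return {
        "type": "FeatureCollection",
        "features": features,
        "region_spec": dataclasses.asdict(region.spec),
        "outline": mapping(region.outline),
    }


def region_from_geojson(doc: dict) -> Region:
    spec = RegionSpec(**doc["region_spec"])
    outline = shape(doc["outline"])
    municipalities: list[Municipality] = []
    facilities: list[Facility] = []
    for feat in doc["features"]:
        props = feat["properties"]
        if props["kind"] == "municipality":
            municipalities.append(
                Municipality(
                    id=props["id"],
                    centroid=tuple(props["centroid"]),
                    polygon=shape(feat["geometry"]),
                    area=props["area_km2"],
                    population=props["population"],
                    annual_stroke_codes=props["annual_stroke_codes"],
                    distance_to_nearest_csc=props["distance_to_nearest_csc_km"],
                )
            )
        else:
            geom = shape(feat["geometry"])
            facilities.append(
                Facility(props["id"], FacilityRole(props["role"]), (geom.x, geom.y))
            )
    municipalities.sort(key=lambda m: m.id)
    facilities.sort(key=lambda f: f.id)
    return Region(spec=spec, outline=outline, municipalities=municipalities, facilities=facilities)


def save_region(region: Region, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(region_to_geojson(region), fh)


def load_region(path) -> Region:
    with open(path, encoding="utf-8") as fh:
        return region_from_geojson(json.load(fh))
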