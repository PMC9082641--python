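"""Summary statistics and derived decision quantities.

Covers the study's reporting layer: median/IQR tables of onset-to-IVT and
onset-to-EVT per transport configuration (restricted to the PSC catchment
population), the paired Wilcoxon signed-rank comparison, Spearman
correlation for the dispatch-pattern analysis, the *number needed to fly*
(reciprocal of the absolute outcome-probability difference between
strategies), and time-saved rasters comparing two configurations over a
spatial grid.

Quartiles use linear interpolation between order statistics (numpy's
default, the common "type 7" rule).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely
from scipy import stats as sps

from .region import AddressPoint, FacilityRole, Region
from .timechain import DelayTable, TimeBreakdown, TransportConfig, evaluate_chain
from .travel import Period, TravelModels, nearest_facility

__all__ = [
    "DegenerateDataError",
    "OutcomeProbabilities",
    "SummaryTable",
    "median_iqr",
    "wilcoxon_signed_rank",
    "spearman",
    "number_needed_to_fly",
    "table1_summary",
    "time_saved_grid",
    "write_ascii_grid",
]

ALL_PERIODS = tuple(Period)
ALL_CONFIGS = tuple(TransportConfig)


class DegenerateDataError(ValueError):
    """Input carries no usable signal (all-zero differences, zero variance, ...)."""


@dataclass(frozen=True)
class OutcomeProbabilities:
    """Probability of an excellent outcome per strategy (conditional-probability
    model estimates for the modelled onset-to-treatment times)."""

    dripship_ground: float = 0.29
    bypass_ground: float = 0.31
    bypass_heli: float = 0.32

    def __post_init__(self):
        for name, v in self.__dict__.items():
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be a fraction in [0, 1]")


def median_iqr(values) -> tuple[float, float, float]:
    """(median, q1, q3) by linear interpolation between order statistics."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise ValueError("median_iqr of empty input")
    q1, med, q3 = np.percentile(arr, [25.0, 50.0, 75.0])
    return float(med), float(q1), float(q3)


def wilcoxon_signed_rank(paired_a, paired_b) -> tuple[float, float]:
    """Two-sided Wilcoxon signed-rank test on paired samples.

    Zero differences are dropped; the exact null distribution is used for
    n <= 25 without ties, otherwise the normal approximation with tie
    correction.
    """
    a = np.asarray(paired_a, dtype=float)
    b = np.asarray(paired_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    d = a - b
    d = d[d != 0]
    if d.size == 0:
        raise DegenerateDataError("all paired differences are zero")
    if d.size < 5:
        raise ValueError("need >= 5 non-zero paired differences")
    ties = np.unique(np.abs(d)).size < d.size
    method = "exact" if (d.size <= 25 and not ties) else "approx"
    res = sps.wilcoxon(a, b, zero_method="wilcox", correction=False, method=method)
    return float(res.statistic), float(res.pvalue)


def spearman(x, y) -> float:
    """Spearman rank correlation (Pearson correlation of mid-ranks)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 pairs")
    if np.unique(x).size == 1 or np.unique(y).size == 1:
        raise DegenerateDataError("zero variance in ranks; correlation undefined")
    rho = sps.spearmanr(x, y).statistic
    return float(rho)


def number_needed_to_fly(p_baseline: float, p_new: float) -> int:
    """Patients flown per additional good outcome: floor(1/|Δp|).

    Symmetric in its arguments; raises on a zero probability difference.
    """
    diff = abs(p_new - p_baseline)
    if diff == 0:
        raise DegenerateDataError("equal outcome probabilities: NNF is infinite")
    # small epsilon so exact reciprocals (1/0.02 -> 50) survive float rounding
    return math.floor(1.0 / diff + 1e-9)


# ---------------------------------------------------------------------------
# Table-1-style summary

@dataclass
class SummaryTable:
    """Median (IQR) of onset-to-IVT and onset-to-EVT per configuration."""

    cells: dict[tuple[str, TransportConfig], tuple[float, float, float]]
    n_samples: int

    def value(self, row: str, config: TransportConfig) -> tuple[float, float, float]:
        return self.cells[(row, config)]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for (row, cfg), (med, q1, q3) in self.cells.items():
            rows.append(
                {"outcome": row, "configuration": cfg.value,
                 "median_min": med, "q1_min": q1, "q3_min": q3}
            )
        return pd.DataFrame(rows)


def _in_psc_catchment(p: AddressPoint, region: Region, models: TravelModels, period: Period) -> bool:
    fac, _ = nearest_facility(
        p.location, {FacilityRole.PSC, FacilityRole.CSC}, region, models.ground, period
    )
    if fac.role is FacilityRole.PSC:
        return True
    if fac.role is FacilityRole.HYBRID_PSC:
        return not period.working_hours  # acts as PSC off-hours only
    return False


def table1_summary(
    region: Region,
    addresses: list[AddressPoint],
    models: TravelModels,
    delays: DelayTable,
    periods: tuple[Period, ...] = ALL_PERIODS,
    configs: tuple[TransportConfig, ...] = ALL_CONFIGS,
) -> SummaryTable:
    """Onset-to-treatment summary over the PSC-catchment address sample.

    Every address × period whose nearest stroke facility acts as a PSC in
    that period contributes one evaluation per configuration; medians and
    quartiles are pooled over addresses and periods.
    """
    if not addresses:
        raise ValueError("address set is empty")
    ivt: dict[TransportConfig, list[float]] = {c: [] for c in configs}
    evt: dict[TransportConfig, list[float]] = {c: [] for c in configs}
    n = 0
    for period in periods:
        for p in addresses:
            if not _in_psc_catchment(p, region, models, period):
                continue
            n += 1
            for cfg in configs:
                tb = evaluate_chain(p, cfg, region, models, delays, period)
                ivt[cfg].append(tb.onset_to_needle_total)
                evt[cfg].append(tb.onset_to_groin_total)
    if n == 0:
        raise ValueError("no address falls in a PSC catchment")
    cells = {}
    for cfg in configs:
        cells[("onset_to_IVT", cfg)] = median_iqr(ivt[cfg])
        cells[("onset_to_EVT", cfg)] = median_iqr(evt[cfg])
    return SummaryTable(cells=cells, n_samples=n)


# ---------------------------------------------------------------------------
# Time-saved raster

def time_saved_grid(
    region: Region,
    models: TravelModels,
    delays: DelayTable,
    resolution: float,
    comparison: tuple[TransportConfig, TransportConfig],
    period: Period = Period.MIDDAY,
    measure: str = "groin",
) -> dict:
    """Raster of per-cell time differences between two configurations.

    Each cell centre inside the region outline gets
    ``total(first) − total(second)`` of the onset-to-groin (or needle)
    totals; positive values mean the first configuration is slower there.
    Cells outside the outline are NaN. Returns ``{"x", "y", "values"}``
    with ``values[i, j]`` at ``(y[i], x[j])``.
    """
    if resolution <= 0:
        raise ValueError("resolution must be > 0")
    if measure not in ("groin", "needle"):
        raise ValueError("measure must be 'groin' or 'needle'")
    minx, miny, maxx, maxy = region.outline.bounds
    xs = np.arange(minx + resolution / 2, maxx, resolution)
    ys = np.arange(miny + resolution / 2, maxy, resolution)
    values = np.full((len(ys), len(xs)), np.nan)
    gx, gy = np.meshgrid(xs, ys)
    inside = shapely.contains_xy(region.outline, gx.ravel(), gy.ravel()).reshape(gy.shape)
    first, second = comparison
    for i in range(len(ys)):
        for j in range(len(xs)):
            if not inside[i, j]:
                continue
            pt = (float(xs[j]), float(ys[i]))
            ta = evaluate_chain(pt, first, region, models, delays, period)
            tb = evaluate_chain(pt, second, region, models, delays, period)
            if measure == "groin":
                values[i, j] = ta.onset_to_groin_total - tb.onset_to_groin_total
            else:
                values[i, j] = ta.onset_to_needle_total - tb.onset_to_needle_total
    return {"x": xs, "y": ys, "values": values, "resolution": resolution}


def write_ascii_grid(grid: dict, path, nodata: float = -9999.0) -> None:
    """Write a raster as an ESRI-ASCII-style text grid."""
    values = np.where(np.isnan(grid["values"]), nodata, grid["values"])
    xs, ys, res = grid["x"], grid["y"], grid["resolution"]
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"ncols {len(xs)}\n")
        fh.write(f"nrows {len(ys)}\n")
        fh.write(f"xllcorner {xs[0] - res / 2:.6f}\n")
        fh.write(f"yllcorner {ys[0] - res / 2:.6f}\n")
        fh.write(f"cellsize {res:.6f}\n")
        fh.write(f"NODATA_value {nodata}\n")
        for row in values[::-1]:  # ASCII grids run north to south
            fh.write(" ".join(f"{v:.3f}" for v in row) + "\n")
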