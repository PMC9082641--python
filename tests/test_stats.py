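"""Summary statistics against brute-force oracles, and the decision quantities."""

import itertools
import math

import numpy as np
import pytest

import helistroke as hs
from helistroke.stats import (
    DegenerateDataError,
    OutcomeProbabilities,
    median_iqr,
    number_needed_to_fly,
    spearman,
    table1_summary,
    time_saved_grid,
    wilcoxon_signed_rank,
    write_ascii_grid,
)
from helistroke.timechain import TransportConfig
from tests.conftest import make_line_region


# --- independent oracles ---------------------------------------------------

def sort_quantile(values, q):
    """Type-7 quantile by explicit sorting and interpolation."""
    s = sorted(values)
    h = (len(s) - 1) * q
    lo, hi = math.floor(h), math.ceil(h)
    return s[lo] + (h - lo) * (s[hi] - s[lo])


def midrank(values):
    s = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(s):
        j = i
        while j + 1 < len(s) and values[s[j + 1]] == values[s[i]]:
            j += 1
        r = (i + j) / 2 + 1
        for k in range(i, j + 1):
            ranks[s[k]] = r
        i = j + 1
    return ranks


def pearson(x, y):
    mx, my = np.mean(x), np.mean(y)
    num = np.sum((np.array(x) - mx) * (np.array(y) - my))
    return num / math.sqrt(np.sum((np.array(x) - mx) ** 2) * np.sum((np.array(y) - my) ** 2))


def wilcoxon_exact_enumeration(a, b):
    """Exact two-sided p by enumerating all sign assignments of |d| ranks."""
    d = np.asarray(a, float) - np.asarray(b, float)
    d = d[d != 0]
    ranks = midrank(np.abs(d).tolist())
    w_plus = sum(r for r, di in zip(ranks, d) if di > 0)
    n = len(d)
    stats = [sum(r for r, s in zip(ranks, signs) if s) for signs in itertools.product([0, 1], repeat=n)]
    w_min = min(w_plus, sum(ranks) - w_plus)
    p = sum(1 for w in stats if min(w, sum(ranks) - w) <= w_min + 1e-12) / 2**n
    return min(p, 1.0)


# --- median / IQR ----------------------------------------------------------

class TestMedianIQR:
    @pytest.mark.parametrize(
        "values,expected",
        [
            ([1, 2, 3], (2.0, 1.5, 2.5)),
            ([5, 5, 5, 5], (5.0, 5.0, 5.0)),
        ],
    )
    def test_small_cases(self, values, expected):
        assert median_iqr(values) == pytest.approx(expected)

    def test_matches_sort_oracle_on_many_random_inputs(self):
        rng = np.random.default_rng(0)
        for _ in range(120):
            vals = rng.normal(100, 30, size=rng.integers(1, 50)).tolist()
            med, q1, q3 = median_iqr(vals)
            assert med == pytest.approx(sort_quantile(vals, 0.5))
            assert q1 == pytest.approx(sort_quantile(vals, 0.25))
            assert q3 == pytest.approx(sort_quantile(vals, 0.75))
            assert q1 <= med <= q3

    def test_empty_input_errors(self):
        with pytest.raises(ValueError):
            median_iqr([])


# --- Wilcoxon --------------------------------------------------------------

class TestWilcoxon:
    def test_identical_samples_degenerate(self):
        with pytest.raises(DegenerateDataError):
            wilcoxon_signed_rank([1, 2, 3, 4, 5, 6], [1, 2, 3, 4, 5, 6])

    def test_extreme_separation_significant(self):
        a = np.arange(20) + 100.0
        b = np.arange(20) * 1.0
        _, p = wilcoxon_signed_rank(a, b)
        assert p < 0.05

    def test_exact_p_matches_sign_flip_enumeration_n6(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            a = rng.normal(0, 1, size=6)
            b = a + rng.normal(0.5, 1, size=6)
            if np.unique(np.abs(a - b)).size < 6:
                continue  # oracle below assumes untied ranks
            _, p = wilcoxon_signed_rank(a, b)
            assert p == pytest.approx(wilcoxon_exact_enumeration(a, b), abs=1e-10)

    def test_large_sample_approximation_reasonable(self):
        rng = np.random.default_rng(2)
        a = rng.normal(0, 1, size=100)
        b = a + rng.normal(0, 1, size=100)
        stat, p = wilcoxon_signed_rank(a, b)
        assert 0.0 <= p <= 1.0

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_signed_rank([1, 2, 3], [2, 3, 4])


# --- Spearman --------------------------------------------------------------

class TestSpearman:
    def test_perfect_monotone(self):
        x = [1, 2, 3, 4, 5]
        assert spearman(x, [2, 4, 9, 16, 30]) == pytest.approx(1.0)
        assert spearman(x, [-1, -3, -4, -9, -20]) == pytest.approx(-1.0)

    def test_matches_midrank_pearson_oracle_with_ties(self):
        rng = np.random.default_rng(3)
        for _ in range(120):
            n = int(rng.integers(4, 30))
            x = rng.integers(0, 6, size=n).astype(float)  # heavy ties
            y = x + rng.integers(-2, 3, size=n)
            if np.unique(x).size == 1 or np.unique(y).size == 1:
                continue
            expected = pearson(midrank(x.tolist()), midrank(y.tolist()))
            assert spearman(x, y) == pytest.approx(expected, abs=1e-12)

    def test_zero_variance_errors(self):
        with pytest.raises(DegenerateDataError):
            spearman([1, 1, 1, 1], [1, 2, 3, 4])


# --- number needed to fly --------------------------------------------------

class TestNumberNeededToFly:
    @pytest.mark.parametrize(
        "p0,p1,expected",
        [
            (0.29, 0.32, 33),  # headline absolute gain of 3%
            (0.5, 0.75, 4),
            (0.29, 0.31, 50),
        ],
    )
    def test_known_values(self, p0, p1, expected):
        assert number_needed_to_fly(p0, p1) == expected

    def test_symmetric(self):
        rng = np.random.default_rng(4)
        for _ in range(50):
            p, q = rng.uniform(0, 1, size=2)
            if p == q:
                continue
            assert number_needed_to_fly(p, q) == number_needed_to_fly(q, p)

    def test_equal_probabilities_error(self):
        with pytest.raises(DegenerateDataError):
            number_needed_to_fly(0.3, 0.3)

    def test_default_outcome_probabilities_valid(self):
        probs = OutcomeProbabilities()
        assert number_needed_to_fly(probs.dripship_ground, probs.bypass_heli) == 33


# --- Table-1 summary -------------------------------------------------------

def plain_models():
    ground = hs.GroundModel(base_speed=60.0, detour_factor=1.0,
                            period_multipliers={p: 1.0 for p in hs.Period})
    return hs.TravelModels(ground=ground, air=hs.AirModel(240.0))


class TestTable1Summary:
    def test_single_address_medians_equal_that_address(self, delays):
        region = make_line_region(psc_x=126.0, csc_x=200.0)
        addr = hs.AddressPoint(0, (100.0, 50.0))
        table = table1_summary(region, [addr], plain_models(), delays,
                               periods=(hs.Period.MIDDAY,))
        med, q1, q3 = table.value("onset_to_IVT", TransportConfig.DRIP_SHIP_GROUND)
        assert med == q1 == q3 == pytest.approx(112.0)

    def test_degenerate_colocated_region_ground_ivt_86(self, delays):
        region = make_line_region(psc_x=100.0, csc_x=100.0, base_x=100.0)
        # let the PSC win the tie-break so the address counts as PSC catchment
        import dataclasses
        region.facilities[:] = [
            dataclasses.replace(f, id={1: 0, 0: 1, 2: 2}[f.id]) for f in region.facilities
        ]
        addr = hs.AddressPoint(0, (100.0, 50.0))
        table = table1_summary(region, [addr], plain_models(), delays,
                               periods=(hs.Period.MIDDAY,))
        for cfg in (TransportConfig.DRIP_SHIP_GROUND, TransportConfig.BYPASS_GROUND):
            med, _, _ = table.value("onset_to_IVT", cfg)
            assert med == pytest.approx(86.0)

    def test_bypass_evt_minus_ivt_median_is_41(self, default_region, models, delays):
        addresses = hs.sample_addresses(default_region, 3, seed=5)
        table = table1_summary(default_region, addresses, models, delays)
        for cfg in (TransportConfig.BYPASS_GROUND, TransportConfig.BYPASS_HELI):
            evt, _, _ = table.value("onset_to_EVT", cfg)
            ivt, _, _ = table.value("onset_to_IVT", cfg)
            assert evt - ivt == pytest.approx(41.0)

    def test_empty_address_set_rejected(self, default_region, models, delays):
        with pytest.raises(ValueError):
            table1_summary(default_region, [], models, delays)


# --- time-saved raster -----------------------------------------------------

class TestTimeSavedGrid:
    def test_self_comparison_all_zero(self, delays):
        region = make_line_region()
        grid = time_saved_grid(region, plain_models(), delays, 50.0,
                               (TransportConfig.BYPASS_GROUND, TransportConfig.BYPASS_GROUND))
        inside = grid["values"][~np.isnan(grid["values"])]
        assert inside.size > 0
        assert np.all(inside == 0.0)

    def test_colocated_facilities_delta_minus_33(self, delays):
        """Where PSC and CSC coincide, bypass beats drip-and-ship to the groin
        by exactly door_in_door_out + dripship groin delay − bypass groin delay."""
        region = make_line_region(psc_x=200.0, csc_x=200.0, base_x=200.0)
        grid = time_saved_grid(region, plain_models(), delays, 100.0,
                               (TransportConfig.BYPASS_GROUND, TransportConfig.DRIP_SHIP_GROUND))
        inside = grid["values"][~np.isnan(grid["values"])]
        assert np.allclose(inside, -33.0)

    def test_heli_advantage_grows_with_distance_from_csc(self, delays):
        """Along a ray away from the CSC, the bypass-ground minus bypass-heli
        groin difference grows once past the helicopter viability cutoff."""
        region = make_line_region(csc_x=0.0, base_x=0.0, psc_x=350.0, width=800.0)
        models = plain_models()
        deltas = []
        for x in range(50, 750, 50):
            a = hs.evaluate_chain((float(x), 50.0), TransportConfig.BYPASS_GROUND,
                                  region, models, delays, hs.Period.MIDDAY)
            b = hs.evaluate_chain((float(x), 50.0), TransportConfig.BYPASS_HELI,
                                  region, models, delays, hs.Period.MIDDAY)
            deltas.append(a.onset_to_groin_total - b.onset_to_groin_total)
        assert all(d2 >= d1 - 1e-9 for d1, d2 in zip(deltas, deltas[1:]))
        assert deltas[-1] > deltas[0]

    def test_ascii_grid_export(self, delays, tmp_path):
        region = make_line_region()
        grid = time_saved_grid(region, plain_models(), delays, 100.0,
                               (TransportConfig.BYPASS_GROUND, TransportConfig.BYPASS_HELI))
        path = tmp_path / "grid.asc"
        write_ascii_grid(grid, path)
        lines = path.read_text().splitlines()
        assert lines[0].startswith("ncols")
        assert len(lines) == 6 + len(grid["y"])

    def test_bad_resolution_rejected(self, default_region, models, delays):
        with pytest.raises(ValueError):
            time_saved_grid(default_region, models, delays, 0.0,
                            (TransportConfig.BYPASS_GROUND, TransportConfig.BYPASS_HELI))
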