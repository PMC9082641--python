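"""Mission generation and the fleet discrete-event simulation."""

import math

import numpy as np
import pandas as pd
import pytest

import helistroke as hs
from helistroke.fleet import (
    CatchmentZone,
    FleetConfig,
    MissionKind,
    MissionRequest,
    QueuePolicy,
    daily_request_rate,
    calibrate_demand_multiplier,
    eligible_municipalities,
    generate_missions,
    mission_duration,
    scenario_sweep,
    simulate,
    summarize_sweep,
)
from helistroke.region import Facility, FacilityRole
from tests.conftest import make_line_region

BASE = Facility(0, FacilityRole.HELI_BASE, (0.0, 0.0))
DEST = Facility(1, FacilityRole.CSC, (0.0, 0.0))


def fixed_fleet(**kw):
    defaults = dict(bases=(BASE,), helicopters_per_base=1, availability=1.0,
                    service_mode="FIXED_AVERAGE", fixed_mission_minutes=165.0)
    defaults.update(kw)
    return FleetConfig(**defaults)


def mk_missions(times, origin=(0.0, 0.0)):
    return [MissionRequest(float(t), origin, 0, DEST, MissionKind.STROKE_CODE) for t in times]


class TestGenerateMissions:
    def test_zero_rates_empty(self, default_region, models):
        import dataclasses

        region = hs.Region(
            spec=default_region.spec,
            outline=default_region.outline,
            municipalities=[
                dataclasses.replace(m, annual_stroke_codes=0)
                for m in default_region.municipalities
            ],
            facilities=list(default_region.facilities),
        )
        assert generate_missions(region, CatchmentZone.LARGE, 10, 0.0, 1, models) == []

    def test_counts_match_poisson_mean_within_3_sigma(self, default_region, models):
        """Over 100 seeds the mean mission count matches the configured
        total daily rate within 3 standard errors of the Poisson law."""
        horizon = 5.0
        rate = daily_request_rate(default_region, CatchmentZone.LARGE, models.ground, 2.0)
        lam = rate * horizon
        counts = [
            len(generate_missions(default_region, CatchmentZone.LARGE, horizon, 2.0, s, models))
            for s in range(100)
        ]
        se = math.sqrt(lam / 100)
        assert abs(np.mean(counts) - lam) < 3 * se

    def test_zone_enlargement_grows_eligible_set(self, default_region, models):
        small = set(eligible_municipalities(default_region, CatchmentZone.SMALL, models.ground))
        middle = set(eligible_municipalities(default_region, CatchmentZone.MIDDLE, models.ground))
        large = set(eligible_municipalities(default_region, CatchmentZone.LARGE, models.ground))
        assert small <= middle <= large

    def test_zone_streams_are_nested_for_shared_seed(self, default_region, models):
        ms = generate_missions(default_region, CatchmentZone.SMALL, 20, 5.6, 9, models)
        ml = generate_missions(default_region, CatchmentZone.LARGE, 20, 5.6, 9, models)
        key = lambda m: (m.arrival_time, m.origin, m.kind)
        assert {key(m) for m in ms} <= {key(m) for m in ml}

    def test_missions_time_sorted_with_shs_destination(self, default_region, models):
        ms = generate_missions(default_region, CatchmentZone.MIDDLE, 10, 5.6, 4, models)
        times = [m.arrival_time for m in ms]
        assert times == sorted(times)
        assert all(m.destination_shs.role in hs.SHS_ROLES for m in ms)


class TestMissionDuration:
    def test_fixed_average_always_165(self):
        req = mk_missions([0.0])[0]
        assert mission_duration(req, BASE, fixed_fleet()) == 165.0

    def test_computed_degenerate_distances(self):
        fleet = fixed_fleet(service_mode="COMPUTED", handover_minutes=0.0)
        req = mk_missions([0.0])[0]
        assert mission_duration(req, BASE, fleet, hs.DelayTable(), hs.AirModel()) == pytest.approx(16.0)

    def test_computed_hand_trace(self):
        # base->origin 40 km (10 min), origin->SHS 80 km (20), SHS->base 100 km (25):
        # 5 + 10 + 11 + 20 + 15 + 25 = 86
        shs = Facility(1, FacilityRole.CSC, (80.0, 0.0))
        base = Facility(0, FacilityRole.HELI_BASE, (-12.5, math.sqrt(1600 - 12.5**2)))
        assert math.dist(base.location, (0.0, 0.0)) == pytest.approx(40.0)
        assert math.dist(base.location, shs.location) == pytest.approx(100.0)
        req = MissionRequest(0.0, (0.0, 0.0), 0, shs, MissionKind.STROKE_CODE)
        fleet = fixed_fleet(service_mode="COMPUTED", handover_minutes=15.0)
        assert mission_duration(req, base, fleet, hs.DelayTable(), hs.AirModel()) == pytest.approx(86.0)


class TestSimulate:
    def test_zero_missions_zero_counters(self):
        res = simulate([], fixed_fleet(), QueuePolicy(), seed=0)
        assert (res.n_requests, res.n_served, res.n_queued, res.n_rejected) == (0, 0, 0, 0)

    def test_single_mission_served_immediately(self):
        res = simulate(mk_missions([100.0]), fixed_fleet(), QueuePolicy(), seed=0)
        assert res.n_served == 1 and res.n_queued == 0 and res.n_rejected == 0
        assert res.waits[0] == 0.0

    def test_two_simultaneous_one_helicopter(self):
        """Second patient waits past 15 min (queued) and is rejected at 60."""
        res = simulate(mk_missions([0.0, 0.0]), fixed_fleet(), QueuePolicy(), seed=0)
        assert res.n_served == 1
        assert res.n_queued == 1
        assert res.n_rejected == 1

    def test_release_just_before_rejection_saves_patient(self):
        # helicopter frees at t=60 == second arrival + reject threshold:
        # the release is processed first, so the patient is served, not rejected
        fleet = fixed_fleet(fixed_mission_minutes=60.0)
        res = simulate(mk_missions([0.0, 0.0]), fleet, QueuePolicy(), seed=0)
        assert res.n_rejected == 0
        assert res.n_served == 2
        assert res.waits[1] == pytest.approx(60.0)
        assert res.n_queued == 1  # waited 60 > 15

    def test_counter_conservation_random_loads(self):
        rng = np.random.default_rng(0)
        for trial in range(10):
            times = np.sort(rng.uniform(0, 5000, size=rng.integers(1, 200)))
            fleet = fixed_fleet(availability=0.8, helicopters_per_base=rng.integers(1, 3))
            res = simulate(mk_missions(times), fleet, QueuePolicy(), seed=trial)
            assert res.n_served + res.n_rejected == res.n_requests
            assert res.n_queued >= res.n_rejected

    def test_unsorted_missions_rejected(self):
        with pytest.raises(ValueError):
            simulate(mk_missions([10.0, 5.0]), fixed_fleet(), QueuePolicy(), seed=0)

    def test_bit_identical_across_runs(self):
        times = np.sort(np.random.default_rng(5).uniform(0, 10000, size=300))
        fleet = fixed_fleet(availability=0.9, helicopters_per_base=2)
        a = simulate(mk_missions(times), fleet, QueuePolicy(), seed=42)
        b = simulate(mk_missions(times), fleet, QueuePolicy(), seed=42)
        assert np.array_equal(a.waits, b.waits, equal_nan=True)
        assert a.utilization == b.utilization

    def test_utilization_matches_offered_load(self):
        """availability 1, no rejection, single base: per-helicopter
        utilization equals arrival_rate x mean_service / c within 3 MC SEs."""
        rng = np.random.default_rng(7)
        lam, mean_s, c = 1 / 100.0, 120.0, 2
        n = 20_000
        times = np.cumsum(rng.exponential(1 / lam, size=n))
        fleet = fixed_fleet(service_mode="EXPONENTIAL", fixed_mission_minutes=mean_s,
                            helicopters_per_base=c)
        res = simulate(mk_missions(times), fleet, QueuePolicy(15.0, float("inf")), seed=3)
        expected = lam * mean_s / c
        # binomial-ish SE for the busy fraction over ~n service periods
        se = expected / math.sqrt(n)
        assert abs(res.utilization[0] - expected) < 5 * se + 0.01

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            FleetConfig(bases=(), helicopters_per_base=1)
        with pytest.raises(ValueError):
            fixed_fleet(availability=0.0)
        with pytest.raises(ValueError):
            QueuePolicy(queue_threshold=60, reject_threshold=60)


class TestScenarioSweep:
    def test_single_replicate_shape(self, default_region, models, delays):
        df = scenario_sweep(default_region, models, delays, n_reps=1, seed=0)
        assert len(df) == 6  # 3 zones x 2 fleet sizes
        assert set(df["zone"]) == {"LARGE", "MIDDLE", "SMALL"}

    def test_more_helicopters_never_worse_paired(self, default_region, models, delays):
        df = scenario_sweep(default_region, models, delays, n_reps=15, seed=3)
        for col in ("n_rejected", "n_queued"):
            p = df.pivot_table(index=["zone", "replicate"], columns="helicopters_per_base",
                               values=col)
            assert (p[2] <= p[1]).all()

    def test_larger_zone_more_rejections_on_average(self, default_region, models, delays):
        # streams are nested per replicate (SMALL ⊂ MIDDLE ⊂ LARGE), so the
        # extra workload of a larger zone raises mean congestion
        df = scenario_sweep(default_region, models, delays, n_reps=60, seed=6,
                            heli_options=(1,))
        means = df.groupby("zone")["n_rejected"].mean()
        assert means["SMALL"] <= means["MIDDLE"] <= means["LARGE"]

    def test_demand_calibration_hits_fleet_tempo(self, default_region, models):
        mult = calibrate_demand_multiplier(default_region, models.ground, 11.2, 5.6)
        rate = daily_request_rate(default_region, CatchmentZone.LARGE, models.ground, 5.6, mult)
        assert rate == pytest.approx(11.2)

    def test_summary_has_one_row_per_cell(self, default_region, models, delays):
        df = scenario_sweep(default_region, models, delays, n_reps=3, seed=1)
        summary = summarize_sweep(df)
        assert len(summary) == 6
        assert (summary["rejected_q1"] <= summary["rejected_q3"]).all()
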