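"""Virtual chamber: baseline generator, scenarios, event revelation."""

import datetime as dt
from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from peakshift import (
    OffsetSchedule,
    ScenarioConfig,
    TemperatureSeries,
    estimate_distribution,
    find_peak,
    generate_baseline_temperature,
    map_real_date,
    map_virtual_date,
    predict_harvest_date,
    run_control_loop,
)
from peakshift.emulator import (
    DEFAULT_ANCHOR,
    REGULATION_START,
    VIRTUAL_SEASON_END,
    ChamberEmulator,
)

REG_WINDOW = (REGULATION_START, VIRTUAL_SEASON_END)


class TestBaselineGenerator:
    def test_deterministic_per_seed(self):
        a = generate_baseline_temperature(42)
        b = generate_baseline_temperature(42)
        assert a.start == b.start
        np.testing.assert_array_equal(a.values, b.values)

    def test_pre_period_fixed_at_19(self):
        base = generate_baseline_temperature(0)
        pre = base.window(base.start, REGULATION_START - dt.timedelta(days=1))
        assert np.all(pre == 19.0)

    def test_regulation_statistics_and_range(self):
        for seed in range(5):
            reg = generate_baseline_temperature(seed).window(*REG_WINDOW)
            assert abs(reg.mean() - 13.62) <= 0.2
            assert abs(reg.std(ddof=0) - 1.99) <= 0.3
            assert reg.min() >= 8.65 and reg.max() <= 18.19

    def test_inverted_clamp_rejected(self):
        with pytest.raises(ValueError, match="inverted"):
            generate_baseline_temperature(0, clamp=(18.0, 8.0))


class TestVirtualCalendar:
    def test_anchor_maps_campaign_start(self):
        assert map_virtual_date(dt.date(2022, 4, 28)) == dt.date(2019, 11, 14)
        assert map_real_date(dt.date(2019, 11, 14)) == dt.date(2022, 4, 28)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.dates(dt.date(2019, 1, 1), dt.date(2024, 12, 31)))
    def test_round_trip_identity(self, real):
        assert map_real_date(map_virtual_date(real)) == real

    def test_anchor_shift_shifts_mapping(self):
        real_ref, virt_ref = DEFAULT_ANCHOR
        shifted = (real_ref + dt.timedelta(days=5), virt_ref)
        day = dt.date(2022, 6, 1)
        assert (map_virtual_date(day, DEFAULT_ANCHOR)
                - map_virtual_date(day, shifted)).days == 5


class TestScenarios:
    def test_population_size(self):
        sc = replace(ScenarioConfig("HT", rng_seed=2), n_plants=7).perfect_model()
        emu = ChamberEmulator(sc)
        assert len(emu.records()) == 49  # 7 plants x 7 flower slots

    @pytest.mark.parametrize("kind,shift", [("CT", 0), ("CL", -7), ("HT", 7)])
    def test_uncontrolled_peak_lands_on_shifted_reference(self, kind, shift):
        """Zero noise, no control: the realized peak sits within a day of
        reference + shift (daily back-calculation granularity)."""
        sc = ScenarioConfig(scenario_kind=kind, rng_seed=3).perfect_model()
        emu = ChamberEmulator(sc)
        recs = emu.advance_to(emu.baseline.end, OffsetSchedule())
        harvests = [r.harvest_observed for r in recs if r.harvest_observed]
        peak = find_peak(estimate_distribution(harvests)).peak_date
        expected = sc.reference_peak + dt.timedelta(days=shift)
        assert abs((peak - expected).days) <= 1

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            ScenarioConfig(scenario_kind="XX")


class TestAdvance:
    def test_advance_is_idempotent_at_same_date(self):
        sc = ScenarioConfig("CT", rng_seed=4).perfect_model()
        emu = ChamberEmulator(sc)
        day = dt.date(2019, 12, 10)
        first = emu.advance_to(day, OffsetSchedule())
        second = emu.advance_to(day, OffsetSchedule())
        assert first == second

    def test_rewind_rejected(self):
        sc = ScenarioConfig("CT", rng_seed=4).perfect_model()
        emu = ChamberEmulator(sc)
        emu.advance_to(dt.date(2019, 12, 10), OffsetSchedule())
        with pytest.raises(ValueError, match="rewind"):
            emu.advance_to(dt.date(2019, 12, 1), OffsetSchedule())

    def test_reveal_is_monotone(self):
        sc = ScenarioConfig("CT", rng_seed=6)
        emu = ChamberEmulator(sc)
        seen: set = set()
        for day in [dt.date(2019, 11, 20), dt.date(2019, 12, 10), dt.date(2020, 1, 10)]:
            recs = emu.advance_to(day, OffsetSchedule())
            now = {(r.plant_id, r.flower_order, r.flowering_observed, r.harvest_observed)
                   for r in recs if r.flowering_observed}
            assert {s[:2] for s in seen} <= {n[:2] for n in now}
            seen = now

    def test_perfect_model_reveals_predicted_harvests(self):
        """Zero noise: every revealed harvest equals the maturation module's
        prediction from the revealed flowering date (oracle identity)."""
        sc = ScenarioConfig("CT", rng_seed=8).perfect_model()
        emu = ChamberEmulator(sc)
        recs = emu.advance_to(emu.baseline.end, OffsetSchedule())
        for r in recs:
            if r.harvest_observed is None:
                continue
            pred = predict_harvest_date(r.flowering_observed, emu.baseline, sc.truth_model)
            assert pred.date == r.harvest_observed

    def test_constant_offset_accelerates_maturation(self):
        """+2 degC from flowering on a constant 13 degC baseline: harvest
        ~7 days earlier (600/15 = 40 vs 600/13 -> 47 days)."""
        start = dt.date(2019, 10, 1)
        baseline = TemperatureSeries.constant(start, 200, 13.0)
        sc = replace(
            ScenarioConfig("CT", rng_seed=0), n_plants=1, fruits_per_plant=1,
            reference_peak=dt.date(2019, 12, 21),
        ).perfect_model()
        warm, cold = {}, {}
        for label, offs in (("cold", 0.0), ("warm", 2.0)):
            emu = ChamberEmulator(sc, baseline=baseline)
            sched = OffsetSchedule()
            if offs:
                sched.set_from(start, offs)
            recs = emu.advance_to(baseline.end, sched)
            (rec,) = [r for r in recs if r.harvest_observed]
            (cold if label == "cold" else warm)["f"] = rec.flowering_observed
            (cold if label == "cold" else warm)["h"] = rec.harvest_observed
        assert (cold["h"] - cold["f"]).days == 47
        assert (warm["h"] - warm["f"]).days == 40


class TestClosedLoopProperties:
    def test_flowering_scarcity_degrades_cooling_control(self):
        """With late flowers absent (3 fruits per plant) while the predictor
        still counts on the full complement, cooling control ends farther
        from the target than the full-population run with the same seed."""
        results = {}
        for fpp in (7, 3):
            sc = replace(
                ScenarioConfig("CL", rng_seed=1), fruits_per_plant=fpp
            ).perfect_model()
            results[fpp] = run_control_loop(ChamberEmulator(sc)).terminal_residual_days
        assert abs(results[3]) > abs(results[7])

    def test_offset_magnitude_narrows_as_harvests_accrue(self):
        """In a perfect-model run the chosen |dT| never grows over the update
        sequence once harvest observations start pinning the distribution."""
        sc = ScenarioConfig("HT", rng_seed=1).perfect_model()
        res = run_control_loop(ChamberEmulator(sc))
        mags = [abs(log.chosen_offset) for log in res.history]
        assert all(b <= a + 1e-9 for a, b in zip(mags, mags[1:]))
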