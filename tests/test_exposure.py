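"""LCT definitions, exposure proportions and quartile categorisation."""

from datetime import datetime, timedelta

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from calftherm.exposure import (
    B2G_SCHEME,
    G2E_SCHEME,
    AgeLCTSchedule,
    PhysiologicalLCTParams,
    categorise_exposure,
    exposure_proportion,
    lct_for_age,
    physiological_lct,
)


def et_frame(values, start="2019-01-01"):
    ts = pd.date_range(start, periods=len(values), freq="h")
    return pd.DataFrame({"timestamp": ts,
                         "effective_temp": np.asarray(values, dtype=float)})


def brute_force_proportion(birth, start, end, frame, schedule):
    """Hour-by-hour enumeration oracle, independent of the vector path."""
    below = total = 0
    for _, row in frame.iterrows():
        h = row["timestamp"]
        if not (start <= h < end):
            continue
        total += 1
        age = int((h - pd.Timestamp(birth)).total_seconds() // 3600) // 24
        lct = schedule.lct_at_birth - schedule.daily_decline * age
        if schedule.floor is not None:
            lct = max(lct, schedule.floor)
        if row["effective_temp"] < lct:
            below += 1
    return below, total


class TestAgeSchedule:
    @pytest.mark.parametrize("age,expected", [(0, 15.0), (10, 10.0),
                                              (30, 0.0), (20, 5.0)])
    def test_default_schedule(self, age, expected):
        assert lct_for_age(age) == pytest.approx(expected)

    def test_floor_clips(self):
        sched = AgeLCTSchedule(floor=5.0)
        assert lct_for_age(40, sched) == 5.0

    def test_negative_age_rejected(self):
        with pytest.raises(ValueError):
            lct_for_age(-1)

    def test_non_increasing_in_age(self):
        ages = np.arange(0, 60)
        assert np.all(np.diff(lct_for_age(ages)) <= 0)


class TestPhysiologicalLCT:
    def test_reduces_to_rectal_temp_without_heat_terms(self):
        p = PhysiologicalLCTParams(rectal_temp=39.0, external_insulation=0.2,
                                   min_evaporative_heat_loss=0.0,
                                   thermoneutral_heat_production=0.0,
                                   tissue_insulation=0.1)
        assert physiological_lct(p) == pytest.approx(39.0)

    def test_direct_substitution(self):
        p = PhysiologicalLCTParams(rectal_temp=39.0, external_insulation=0.1,
                                   min_evaporative_heat_loss=10.0,
                                   thermoneutral_heat_production=60.0,
                                   tissue_insulation=0.05)
        assert physiological_lct(p) == pytest.approx(31.0)

    def test_more_tissue_insulation_lowers_lct(self):
        base = dict(rectal_temp=39.0, external_insulation=0.1,
                    min_evaporative_heat_loss=10.0,
                    thermoneutral_heat_production=60.0)
        lo = physiological_lct(PhysiologicalLCTParams(**base,
                                                      tissue_insulation=0.05))
        hi = physiological_lct(PhysiologicalLCTParams(**base,
                                                      tissue_insulation=0.10))
        assert hi < lo

    def test_negative_insulation_rejected(self):
        with pytest.raises(ValueError):
            PhysiologicalLCTParams(39.0, -0.1, 10.0, 60.0, 0.05)


class TestCategorise:
    @pytest.mark.parametrize("p,label", [
        (0.32, "<=0.32"), (0.33, "0.33-0.58"), (0.58, "0.33-0.58"),
        (0.59, "0.59-0.96"), (0.96, "0.59-0.96"), (0.97, ">=0.97"),
        (0.585, "0.59-0.96"),  # rounds half-up to 0.59
        (0.325, "0.33-0.58"),  # rounds half-up to 0.33
        (0.0, "<=0.32"), (1.0, ">=0.97"),
    ])
    def test_b2g_boundaries(self, p, label):
        assert categorise_exposure(p, B2G_SCHEME) == label

    @pytest.mark.parametrize("p,label", [
        (0.01, "<=0.01"), (0.02, "0.02-0.06"), (0.06, "0.02-0.06"),
        (0.07, "0.07-0.27"), (0.27, "0.07-0.27"), (0.28, ">=0.28"),
        (0.015, "0.02-0.06"), (0.0, "<=0.01"),
    ])
    def test_g2e_boundaries(self, p, label):
        assert categorise_exposure(p, G2E_SCHEME) == label

    def test_every_proportion_maps_to_exactly_one_band(self):
        for scheme in (B2G_SCHEME, G2E_SCHEME):
            for cents in range(101):
                assert categorise_exposure(cents / 100, scheme) in scheme.labels

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            categorise_exposure(1.2, B2G_SCHEME)


class TestExposureProportion:
    birth = datetime(2019, 1, 1, 0, 0)

    def test_warm_window_proportion_zero(self):
        frame = et_frame([20.0] * 240)
        s = exposure_proportion(self.birth, self.birth,
                                self.birth + timedelta(days=10), frame)
        assert s.proportion == 0.0 and s.hours_below == 0
        assert s.total_hours == 240 and s.category == "<=0.32"

    def test_freezing_window_proportion_one(self):
        frame = et_frame([-10.0] * 240)
        s = exposure_proportion(self.birth, self.birth,
                                self.birth + timedelta(days=10), frame)
        assert s.proportion == 1.0 and s.category == ">=0.97"

    def test_crafted_quarter_exposure_counted_by_enumeration(self):
        # 48-h window; 12 cold hours placed on day 1 where LCT is 14.5
        values = np.full(48, 20.0)
        values[30:42] = 14.0
        frame = et_frame(values)
        end = self.birth + timedelta(hours=48)
        s = exposure_proportion(self.birth, self.birth, end, frame)
        oracle = brute_force_proportion(self.birth, pd.Timestamp(self.birth),
                                        pd.Timestamp(end), frame,
                                        AgeLCTSchedule())
        assert oracle == (12, 48)
        assert (s.hours_below, s.total_hours) == oracle
        assert s.proportion == pytest.approx(0.25)

    def test_lct_step_at_day_boundary(self):
        # ET 14.7 straddling the age-0 (LCT 15) / age-1 (LCT 14.5) step:
        # only the age-0 hours count as below
        values = np.full(48, 20.0)
        values[20:32] = 14.7
        frame = et_frame(values)
        s = exposure_proportion(self.birth, self.birth,
                                self.birth + timedelta(hours=48), frame)
        assert s.hours_below == 4  # hours 20..23 (age 0)

    def test_equality_is_not_below(self):
        frame = et_frame([15.0] * 24)
        s = exposure_proportion(self.birth, self.birth,
                                self.birth + timedelta(hours=24), frame)
        assert s.hours_below == 0

    def test_missing_hours_excluded_both_sides(self):
        frame = et_frame([-10.0] * 48)
        frame = frame.drop(index=range(10, 20)).reset_index(drop=True)
        s = exposure_proportion(self.birth, self.birth,
                                self.birth + timedelta(hours=48), frame)
        assert s.total_hours == 38 and s.proportion == 1.0

    def test_no_hours_available_is_an_error(self):
        frame = et_frame([0.0] * 24, start="2020-06-01")
        with pytest.raises(ValueError, match="no climate hours"):
            exposure_proportion(self.birth, self.birth,
                                self.birth + timedelta(hours=24), frame)

    def test_window_before_birth_rejected(self):
        frame = et_frame([0.0] * 24)
        with pytest.raises(ValueError):
            exposure_proportion(self.birth + timedelta(hours=5), self.birth,
                                self.birth + timedelta(hours=24), frame)

    @given(st.integers(0, 2**31 - 1))
    def test_matches_brute_force_on_random_instances(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(24, 120))
        frame = et_frame(rng.normal(12, 6, n))
        birth = pd.Timestamp("2019-01-01") + pd.Timedelta(
            hours=int(rng.integers(0, 12)))
        start = birth + pd.Timedelta(hours=int(rng.integers(0, 6)))
        end = start + pd.Timedelta(hours=int(rng.integers(5, n - 20)))
        s = exposure_proportion(birth, start, end, frame)
        below, total = brute_force_proportion(birth, start, end, frame,
                                              AgeLCTSchedule())
        assert (s.hours_below, s.total_hours) == (below, total)
        assert 0.0 <= s.proportion <= 1.0

    def test_conserved_under_window_splitting(self):
        rng = np.random.default_rng(7)
        frame = et_frame(rng.normal(12, 6, 200))
        birth = pd.Timestamp("2019-01-01")
        end = birth + pd.Timedelta(hours=200)
        whole = exposure_proportion(birth, birth, end, frame)
        mid = birth + pd.Timedelta(hours=77)
        a = exposure_proportion(birth, birth, mid, frame)
        b = exposure_proportion(birth, mid, end, frame)
        assert a.hours_below + b.hours_below == whole.hours_below
        assert a.total_hours + b.total_hours == whole.total_hours

    def test_monotone_in_et_shift_and_schedule_shift(self):
        rng = np.random.default_rng(11)
        values = rng.normal(12, 6, 150)
        birth = pd.Timestamp("2019-01-01")
        end = birth + pd.Timedelta(hours=150)
        base = exposure_proportion(birth, birth, end, et_frame(values))
        colder = exposure_proportion(birth, birth, end,
                                     et_frame(values - 2.0))
        assert colder.proportion >= base.proportion
        warmer_lct = exposure_proportion(
            birth, birth, end, et_frame(values),
            schedule=AgeLCTSchedule(lct_at_birth=17.0))
        assert warmer_lct.proportion >= base.proportion
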