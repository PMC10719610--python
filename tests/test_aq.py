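"""Concentration computations and daily statistics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from envmeasures import (
    compute_daily_statistics,
    convert_constituents_to_ug,
    daily_max_1h,
    daily_mean_24h,
    max_rolling_8h,
    reconstruct_pm25,
    so2_mass_to_ppb,
    utc_to_local,
)
from envmeasures.aq import SULFATE_TO_AMMONIUM_SULFATE
from envmeasures.grids import GridAlignmentError, UnitError

from conftest import make_field, make_series

SHAPE = (24, 2, 2)


def constituent_fields(du=0.0, ss=0.0, oc=0.0, bc=0.0, so4=0.0):
    return tuple(
        make_field(np.full(SHAPE, v), variable=name, units="ug m^-3")
        for name, v in [("DU", du), ("SS", ss), ("OC", oc), ("BC", bc), ("SO4", so4)]
    )


class TestReconstructPM25:
    def test_all_zero(self):
        pm = reconstruct_pm25(*constituent_fields())
        assert np.all(pm.values == 0.0)

    def test_sulfate_factor_cancels_exactly(self):
        # SO4 = 96.06 with the 132.14/96.06 factor gives exactly 132.14
        pm = reconstruct_pm25(*constituent_fields(so4=96.06))
        np.testing.assert_allclose(pm.values, 132.14, rtol=1e-12)

    def test_worked_example(self):
        pm = reconstruct_pm25(*constituent_fields(du=2.0, ss=1.0, oc=3.0, bc=0.5, so4=4.0))
        expected = 6.5 + 4.0 * (132.14 / 96.06)
        np.testing.assert_allclose(pm.values, expected, rtol=1e-9)

    def test_linear_and_permutation_invariant_in_nonsulfate(self):
        rng = np.random.default_rng(0)
        du, ss, oc, bc = rng.uniform(0, 10, size=4)
        base = reconstruct_pm25(*constituent_fields(du, ss, oc, bc, so4=2.0))
        perm = reconstruct_pm25(*constituent_fields(bc, du, ss, oc, so4=2.0))
        np.testing.assert_allclose(base.values, perm.values, rtol=1e-12)
        doubled = reconstruct_pm25(
            *constituent_fields(2 * du, 2 * ss, 2 * oc, 2 * bc, so4=4.0)
        )
        np.testing.assert_allclose(doubled.values, 2 * base.values, rtol=1e-12)

    def test_result_bounds_each_nonsulfate_constituent(self):
        pm = reconstruct_pm25(*constituent_fields(du=5.0, ss=1.0, oc=0.5, bc=2.0, so4=1.0))
        assert np.all(pm.values >= 5.0)

    def test_missing_propagates(self):
        fields = list(constituent_fields(du=1.0, so4=1.0))
        vals = fields[0].values.copy()
        vals[0, 0, 0] = np.nan
        fields[0] = make_field(vals, variable="DU", units="ug m^-3")
        pm = reconstruct_pm25(*fields)
        assert np.isnan(pm.values[0, 0, 0]) and np.isfinite(pm.values[1, 0, 0])

    def test_unit_and_alignment_errors(self):
        fields = list(constituent_fields(du=1.0))
        bad = make_field(np.full(SHAPE, 1e-9), variable="SS", units="kg m^-3")
        with pytest.raises(UnitError):
            reconstruct_pm25(fields[0], bad, *fields[2:])
        shifted = make_field(np.full(SHAPE, 1.0), variable="SS",
                             units="ug m^-3", origin=(5.0, 5.0))
        with pytest.raises(GridAlignmentError):
            reconstruct_pm25(fields[0], shifted, *fields[2:])


class TestUnitConversions:
    def test_kg_to_ug_definition(self):
        f = make_field(np.full(SHAPE, 1e-9), variable="DU", units="kg m^-3")
        out = convert_constituents_to_ug(f)
        np.testing.assert_allclose(out.values, 1.0)
        assert out.units == "ug m^-3"

    @given(st.floats(min_value=0, max_value=1e-6, allow_nan=False))
    @settings(deadline=None, max_examples=50)
    def test_round_trip_machine_precision(self, value):
        f = make_field(np.full((1, 1, 1), value), variable="X", units="kg m^-3")
        back = convert_constituents_to_ug(f).values * 1e-9
        np.testing.assert_allclose(back, value, rtol=1e-12)

    def test_wrong_units_rejected(self):
        f = make_field(np.full(SHAPE, 1.0), variable="X", units="ug m^-3")
        with pytest.raises(UnitError):
            convert_constituents_to_ug(f)


class TestSo2Conversion:
    def test_zero_is_zero(self):
        so2 = make_field(np.zeros(SHAPE), variable="SO2", units="kg m^-3")
        t = make_field(np.full(SHAPE, 250.0), variable="T", units="K")
        assert np.all(so2_mass_to_ppb(so2, t).values == 0.0)

    def test_worked_value(self):
        # independently evaluated: 300 * 1e-9 * 8.314e7 / (1.013 * 64.066)
        so2 = make_field(np.full(SHAPE, 1.0e-9), variable="SO2", units="kg m^-3")
        t = make_field(np.full(SHAPE, 300.0), variable="T", units="K")
        out = so2_mass_to_ppb(so2, t)
        np.testing.assert_allclose(out.values, 0.38432109236806614, rtol=1e-9)
        assert out.units == "ppb"

    def test_linearity_in_temperature(self):
        so2 = make_field(np.full(SHAPE, 2.0e-9), variable="SO2", units="kg m^-3")
        t1 = make_field(np.full(SHAPE, 280.0), variable="T", units="K")
        t2 = make_field(np.full(SHAPE, 560.0), variable="T", units="K")
        np.testing.assert_allclose(
            so2_mass_to_ppb(so2, t2).values, 2 * so2_mass_to_ppb(so2, t1).values,
            rtol=1e-12,
        )

    def test_matches_scalar_oracle_on_random_fields(self):
        rng = np.random.default_rng(123)
        t_vals = rng.uniform(230, 320, size=1000)
        so2_vals = rng.uniform(0, 5e-8, size=1000)
        so2 = make_field(so2_vals.reshape(1000, 1, 1), variable="SO2", units="kg m^-3")
        t = make_field(t_vals.reshape(1000, 1, 1), variable="T", units="K")
        out = so2_mass_to_ppb(so2, t).values.ravel()
        for i in range(1000):  # independently coded scalar loop
            expected = t_vals[i] * so2_vals[i] * 8.314e7 / (1.013 * 64.066)
            assert abs(out[i] - expected) <= 1e-12 * max(expected, 1e-300)


class TestLocalTime:
    def test_offset_zero_identity(self):
        s = make_series(np.arange(24.0), timezone="UTC")
        out = utc_to_local(s, 0)
        assert out.values.equals(s.values)

    def test_offset_minus_five(self):
        s = make_series([1.0], start="2023-06-01T04:00", timezone="UTC")
        out = utc_to_local(s, -5)
        assert out.values.index[0] == pd.Timestamp("2023-05-31T23:00")
        assert out.values.iloc[0] == 1.0

    def test_non_integer_offset_rejected(self):
        s = make_series(np.arange(24.0), timezone="UTC")
        with pytest.raises(ValueError):
            utc_to_local(s, 2.5)

    def test_48h_series_offset_minus_six_partial_days(self):
        # local dates touched: May 31 (6 valid h), Jun 1 (24), Jun 2 (18)
        s = make_series(np.ones(48), start="2023-06-01T00:00", timezone="UTC")
        local = utc_to_local(s, -6)
        stats = compute_daily_statistics("PM25", local)
        by_date = {st.local_date: st for st in stats}
        assert by_date["2023-05-31"].completeness == pytest.approx(6 / 24)
        assert by_date["2023-05-31"].is_missing
        assert by_date["2023-06-01"].completeness == 1.0
        assert by_date["2023-06-01"].value == 1.0
        assert by_date["2023-06-02"].completeness == pytest.approx(18 / 24)
        assert not by_date["2023-06-02"].is_missing  # exactly at the 18-h floor


class TestDailyStatistics:
    def test_constant_series_all_stats_equal_constant(self):
        s = make_series(np.full(48, 7.5))
        assert daily_mean_24h(s, "2023-06-01").value == 7.5
        assert daily_max_1h(s, "2023-06-01").value == 7.5
        assert max_rolling_8h(s, "2023-06-01").value == 7.5

    def test_ramp_statistics(self):
        s = make_series(np.arange(24.0))
        assert daily_mean_24h(s, "2023-06-01").value == 11.5
        assert daily_max_1h(s, "2023-06-01").value == 23.0

    def test_rolling_ramp_next_day_missing_brute_force(self):
        """0..23 ramp, next day absent: windows starting 17/18 keep >=6 valid
        hours; the oracle (all 24 windows, mean over valid) gives 20.5."""
        vals = np.arange(24.0)
        best = -np.inf
        for start in range(24):  # brute-force oracle over all 24 windows
            window = vals[start:start + 8]  # hours beyond 23 simply absent
            if len(window) >= 6:
                best = max(best, window.mean())
        assert best == 20.5
        s = make_series(vals)
        assert max_rolling_8h(s, "2023-06-01").value == best

    def test_rolling_requires_six_of_eight(self):
        vals = np.full(24, np.nan)
        vals[:5] = 100.0  # every window sees at most 5 valid hours
        s = make_series(vals)
        stat = max_rolling_8h(s, "2023-06-01", min_valid_hours=0)
        assert stat.is_missing

    def test_rolling_spills_into_next_day(self):
        vals = np.zeros(31)
        vals[24:] = 100.0  # 7 next-day hours lift the last windows
        s = make_series(vals)
        stat = max_rolling_8h(s, "2023-06-01")
        assert stat.value == pytest.approx((1 * 0 + 7 * 100) / 8)
        clipped = max_rolling_8h(s, "2023-06-01", clip_at_midnight=True)
        assert clipped.value == 0.0

    def test_ten_missing_hours_suppress_all_stats(self):
        vals = np.arange(24.0)
        vals[:10] = np.nan
        s = make_series(vals)
        for stat in compute_daily_statistics("SO2", s, dates=["2023-06-01"]):
            assert stat.is_missing
            assert stat.completeness == pytest.approx(14 / 24)

    def test_dispatch_per_pollutant(self):
        s = make_series(np.full(24, 5.0), pollutant="SO2", units="ppb")
        stats = compute_daily_statistics("SO2", s, dates=["2023-06-01"])
        assert {(st.statistic, st.value) for st in stats} == {
            ("mean_24h", 5.0), ("max_1h", 5.0)
        }
        s = make_series(np.arange(24.0), pollutant="NO2", units="ppb")
        (stat,) = compute_daily_statistics("NO2", s, dates=["2023-06-01"])
        assert stat.statistic == "max_1h" and stat.value == 23.0
        s = make_series(np.full(24, 1.0), pollutant="PM25", units="ug m^-3")
        assert len(compute_daily_statistics("PM25", s, dates=["2023-06-01"])) == 1

    def test_unknown_pollutant_rejected(self):
        s = make_series(np.ones(24))
        with pytest.raises(ValueError):
            compute_daily_statistics("PB", s)

    def test_stat_ordering_invariants(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            vals = rng.uniform(0, 50, size=48)
            vals[rng.random(48) < 0.15] = np.nan
            s = make_series(vals)
            mean = daily_mean_24h(s, "2023-06-01")
            mx = daily_max_1h(s, "2023-06-01")
            roll = max_rolling_8h(s, "2023-06-01")
            if not mx.is_missing:
                assert mean.value <= mx.value + 1e-12
                if not roll.is_missing:
                    assert roll.value <= mx.value + 1e-12

    def test_invariant_to_explicit_missing_hours(self):
        # a series with hours simply absent equals one with explicit NaNs
        vals = np.arange(24.0)
        sparse = make_series(vals[:20])
        explicit_vals = vals.copy()
        explicit_vals[20:] = np.nan
        explicit = make_series(explicit_vals)
        for fn in (daily_mean_24h, daily_max_1h, max_rolling_8h):
            a, b = fn(sparse, "2023-06-01"), fn(explicit, "2023-06-01")
            assert a.value == b.value or (np.isnan(a.value) and np.isnan(b.value))
            assert a.completeness == b.completeness
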