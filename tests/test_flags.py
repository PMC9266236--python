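"""Flag classification, rest-hour ledgers and reporting arithmetic."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import urbanheat as uh
from urbanheat.flags import (DEFAULT_FLAG_TABLE, FlagBand, FlagTable,
                             JJA_DAYS, WorkingWindow)


class TestClassification:
    @pytest.mark.parametrize("wbgt,expected,minutes", [
        (28.0, "none", 0), (30.0, "yellow", 15), (33.0, "black", 45),
        (31.5, "red", 30),
    ])
    def test_table_examples(self, wbgt, expected, minutes):
        assert uh.classify_flag(wbgt) == expected
        assert DEFAULT_FLAG_TABLE.rest_minutes_for(wbgt) == minutes

    @pytest.mark.parametrize("wbgt,expected", [
        (29.4, "yellow"),   # lower yellow bound inclusive
        (31.1, "red"),      # yellow/red bound owned by red
        (32.2, "red"),      # red/black bound owned by red
        (32.2000001, "black"),
    ])
    def test_boundary_ownership_as_documented(self, wbgt, expected):
        assert uh.classify_flag(wbgt) == expected

    @given(st.floats(20.0, 45.0))
    def test_every_finite_wbgt_maps_to_exactly_one_category(self, w):
        hits = [b.contains(w) for b in DEFAULT_FLAG_TABLE.bands]
        assert sum(bool(h) for h in hits) == 1

    def test_dense_sweep_total_and_exclusive(self):
        sweep = np.linspace(20.0, 45.0, 25001)
        idx = DEFAULT_FLAG_TABLE.classify(sweep)
        assert (idx >= 0).all()
        mins = DEFAULT_FLAG_TABLE.rest_minutes_for(sweep)
        assert set(np.unique(mins)) == {0.0, 15.0, 30.0, 45.0}

    def test_missing_wbgt_gives_missing_category(self):
        assert uh.classify_flag(np.nan) is None
        assert np.isnan(DEFAULT_FLAG_TABLE.rest_minutes_for(np.nan))

    def test_malformed_tables_rejected(self):
        with pytest.raises(ValueError):
            FlagTable((FlagBand("a", -np.inf, 30.0, False, False, 0.0),
                       FlagBand("b", 31.0, np.inf, True, True, 15.0)))  # gap
        with pytest.raises(ValueError):
            FlagTable((FlagBand("a", -np.inf, 30.0, False, True, 30.0),
                       FlagBand("b", 30.0, np.inf, False, True, 15.0)))  # decreasing


def hourly_series(values, start="2013-06-01", lon=0.0):
    idx = pd.date_range(start, periods=len(values), freq="h")
    return pd.Series(np.asarray(values, dtype=float), index=idx)


class TestAccumulation:
    def test_cool_season_accrues_nothing(self):
        s = hourly_series(np.full(92 * 24, 25.0))
        (led,) = uh.accumulate_rest(s, longitude=0.0)
        assert led.total_rest_hours == 0.0
        assert led.exposed_hours == 92 * 10

    def test_all_black_season_closed_form(self):
        """92 JJA days, 10-hour window, every hour black:
        92 x 10 x 45 / 60 = 690 rest hours."""
        s = hourly_series(np.full(92 * 24, 35.0))
        (led,) = uh.accumulate_rest(s, longitude=0.0)
        assert led.total_rest_hours == pytest.approx(690.0)
        assert led.rest_hours["black"] == pytest.approx(690.0)
        assert led.exposed_hours == 920

    def test_hand_built_pattern_matches_enumeration(self):
        """Three synthetic days with a known flag pattern: the ledger
        equals an explicit per-hour enumeration done right here."""
        rng = np.random.default_rng(42)
        values = rng.uniform(26.0, 36.0, 72)
        s = hourly_series(values)
        (led,) = uh.accumulate_rest(s, longitude=0.0)

        # independent enumeration with plain python
        expected = {"none": 0.0, "yellow": 0.0, "red": 0.0, "black": 0.0}
        for ts, w in s.items():
            if 8 <= ts.hour < 18:  # longitude 0: local == UTC
                if w < 29.4:
                    expected["none"] += 0.0
                elif w < 31.1:
                    expected["yellow"] += 15.0
                elif w <= 32.2:
                    expected["red"] += 30.0
                else:
                    expected["black"] += 45.0
        for cat in expected:
            assert led.rest_minutes[cat] == pytest.approx(expected[cat])

    def test_longitude_shifts_the_local_window(self):
        """At 90 E the 08-18 local window is 02:00-12:00 UTC."""
        values = np.full(48, 35.0)
        s = hourly_series(values)
        (led,) = uh.accumulate_rest(s, longitude=90.0)
        assert led.exposed_hours == 20  # 2 days x 10 in-window hours

    def test_missing_hours_counted_not_interpolated(self):
        values = np.full(92 * 24, 35.0)
        values[10 * 24:11 * 24] = np.nan  # one full missing day
        (led,) = uh.accumulate_rest(hourly_series(values), longitude=0.0)
        assert led.missing_hours == 10
        assert led.exposed_hours == 910
        assert led.total_rest_hours == pytest.approx(910 * 45 / 60.0)

    def test_non_hourly_spacing_rejected(self):
        idx = pd.date_range("2013-06-01", periods=30, freq="2h")
        s = pd.Series(30.0, index=idx)
        with pytest.raises(ValueError, match="hourly"):
            uh.accumulate_rest(s, longitude=0.0)

    def test_additive_over_month_partition(self):
        """Accumulating JJA at once equals summing per-month windows."""
        rng = np.random.default_rng(7)
        idx = pd.date_range("2013-06-01", "2013-08-31 23:00", freq="h")
        s = pd.Series(rng.uniform(26.0, 36.0, len(idx)), index=idx)
        (whole,) = uh.accumulate_rest(s, longitude=30.0)
        parts = []
        for m in (6, 7, 8):
            win = WorkingWindow(season_months=(m,))
            parts.extend(uh.accumulate_rest(s, longitude=30.0, window=win))
        for cat in whole.rest_minutes:
            total = sum(p.rest_minutes[cat] for p in parts)
            assert total == pytest.approx(whole.rest_minutes[cat])

    def test_ledger_cap_invariant(self):
        s = hourly_series(np.full(92 * 24, 40.0))
        (led,) = uh.accumulate_rest(s, longitude=0.0)
        assert led.total_rest_hours <= led.exposed_hours * 0.75 + 1e-9


class TestPeriodDifference:
    def _ledgers(self, years, wbgt_value):
        out = []
        for y in years:
            s = hourly_series(np.full(92 * 24, wbgt_value), start=f"{y}-06-01")
            out.extend(uh.accumulate_rest(s, longitude=0.0, domain="X"))
        return out

    def test_identical_periods_give_zero(self):
        a = self._ledgers([2015, 2016], 30.0)
        b = self._ledgers([2010, 2011], 30.0)
        diff = uh.period_difference(a, b)
        assert all(v == pytest.approx(0.0) for v in diff.values())

    def test_warmer_later_period_positive_difference(self):
        a = self._ledgers([2015, 2016], 30.5)   # yellow everywhere
        b = self._ledgers([2010, 2011], 28.0)   # no flag
        diff = uh.period_difference(a, b)
        assert diff["total"] > 0
        assert diff["yellow"] > 0

    def test_single_category_additivity(self):
        """Only black hours differ: black diff = k, others 0."""
        a = self._ledgers([2015], 35.0)
        b = self._ledgers([2010], 35.0)
        # remove k = 4 black hours (i.e. 4 x 45 min) from the earlier period
        b[0].rest_minutes["black"] -= 4 * 45.0
        diff = uh.period_difference(a, b)
        assert diff["black"] == pytest.approx(3.0)  # 4 x 45 min = 3 h
        assert diff["yellow"] == pytest.approx(0.0)
        assert diff["total"] == pytest.approx(3.0)

    def test_overlapping_seasons_rejected(self):
        a = self._ledgers([2014, 2015], 30.0)
        b = self._ledgers([2014], 30.0)
        with pytest.raises(ValueError, match="overlap"):
            uh.period_difference(a, b)

    def test_empty_period_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            uh.period_difference([], self._ledgers([2010], 30.0))


class TestConversions:
    def test_per_day_minutes_printed_examples(self):
        """100 h over five 92-day seasons ~ 13 min/day; 1300 h ~ 170."""
        assert uh.per_day_minutes(100.0, 5) == pytest.approx(13.04, abs=0.01)
        assert uh.per_day_minutes(1300.0, 5) == pytest.approx(169.6, abs=0.1)
        assert uh.per_day_minutes(0.0, 3) == 0.0

    def test_hours_per_year(self):
        assert 100.0 / 5 == pytest.approx(20.0)  # definitionally 20 h/season
        assert uh.per_day_minutes(100.0, 5) * JJA_DAYS / 60.0 == pytest.approx(20.0)

    def test_workweek_equivalent(self):
        assert uh.workweek_equivalent(150.0) == pytest.approx(3.75)
        assert uh.workweek_equivalent(40.0) == pytest.approx(1.0)
        assert uh.workweek_equivalent(0.0) == 0.0

    def test_invalid_divisors_rejected(self):
        with pytest.raises(ValueError):
            uh.per_day_minutes(10.0, 0)
        with pytest.raises(ValueError):
            uh.workweek_equivalent(10.0, hours_per_day=0.0)


class TestPercentileAggregate:
    def test_constant_series(self):
        p50, p98 = uh.percentile_aggregate(np.full(100, 31.3))
        assert p50 == p98 == pytest.approx(31.3)

    def test_linear_interpolation_rule(self):
        """0..99 evenly spaced: linear interpolation between order
        statistics gives (49.5, 97.02)."""
        p50, p98 = uh.percentile_aggregate(np.arange(100.0))
        assert p50 == pytest.approx(49.5)
        assert p98 == pytest.approx(97.02)

    def test_outlier_moves_tail_not_median(self, rng):
        base = rng.normal(30.0, 1.0, 1000)
        p50a, p98a = uh.percentile_aggregate(base)
        spiked = np.append(base, 60.0)
        p50b, p98b = uh.percentile_aggregate(spiked)
        assert abs(p50b - p50a) < 0.01
        assert p98b >= p98a

    def test_small_or_empty_series_rejected(self):
        with pytest.raises(ValueError):
            uh.percentile_aggregate([])
        with pytest.raises(ValueError):
            uh.percentile_aggregate(np.arange(10.0))
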