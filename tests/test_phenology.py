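"""Winter/spring delimitation rules, arrival detection, migration metrics."""

import datetime as dt
import math

import numpy as np
import pandas as pd
import pytest

from flytrack.geo import GeoPoint, great_circle_km
from flytrack.phenology import (PhenologyRecord, WinterDelimitation,
                                delimit_winter, detect_arrival,
                                qc_rate_outlier, records_to_frame,
                                spring_metrics)
from flytrack.schedule import Schedule, StationaryPeriod
from flytrack.sites import SITES
from flytrack.track import LocationPosterior

W = GeoPoint(2.5, -65.0)


def make_schedule(durations, start=dt.date(2014, 3, 1), gap=3, point=W):
    """A schedule of stationary periods with given durations (days),
    separated by ``gap`` movement days."""
    periods = []
    day = start
    for dur in durations:
        end = day + dt.timedelta(days=dur - 1)
        periods.append(StationaryPeriod(day, end, point,
                                        (point.lat - 1, point.lat + 1),
                                        (point.lon - 1, point.lon + 1)))
        day = end + dt.timedelta(days=gap + 1)
    return Schedule(periods)


class TestDelimitWinter:
    def test_rule_forced_sequence(self):
        """Periods of 40/35/10/5 days: initiation is the end of the 35-day
        period (the last >=30-day one)."""
        sched = make_schedule([40, 35, 10, 5])
        win = delimit_winter(sched, search_from=dt.date(2014, 1, 1))
        assert win is not None
        assert win.spring_initiation == sched.periods[1].end
        assert win.winter_start == sched.periods[0].start
        assert win.n_winter_sites == 2

    def test_single_long_period(self):
        """One 133-day period then short stopovers: one winter site whose
        end is the initiation, winter duration 133 days."""
        sched = make_schedule([133, 8, 5])
        win = delimit_winter(sched, search_from=dt.date(2014, 1, 1))
        assert win.n_winter_sites == 1
        assert win.spring_initiation == sched.periods[0].end
        assert win.winter_duration_days == 133

    def test_no_long_period_is_undefined(self):
        sched = make_schedule([20, 25, 10])
        assert delimit_winter(sched, search_from=dt.date(2014, 1, 1)) is None

    def test_deployment_season_skipped_by_default(self):
        """A leading 60-day breeding period must not masquerade as winter."""
        sched = make_schedule([60, 90, 8])
        win = delimit_winter(sched)
        assert win.winter_start == sched.periods[1].start
        assert win.n_winter_sites == 1

    def test_search_until_excludes_tail(self):
        sched = make_schedule([40, 35, 45])
        win = delimit_winter(sched, search_from=dt.date(2014, 1, 1),
                             search_until=sched.periods[1].end)
        assert win.spring_initiation == sched.periods[1].end


def posterior_with_lon_window(dates, lon_lo, lon_hi):
    df = pd.DataFrame(
        dict(date=list(dates), lat_med=0.0, lat_lo=-1.0, lat_hi=1.0,
             lon_med=(np.asarray(lon_lo) + np.asarray(lon_hi)) / 2,
             lon_lo=lon_lo, lon_hi=lon_hi)
    )
    return LocationPosterior.from_summary(df)


class TestDetectArrival:
    def test_census_floor_applied_at_austral_site(self):
        """The longitude criterion fires early at RED; the census date
        floors the arrival."""
        site = SITES["RED"]  # lon -57.4; census 2014-10-05
        init = dt.date(2014, 9, 10)
        dates = [init + dt.timedelta(days=i) for i in range(40)]
        post = posterior_with_lon_window(dates, [-60.0] * 40, [-55.0] * 40)
        assert detect_arrival(post, site, init) == dt.date(2014, 10, 5)

    def test_intratropical_site_uses_first_qualifying_date(self):
        site = SITES["EEI"]  # lon -47.9, no census constraint
        init = dt.date(2014, 8, 10)
        dates = [init + dt.timedelta(days=i) for i in range(20)]
        lo = [-65.0] * 8 + [-50.0] * 12
        hi = [-60.0] * 8 + [-45.0] * 12
        post = posterior_with_lon_window(dates, lo, hi)
        assert detect_arrival(post, site, init) == dates[8]

    def test_never_qualifying_is_missing(self):
        site = SITES["EEI"]
        init = dt.date(2014, 8, 10)
        dates = [init + dt.timedelta(days=i) for i in range(20)]
        post = posterior_with_lon_window(dates, [-70.0] * 20, [-60.0] * 20)
        assert detect_arrival(post, site, init) is None


class TestGreatCircle:
    def test_zero_iff_same_point(self):
        assert great_circle_km(W, W) == 0.0

    def test_quarter_circumference(self):
        assert great_circle_km((0.0, 0.0), (0.0, 90.0)) == pytest.approx(10007.5, abs=0.1)

    def test_symmetry(self):
        a, b = SITES["DF"].point, SITES["RED"].point
        assert great_circle_km(a, b) == great_circle_km(b, a)

    def test_against_independent_spherical_oracle(self):
        """Spherical law of cosines, written independently here."""
        a, b = SITES["DF"].point, SITES["RED"].point
        p1, l1 = math.radians(a.lat), math.radians(a.lon)
        p2, l2 = math.radians(b.lat), math.radians(b.lon)
        oracle = 6371.0 * math.acos(
            math.sin(p1) * math.sin(p2) + math.cos(p1) * math.cos(p2) * math.cos(l2 - l1)
        )
        assert great_circle_km(a, b) == pytest.approx(oracle, abs=0.1)


def winter_ending(site_code, initiation, distance_km, n_sites=1):
    """A winter delimitation whose last period sits exactly
    ``distance_km`` due south of the breeding site (meridian arc)."""
    site = SITES[site_code]
    dlat = math.degrees(distance_km / 6371.0)
    pt = GeoPoint(site.point.lat + dlat, site.point.lon)
    start = initiation - dt.timedelta(days=99)
    last = StationaryPeriod(initiation - dt.timedelta(days=40), initiation, pt,
                            (pt.lat - 1, pt.lat + 1), (pt.lon - 1, pt.lon + 1))
    return WinterDelimitation(start, initiation, n_sites, 100, last)


class TestSpringMetrics:
    def test_inclusive_day_arithmetic_and_rate(self):
        """Initiation 23 Sep, arrival 10 Oct, 2,922 km: 18 days inclusive
        at 162.3 km/day (the printed-precision convention)."""
        win = winter_ending("RED", dt.date(2010, 9, 23), 2922.0)
        rec = spring_metrics(Schedule([win.last_winter_period]), win,
                             dt.date(2010, 10, 10), SITES["RED"])
        assert rec.spring_duration_days == 18
        assert rec.spring_distance_km == pytest.approx(2922.0, abs=0.5)
        assert round(rec.spring_rate_km_per_day, 1) == 162.3

    def test_second_printed_row(self):
        """Initiation 4 Aug, arrival 19 Aug, 2,604 km: 16 days, 162.8 km/day."""
        win = winter_ending("DF", dt.date(2014, 8, 4), 2604.0)
        rec = spring_metrics(Schedule([win.last_winter_period]), win,
                             dt.date(2014, 8, 19), SITES["DF"])
        assert rec.spring_duration_days == 16
        assert round(rec.spring_rate_km_per_day, 1) == 162.8

    def test_missing_arrival_propagates(self):
        win = winter_ending("RED", dt.date(2014, 9, 27), 4816.0)
        rec = spring_metrics(Schedule([win.last_winter_period]), win, None, SITES["RED"])
        assert rec.spring_duration_days is None
        assert rec.spring_rate_km_per_day is None
        assert rec.spring_distance_km == pytest.approx(4816.0, abs=0.5)

    def test_stopovers_strictly_between(self):
        init = dt.date(2014, 8, 10)
        arrival = dt.date(2014, 9, 5)
        win = winter_ending("EEI", init, 3100.0)
        stop = StationaryPeriod(init + dt.timedelta(days=5), init + dt.timedelta(days=10),
                                W, (0, 1), (0, 1))
        tail = StationaryPeriod(arrival, arrival + dt.timedelta(days=20),
                                SITES["EEI"].point, (0, 1), (0, 1))
        rec = spring_metrics(Schedule([win.last_winter_period, stop, tail]), win,
                             arrival, SITES["EEI"])
        assert rec.n_spring_stopovers == 1
        assert rec.spring_stopover_days == 6

    def test_arrival_before_initiation_rejected(self):
        win = winter_ending("RED", dt.date(2014, 9, 27), 4000.0)
        with pytest.raises(ValueError):
            spring_metrics(Schedule([win.last_winter_period]), win,
                           dt.date(2014, 9, 1), SITES["RED"])


class TestRateOutlierQC:
    @staticmethod
    def records(site, rates):
        return [
            PhenologyRecord(individual_id=str(i), site=site,
                            spring_rate_km_per_day=r, spring_distance_km=1.0,
                            spring_duration_days=1)
            for i, r in enumerate(rates)
        ]

    def test_extreme_rate_flagged(self):
        out = qc_rate_outlier(self.records("RED", [535.0, 223.0, 168.0]))
        assert [r.excluded for r in out] == [True, False, False]
        assert "535" in out[0].exclusion_reason

    def test_close_rates_unflagged(self):
        out = qc_rate_outlier(self.records("RED", [170.0, 168.0]))
        assert not any(r.excluded for r in out)

    def test_single_record_never_flagged(self):
        out = qc_rate_outlier(self.records("RED", [535.0]))
        assert not out[0].excluded

    def test_sites_judged_separately(self):
        recs = self.records("RED", [535.0, 223.0]) + self.records("DF", [100.0])
        out = qc_rate_outlier(recs)
        assert [r.excluded for r in out] == [True, False, False]


class TestFixtureConsistency:
    def test_rate_equals_distance_over_duration(self, table1):
        """Printed rates agree with printed distance/duration within the
        rounding of the distances (0.5 km/day), on every rated row."""
        rated = table1.dropna(subset=["spring_rate_km_per_day"])
        assert len(rated) == 27
        recomputed = rated["spring_distance_km"] / rated["spring_duration_days"]
        assert (recomputed - rated["spring_rate_km_per_day"]).abs().max() <= 0.5

    def test_duration_is_inclusive_date_difference(self, table1):
        """duration = (arrival - initiation) + 1 on every dated row."""
        dated = table1.dropna(subset=["spring_initiation", "spring_arrival"])
        assert len(dated) == 27
        for row in dated.itertuples():
            implied = (row.spring_arrival - row.spring_initiation).days + 1
            assert implied == row.spring_duration_days

    def test_record_table_rendering(self):
        win = winter_ending("DF", dt.date(2014, 8, 4), 2604.3)
        rec = spring_metrics(Schedule([win.last_winter_period]), win,
                             dt.date(2014, 8, 19), SITES["DF"], individual_id="x")
        df = records_to_frame([rec])
        assert df["spring_distance_km"].iloc[0] == 2604  # whole km
        assert df["spring_rate_km_per_day"].iloc[0] == round(2604.3 / 16, 1)
        assert df["group"].iloc[0] == "intratropical"
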