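"""Segmentation of daily location posteriors into stationary periods.

A stationary period is a run of days whose location posteriors are
statistically indistinguishable.  The segmentation is a greedy forward
pass over the daily posterior summaries: a segment keeps a running mean
of its daily medians and a pooled daily credible-interval half-width;
an incoming day opens a break when its median departs from the running
mean by more than ``z_break`` pooled half-widths on either axis.  Near
an equinox the latitude is unidentifiable, so an option restricts the
break test to longitude within a window of the equinoxes.  Segments
shorter than ``min_days`` are classed as movement days.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .geo import GeoPoint
from .track import LocationPosterior

#: equinox anniversaries used for the longitude-only window
EQUINOXES = ((3, 20), (9, 22))


def _near_equinox(day: dt.date, window_days: int) -> bool:
    for month, dom in EQUINOXES:
        for year in (day.year - 1, day.year, day.year + 1):
            if abs((day - dt.date(year, month, dom)).days) <= window_days:
                return True
    return False


@dataclass(frozen=True)
class StationaryPeriod:
    """One stationary period with pooled location and credible interval."""

    start: dt.date
    end: dt.date
    point: GeoPoint
    lat_ci: Tuple[float, float]
    lon_ci: Tuple[float, float]

    def __post_init__(self):
        if self.end < self.start:
            raise ValueError("period end precedes start")

    @property
    def duration_days(self) -> int:
        return (self.end - self.start).days + 1

    @property
    def midpoint(self) -> dt.date:
        return self.start + dt.timedelta(days=(self.end - self.start).days // 2)


@dataclass
class Schedule:
    """Ordered stationary periods and the movement days between them."""

    periods: List[StationaryPeriod]
    movement_days: List[dt.date] = field(default_factory=list)
    equinox_lon_only: bool = False

    def __post_init__(self):
        for a, b in zip(self.periods, self.periods[1:]):
            if b.start <= a.end:
                raise ValueError("stationary periods overlap or are unordered")

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, p in enumerate(self.periods):
            rows.append(
                dict(
                    period_id=i, start=p.start, end=p.end, kind="stationary",
                    lat_med=p.point.lat, lon_med=p.point.lon,
                    lat_lo=p.lat_ci[0], lat_hi=p.lat_ci[1],
                    lon_lo=p.lon_ci[0], lon_hi=p.lon_ci[1],
                )
            )
        for d in self.movement_days:
            rows.append(
                dict(period_id=-1, start=d, end=d, kind="movement",
                     lat_med=np.nan, lon_med=np.nan, lat_lo=np.nan,
                     lat_hi=np.nan, lon_lo=np.nan, lon_hi=np.nan)
            )
        df = pd.DataFrame(rows).sort_values("start").reset_index(drop=True)
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "Schedule":
        df = pd.read_csv(path)
        periods = []
        movement = []
        for row in df.itertuples():
            start = pd.Timestamp(row.start).date()
            end = pd.Timestamp(row.end).date()
            if row.kind == "stationary":
                periods.append(
                    StationaryPeriod(
                        start, end, GeoPoint(row.lat_med, row.lon_med),
                        (row.lat_lo, row.lat_hi), (row.lon_lo, row.lon_hi),
                    )
                )
            else:
                movement.append(start)
        periods.sort(key=lambda p: p.start)
        return cls(periods, sorted(movement))


def segment_stationary(
    post: LocationPosterior,
    min_days: int = 2,
    z_break: float = 2.0,
    equinox_lon_only: bool = False,
    equinox_window_days: int = 15,
) -> Schedule:
    """Delimit a daily posterior into stationary periods and movement days.

    Parameters
    ----------
    post
        Daily location posterior (summaries suffice; samples, when
        present, refine the pooled period intervals).
    min_days
        Minimum days for a segment to count as stationary.
    z_break
        Break threshold in pooled CrI half-widths: the central free
        parameter of the segmentation.
    equinox_lon_only, equinox_window_days
        When set, only longitude is tested within the window around the
        equinoxes (latitude is unidentifiable there).
    """
    s = post.summary
    if len(s) < min_days:
        raise ValueError("posterior shorter than min_days")
    dates: List[dt.date] = list(s["date"])
    med = s[["lat_med", "lon_med"]].to_numpy()
    hw = np.column_stack(
        [
            (s["lat_hi"] - s["lat_lo"]).to_numpy() / 2.0,
            (s["lon_hi"] - s["lon_lo"]).to_numpy() / 2.0,
        ]
    )
    hw = np.maximum(hw, 1e-6)

    def breaches(i: int, seg: List[int]) -> bool:
        run_mean = med[seg].mean(axis=0)
        pooled = hw[seg].mean(axis=0)
        dev = np.abs(med[i] - run_mean) / (z_break * pooled)
        if equinox_lon_only and _near_equinox(dates[i], equinox_window_days):
            return bool(dev[1] > 1.0)
        return bool((dev > 1.0).any())

    # a break must be confirmed by the following day: a single-day
    # excursion (shading artefact, equinox wobble) is absorbed rather
    # than allowed to split a long stationary period
    segments: List[List[int]] = [[0]]
    for i in range(1, len(dates)):
        seg = segments[-1]
        if breaches(i, seg):
            if i + 1 < len(dates) and not breaches(i + 1, seg):
                seg.append(i)  # isolated outlier day
            else:
                segments.append([i])
        else:
            seg.append(i)

    periods: List[StationaryPeriod] = []
    movement: List[dt.date] = []
    for seg in segments:
        span_days = (dates[seg[-1]] - dates[seg[0]]).days + 1
        if span_days >= min_days and len(seg) >= min_days:
            if post.samples is not None:
                pool = post.samples[seg].reshape(-1, 2)
                lat_q = np.quantile(pool[:, 0], [0.5, 0.025, 0.975])
                lon_q = np.quantile(pool[:, 1], [0.5, 0.025, 0.975])
            else:
                lat_q = (np.median(med[seg, 0]), hw_lo(s, seg, "lat"), hw_hi(s, seg, "lat"))
                lon_q = (np.median(med[seg, 1]), hw_lo(s, seg, "lon"), hw_hi(s, seg, "lon"))
            periods.append(
                StationaryPeriod(
                    dates[seg[0]], dates[seg[-1]],
                    GeoPoint(float(lat_q[0]), float(lon_q[0])),
                    (float(lat_q[1]), float(lat_q[2])),
                    (float(lon_q[1]), float(lon_q[2])),
                )
            )
        else:
            movement.extend(dates[j] for j in seg)
    return Schedule(periods, movement, equinox_lon_only)


def hw_lo(s: pd.DataFrame, seg: Sequence[int], axis: str) -> float:
    return float(s[f"{axis}_lo"].to_numpy()[list(seg)].mean())


def hw_hi(s: pd.DataFrame, seg: Sequence[int], axis: str) -> float:
    return float(s[f"{axis}_hi"].to_numpy()[list(seg)].mean())


def period_counts(schedule: Schedule, window: Tuple[dt.date, dt.date]) -> int:
    """Number of stationary periods whose midpoint lies in ``window``."""
    lo, hi = window
    if hi < lo:
        return 0
    return sum(1 for p in schedule.periods if lo <= p.midpoint <= hi)


def schedule_to_geojson(schedule: Schedule, path) -> None:
    """Write the schedule as GeoJSON: one Point feature per stationary
    period (with dates and kind) and a LineString route through the
    period medians, for mapping."""
    import json

    features = []
    for i, p in enumerate(schedule.periods):
        features.append(
            {
                "type": "Feature",
                "geometry": {"type": "Point", "coordinates": [p.point.lon, p.point.lat]},
                "properties": {
                    "period_id": i,
                    "start": p.start.isoformat(),
                    "end": p.end.isoformat(),
                    "duration_days": p.duration_days,
                },
            }
        )
    if len(schedule.periods) > 1:
        features.append(
            {
                "type": "Feature",
                "geometry": {
                    "type": "LineString",
                    "coordinates": [[p.point.lon, p.point.lat] for p in schedule.periods],
                },
                "properties": {"kind": "route"},
            }
        )
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)


def schedule_to_daily_medians(schedule: Schedule) -> pd.DataFrame:
    """Reconstruct a per-day summary from a schedule (period values
    repeated across their days), usable to re-segment."""
    rows = []
    for p in schedule.periods:
        day = p.start
        while day <= p.end:
            rows.append(
                dict(date=day, lat_med=p.point.lat, lon_med=p.point.lon,
                     lat_lo=p.lat_ci[0], lat_hi=p.lat_ci[1],
                     lon_lo=p.lon_ci[0], lon_hi=p.lon_ci[1])
            )
            day += dt.timedelta(days=1)
    return pd.DataFrame(rows).sort_values("date").reset_index(drop=True)
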