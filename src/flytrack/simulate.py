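"""Ground-truthed track and light-series simulation.

The generator emulates the annual movements behind the study system:
a breeding season at one of the four sites, fall migration to a winter
range near 2-3 degrees N in northern South America, one to a few winter
stationary sites, and a spring migration of roughly 2,600-5,100 km back
to the breeding site over 16-57 days with 0-5 stopovers.  Every
stationary period and phenology date is retained as ground truth so the
whole estimation chain can be scored against it.

Light is generated as a logistic function of solar zenith relative to a
truth zenith angle, with per-twilight log-normal delays (sunrise late,
sunset early - the shading direction) and optional discrete shading
events, then clipped to the sensor range.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .geo import GeoPoint, great_circle_km, intermediate_point
from .light import LightSeries
from .sites import SITES, SiteConfig
from .solar import predict_twilights, solar_position, solar_zenith

#: steepness of the logistic light response (degrees of solar zenith)
LIGHT_STEEPNESS_DEG = 0.5


@dataclass(frozen=True)
class Leg:
    """A stationary leg of the itinerary."""

    point: GeoPoint
    start: dt.date
    end: dt.date  # inclusive
    kind: str  # breeding | winter | stopover | arrival

    @property
    def duration_days(self) -> int:
        return (self.end - self.start).days + 1


@dataclass(frozen=True)
class NoiseConfig:
    """Observation-noise model for the simulated light sensor.

    Twilight delays (minutes) are log-normal; shading events zero (or
    attenuate) the light for 10-60 minutes at ``shading_rate`` events
    per day.  ``interval_minutes`` is the logger sampling interval.
    """

    twilight_meanlog: float = float(np.log(3.0))
    twilight_sdlog: float = 0.5
    shading_rate: float = 0.2
    shading_depth: float = 0.0  # multiplier applied during an event
    sensor_max: float = 1.0
    interval_minutes: int = 5

    def __post_init__(self):
        if self.shading_rate < 0 or not 0 <= self.shading_depth <= 1:
            raise ValueError("invalid shading parameters")
        if self.interval_minutes not in (1, 2, 5, 10):
            raise ValueError("interval must be one of 1, 2, 5, 10 minutes")


NOISE_FREE = NoiseConfig(twilight_meanlog=-np.inf, twilight_sdlog=0.0, shading_rate=0.0)


@dataclass(frozen=True)
class ScenarioConfig:
    """Itinerary blueprint for one simulated deployment."""

    site: str
    deploy: dt.date
    fall_depart: dt.date
    winter_arrive: dt.date
    spring_initiation: dt.date
    spring_arrival: dt.date
    track_end: dt.date
    n_winter_sites: int = 2
    stopover_days: Tuple[int, ...] = (6, 5, 6)
    winter_center: GeoPoint = GeoPoint(2.5, -65.0)
    winter_spread_deg: float = 2.5
    stopover_jitter_deg: float = 0.7
    max_transit_kmday: float = 800.0

    def __post_init__(self):
        order = (self.deploy, self.fall_depart, self.winter_arrive,
                 self.spring_initiation, self.spring_arrival, self.track_end)
        if any(a >= b for a, b in zip(order, order[1:])):
            raise ValueError("scenario dates must be strictly increasing")
        if self.n_winter_sites < 1:
            raise ValueError("need at least one winter site")


#: per-site presets; dates follow each site's deployment seasons
SCENARIOS: Dict[str, ScenarioConfig] = {
    "DF": ScenarioConfig(
        site="DF", deploy=dt.date(2013, 10, 15), fall_depart=dt.date(2014, 2, 20),
        winter_arrive=dt.date(2014, 3, 12), spring_initiation=dt.date(2014, 7, 28),
        spring_arrival=dt.date(2014, 8, 18), track_end=dt.date(2014, 9, 8),
        n_winter_sites=1, stopover_days=(5, 5),
    ),
    "EEI": ScenarioConfig(
        site="EEI", deploy=dt.date(2013, 11, 1), fall_depart=dt.date(2014, 2, 20),
        winter_arrive=dt.date(2014, 3, 15), spring_initiation=dt.date(2014, 8, 10),
        spring_arrival=dt.date(2014, 9, 5), track_end=dt.date(2014, 9, 26),
        n_winter_sites=2, stopover_days=(6, 5, 6),
    ),
    "RED": ScenarioConfig(
        site="RED", deploy=dt.date(2010, 11, 15), fall_depart=dt.date(2011, 2, 15),
        winter_arrive=dt.date(2011, 3, 20), spring_initiation=dt.date(2011, 9, 10),
        spring_arrival=dt.date(2011, 10, 12), track_end=dt.date(2011, 11, 2),
        n_winter_sites=2, stopover_days=(7, 5, 8),
    ),
    "RPL": ScenarioConfig(
        site="RPL", deploy=dt.date(2014, 11, 10), fall_depart=dt.date(2015, 2, 15),
        winter_arrive=dt.date(2015, 3, 22), spring_initiation=dt.date(2015, 9, 8),
        spring_arrival=dt.date(2015, 10, 14), track_end=dt.date(2015, 11, 4),
        n_winter_sites=3, stopover_days=(8, 7, 9),
    ),
}


def scenario(site_code: str, **overrides) -> ScenarioConfig:
    """The preset scenario for ``site_code``, with field overrides."""
    return replace(SCENARIOS[site_code], **overrides)


@dataclass
class SimTrack:
    """A simulated deployment: itinerary, daily positions and truth table."""

    legs: List[Leg]
    positions: pd.DataFrame  # date, lat, lon
    truth: Dict
    seed: int

    def position_on(self, date: dt.date) -> GeoPoint:
        row = self.positions.loc[self.positions["date"] == date]
        if row.empty:
            raise KeyError(f"{date} outside track span")
        return GeoPoint(float(row["lat"].iloc[0]), float(row["lon"].iloc[0]))


def _daterange(a: dt.date, b: dt.date) -> List[dt.date]:
    """Dates from a to b inclusive."""
    return [a + dt.timedelta(days=i) for i in range((b - a).days + 1)]


def _split_span(start: dt.date, end: dt.date, n: int, gap_days: int = 2):
    """Split [start, end] into n legs separated by ``gap_days`` transits."""
    total = (end - start).days + 1
    usable = total - gap_days * (n - 1)
    base, extra = divmod(usable, n)
    spans = []
    cur = start
    for i in range(n):
        d = base + (1 if i < extra else 0)
        spans.append((cur, cur + dt.timedelta(days=d - 1)))
        cur = cur + dt.timedelta(days=d + gap_days)
    return spans


def simulate_annual_track(cfg: ScenarioConfig, seed: int = 0) -> SimTrack:
    """Build a ground-truthed annual itinerary from a scenario.

    Deterministic given ``seed``: winter-site and stopover coordinates
    are jittered reproducibly; all dates come from the scenario.
    """
    rng = np.random.default_rng(seed)
    site = SITES[cfg.site]
    legs: List[Leg] = [Leg(site.point, cfg.deploy, cfg.fall_depart, "breeding")]

    # winter sites, jittered around the winter range centre
    spans = _split_span(cfg.winter_arrive, cfg.spring_initiation, cfg.n_winter_sites)
    winter_pts = []
    for (s, e) in spans:
        p = GeoPoint(
            float(np.clip(cfg.winter_center.lat + rng.uniform(-1.5, 1.5), -10, 10)),
            cfg.winter_center.lon + rng.uniform(-cfg.winter_spread_deg, cfg.winter_spread_deg),
        )
        winter_pts.append(p)
        legs.append(Leg(p, s, e, "winter"))

    last_winter = winter_pts[-1]
    distance_km = great_circle_km(last_winter, site.point)

    # spring: split the strictly-between days into stopovers + transit
    n_between = (cfg.spring_arrival - cfg.spring_initiation).days - 1
    stop_days = list(cfg.stopover_days)
    n_stops = len(stop_days)
    transit_days = n_between - sum(stop_days)
    if transit_days < n_stops + 1:
        raise ValueError("spring window too short for the requested stopovers")
    seg_base, seg_extra = divmod(transit_days, n_stops + 1)
    seg_transits = [seg_base + (1 if i < seg_extra else 0) for i in range(n_stops + 1)]

    stop_legs: List[Leg] = []
    cur = cfg.spring_initiation
    done_transit = 0
    for i, sd in enumerate(stop_days):
        cur = cur + dt.timedelta(days=seg_transits[i])
        done_transit += seg_transits[i]
        # stopovers sit at the fraction of *transit* time already flown,
        # so every flight day covers a comparable distance
        frac = done_transit / max(1, transit_days)
        p = intermediate_point(last_winter, site.point, min(0.95, max(0.05, frac)))
        p = GeoPoint(
            float(np.clip(p.lat + rng.uniform(-cfg.stopover_jitter_deg, cfg.stopover_jitter_deg), -89, 89)),
            p.lon + rng.uniform(-cfg.stopover_jitter_deg, cfg.stopover_jitter_deg),
        )
        start = cur + dt.timedelta(days=1)
        end = start + dt.timedelta(days=sd - 1)
        stop_legs.append(Leg(p, start, end, "stopover"))
        cur = end
    legs.extend(stop_legs)
    legs.append(Leg(site.point, cfg.spring_arrival, cfg.track_end, "arrival"))

    # daily positions: stationary on legs, great-circle interpolation between
    dates = _daterange(cfg.deploy, cfg.track_end)
    lats = np.empty(len(dates))
    lons = np.empty(len(dates))
    legs_sorted = sorted(legs, key=lambda l: l.start)
    for i, day in enumerate(dates):
        placed = False
        for j, leg in enumerate(legs_sorted):
            if leg.start <= day <= leg.end:
                lats[i], lons[i] = leg.point.lat, leg.point.lon
                placed = True
                break
            if day < leg.start:
                prev = legs_sorted[j - 1]
                gap = (leg.start - prev.end).days
                frac = (day - prev.end).days / gap
                p = intermediate_point(prev.point, leg.point, frac)
                lats[i], lons[i] = p.lat, p.lon
                placed = True
                break
        if not placed:
            lats[i], lons[i] = legs_sorted[-1].point.lat, legs_sorted[-1].point.lon

    positions = pd.DataFrame({"date": dates, "lat": lats, "lon": lons})
    step_km = np.array([
        great_circle_km((lats[i], lons[i]), (lats[i + 1], lons[i + 1]))
        for i in range(len(dates) - 1)
    ])
    if step_km.size and step_km.max() > cfg.max_transit_kmday:
        raise ValueError(
            f"transit speed {step_km.max():.0f} km/day exceeds limit "
            f"{cfg.max_transit_kmday}"
        )

    truth = {
        "site": cfg.site,
        "winter_start": cfg.winter_arrive,
        "spring_initiation": cfg.spring_initiation,
        "spring_arrival": cfg.spring_arrival,
        "n_winter_sites": cfg.n_winter_sites,
        "n_spring_stopovers": len(stop_legs),
        "spring_stopovers": [(l.start, l.end) for l in stop_legs],
        "spring_stopover_days": sum(l.duration_days for l in stop_legs),
        "last_winter_site": last_winter,
        "spring_distance_km": distance_km,
        "spring_duration_days": (cfg.spring_arrival - cfg.spring_initiation).days + 1,
    }
    truth["spring_rate_km_per_day"] = distance_km / truth["spring_duration_days"]
    return SimTrack(legs_sorted, positions, truth, seed)


def simulate_light(
    track: SimTrack,
    zenith_deg: float = 96.0,
    noise: NoiseConfig = NoiseConfig(),
    seed: int = 0,
    logger_id: str = "sim",
) -> LightSeries:
    """Render a light series for a track under a truth zenith and noise model.

    Per day, light is a logistic function of the solar zenith at the
    day's position; the time axis is warped so the sunrise crossing is
    delayed and the sunset crossing advanced by that day's log-normal
    draws.  Shading events multiply the light by ``shading_depth``.
    Deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed)
    dates = list(track.positions["date"])
    lats = track.positions["lat"].to_numpy()
    lons = track.positions["lon"].to_numpy()
    step = noise.interval_minutes
    n_per_day = (24 * 60) // step

    all_times: List[np.ndarray] = []
    all_light: List[np.ndarray] = []
    for day, lat, lon in zip(dates, lats, lons):
        day0 = np.datetime64(day.isoformat(), "s")
        minutes = np.arange(n_per_day) * float(step)
        times = day0 + (minutes * 60).astype("timedelta64[s]")

        if np.isfinite(noise.twilight_meanlog):
            d_sr = float(rng.lognormal(noise.twilight_meanlog, noise.twilight_sdlog))
            d_ss = float(rng.lognormal(noise.twilight_meanlog, noise.twilight_sdlog))
        else:
            d_sr = d_ss = 0.0

        _, eot = solar_position(day0 + np.timedelta64(12 * 3600, "s"))
        noon_min = 720.0 - 4.0 * lon - eot
        morning = minutes < (noon_min % 1440.0)
        warped = np.where(morning, minutes - d_sr, minutes + d_ss)
        tw = day0 + np.round(warped * 60).astype("timedelta64[s]")
        z = solar_zenith(tw, lat, lon)
        lightv = noise.sensor_max / (1.0 + np.exp((z - zenith_deg) / LIGHT_STEEPNESS_DEG))

        n_events = rng.poisson(noise.shading_rate)
        for _ in range(n_events):
            start = noon_min % 1440.0 + rng.uniform(-300.0, 300.0)
            dur = rng.uniform(10.0, 60.0)
            mask = (minutes >= start) & (minutes <= start + dur)
            lightv = np.where(mask, lightv * noise.shading_depth, lightv)

        all_times.append(times)
        all_light.append(np.clip(lightv, 0.0, noise.sensor_max))

    return LightSeries(
        np.concatenate(all_times), np.concatenate(all_light), logger_id=logger_id
    )


def true_twilights(track: SimTrack, zenith_deg: float = 96.0):
    """Noise-free predicted twilight times per day of the track (for
    scoring twilight detection), as a list of (date, sunrise, sunset)."""
    out = []
    for row in track.positions.itertuples():
        pred = predict_twilights(row.date, (row.lat, row.lon), zenith_deg)
        if pred is not None:
            out.append((row.date, pred[0], pred[1]))
    return out
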