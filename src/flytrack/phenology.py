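"""Migration-phenology rules: winter delimitation, spring metrics, QC.

The delimitation rules operate on a stationary-period schedule:

* the winter period begins with the first stationary period of at
  least 30 days after the deployment season;
* spring migration initiates at the end of the first >=30-day period
  that is not followed by another >=30-day period;
* spring migration terminates on the first post-initiation date whose
  daily longitude 95% credible interval contains the breeding-site
  longitude, floored (at the austral sites) by the census
  first-observation date for that year;
* spring stopovers are the stationary periods strictly between
  initiation and arrival.

Day arithmetic is inclusive: a migration initiated on 23 Sep with
arrival on 10 Oct lasts 18 days, counting both endpoints.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field, replace
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .geo import GeoPoint, great_circle_km
from .schedule import Schedule, StationaryPeriod
from .sites import SiteConfig
from .track import LocationPosterior

MIN_WINTER_PERIOD_DAYS = 30


@dataclass
class PhenologyRecord:
    """One individual's migration history (one table row)."""

    individual_id: str
    site: str
    sex: str = ""
    n_winter_sites: Optional[int] = None
    winter_duration_days: Optional[int] = None
    n_spring_stopovers: Optional[int] = None
    spring_duration_days: Optional[int] = None
    spring_distance_km: Optional[float] = None
    spring_rate_km_per_day: Optional[float] = None
    spring_stopover_days: Optional[int] = None
    spring_initiation: Optional[dt.date] = None
    spring_arrival: Optional[dt.date] = None
    excluded: bool = False
    exclusion_reason: str = ""

    def __post_init__(self):
        for name in ("winter_duration_days", "spring_duration_days",
                     "spring_stopover_days", "spring_distance_km"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.spring_initiation and self.spring_arrival and self.spring_duration_days:
            implied = (self.spring_arrival - self.spring_initiation).days + 1
            if implied != self.spring_duration_days:
                raise ValueError(
                    "spring_duration_days inconsistent with initiation/arrival "
                    f"({self.spring_duration_days} vs {implied})"
                )


@dataclass(frozen=True)
class WinterDelimitation:
    winter_start: dt.date
    spring_initiation: dt.date
    n_winter_sites: int
    winter_duration_days: int
    last_winter_period: StationaryPeriod


def delimit_winter(
    schedule: Schedule,
    search_from: Optional[dt.date] = None,
    search_until: Optional[dt.date] = None,
) -> Optional[WinterDelimitation]:
    """Apply the winter/spring delimitation rules to a schedule.

    ``search_from`` excludes the deployment (breeding) season from the
    >=30-day search; when omitted, a leading stationary period that
    opens the schedule is taken as the deployment season and skipped.
    ``search_until`` optionally excludes the end of the record (e.g. a
    re-occupied breeding site).  Returns ``None`` when no >=30-day
    stationary period exists (the record is then flagged).
    """
    periods = list(schedule.periods)
    if search_from is None and periods:
        first = periods[0]
        all_days = [p.start for p in periods] + list(schedule.movement_days)
        if first.start == min(all_days):
            search_from = first.end + dt.timedelta(days=1)
    if search_from is not None:
        periods = [p for p in periods if p.start >= search_from]
    if search_until is not None:
        periods = [p for p in periods if p.end <= search_until]

    big = [p for p in periods if p.duration_days >= MIN_WINTER_PERIOD_DAYS]
    if not big:
        return None
    winter_start = big[0].start
    last = big[-1]  # first >=30-d period with no later >=30-d period
    initiation = last.end
    duration = (initiation - winter_start).days + 1
    return WinterDelimitation(winter_start, initiation, len(big), duration, last)


def detect_arrival(
    post: LocationPosterior,
    site: SiteConfig,
    initiation: dt.date,
) -> Optional[dt.date]:
    """First post-initiation date whose longitude 95% CrI contains the
    breeding-site longitude, floored by the census date at austral
    sites.  ``None`` when no qualifying date exists."""
    s = post.summary
    target = site.point.lon
    for row in s.itertuples():
        day = row.date
        if day <= initiation:
            continue
        if row.lon_lo <= target <= row.lon_hi:
            floor = site.census_floor(day.year)
            if floor is not None and day < floor:
                return floor
            return day
    return None


def spring_metrics(
    schedule: Schedule,
    winter: WinterDelimitation,
    arrival: Optional[dt.date],
    site: SiteConfig,
    individual_id: str = "",
    sex: str = "",
) -> PhenologyRecord:
    """Assemble the per-individual phenology record.

    Distance is the great-circle distance from the median location of
    the last winter stationary period to the breeding site; duration is
    inclusive of both endpoints; rate is their ratio; stopovers are the
    stationary periods strictly between initiation and arrival.
    """
    init = winter.spring_initiation
    if arrival is not None and arrival < init:
        raise ValueError("arrival precedes spring initiation")
    distance = great_circle_km(winter.last_winter_period.point, site.point)

    if arrival is not None:
        stops = [p for p in schedule.periods if p.start > init and p.end < arrival]
        duration = (arrival - init).days + 1
        rate = distance / duration
    else:
        stops = [p for p in schedule.periods if p.start > init]
        duration = None
        rate = None
    return PhenologyRecord(
        individual_id=individual_id,
        site=site.code,
        sex=sex,
        n_winter_sites=winter.n_winter_sites,
        winter_duration_days=winter.winter_duration_days,
        n_spring_stopovers=len(stops),
        spring_duration_days=duration,
        spring_distance_km=distance,
        spring_rate_km_per_day=rate,
        spring_stopover_days=sum(p.duration_days for p in stops),
        spring_initiation=init,
        spring_arrival=arrival,
    )


def qc_rate_outlier(
    records: Sequence[PhenologyRecord], factor: float = 2.0
) -> List[PhenologyRecord]:
    """Flag implausible migration rates within each site.

    A record is excluded when its rate exceeds ``factor`` times the
    next-fastest rate at the same site (an artefact of arrival-date
    uncertainty).  Records without a rate, and sites with a single
    rated record, are never flagged.
    """
    out = [replace(r) if hasattr(r, "__dataclass_fields__") else r for r in records]
    by_site = {}
    for i, r in enumerate(out):
        if r.spring_rate_km_per_day is not None:
            by_site.setdefault(r.site, []).append(i)
    for site, idxs in by_site.items():
        if len(idxs) < 2:
            continue
        idxs_sorted = sorted(idxs, key=lambda i: -out[i].spring_rate_km_per_day)
        for a, b in zip(idxs_sorted, idxs_sorted[1:]):
            ra = out[a].spring_rate_km_per_day
            rb = out[b].spring_rate_km_per_day
            if ra > factor * rb:
                out[a] = replace(
                    out[a], excluded=True,
                    exclusion_reason=f"rate {ra:.0f} km/day > {factor} x next fastest at {site}",
                )
    return out


# ---------------------------------------------------------------------------
# tabulation

_COLUMNS = [
    "individual_id", "site", "group", "sex", "n_winter_sites",
    "winter_duration_days", "n_spring_stopovers", "spring_duration_days",
    "spring_distance_km", "spring_rate_km_per_day", "spring_stopover_days",
    "spring_initiation", "spring_arrival", "excluded", "exclusion_reason",
]


def records_to_frame(records: Sequence[PhenologyRecord], sites=None) -> pd.DataFrame:
    """Phenology records as a table mirroring the reporting layout:
    distances to whole km, rates to one decimal."""
    from .sites import SITES

    sites = sites or SITES
    rows = []
    for r in records:
        rows.append(
            dict(
                individual_id=r.individual_id,
                site=r.site,
                group=sites[r.site].group if r.site in sites else "",
                sex=r.sex,
                n_winter_sites=r.n_winter_sites,
                winter_duration_days=r.winter_duration_days,
                n_spring_stopovers=r.n_spring_stopovers,
                spring_duration_days=r.spring_duration_days,
                spring_distance_km=(
                    None if r.spring_distance_km is None else round(r.spring_distance_km)
                ),
                spring_rate_km_per_day=(
                    None if r.spring_rate_km_per_day is None
                    else round(r.spring_rate_km_per_day, 1)
                ),
                spring_stopover_days=r.spring_stopover_days,
                spring_initiation=r.spring_initiation,
                spring_arrival=r.spring_arrival,
                excluded=r.excluded,
                exclusion_reason=r.exclusion_reason,
            )
        )
    return pd.DataFrame(rows, columns=_COLUMNS)
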