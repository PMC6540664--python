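"""Threshold-method geolocation: a (lat, lon) fix from one twilight pair.

Longitude follows from the midpoint of sunrise and sunset versus
apparent solar noon (equation of time applied); latitude from day
length and solar declination at the calibrated zenith angle.  Near the
equinoxes day length is ~12 h at every latitude, so latitude becomes
unidentifiable and is flagged rather than trusted.
"""

from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np

from .geo import GeoPoint, normalize_lon
from .light import TwilightEvent
from .solar import solar_position

#: |day length - 12 h| below which latitude is flagged unreliable (minutes);
#: only meaningful at zenith 90, kept as a cheap guard.
EQUINOX_DAYLENGTH_MIN = 8.0

#: latitude sensitivity (degrees latitude per minute of day length) above
#: which the fix is flagged; twilight noise is minutes-scale, so beyond
#: this the latitude is dominated by noise (the equinox problem).
MAX_LAT_SENSITIVITY_DEG_PER_MIN = 2.0

FLAG_OK = "ok"
FLAG_LAT_UNRELIABLE = "latitude_unreliable"


@dataclass(frozen=True)
class ThresholdFix:
    point: GeoPoint
    flag: str
    date: Optional[dt.date] = None


def _minutes_of_day_utc(t: dt.datetime) -> float:
    return t.hour * 60.0 + t.minute + t.second / 60.0 + t.microsecond / 6e7


def threshold_location(sunrise: dt.datetime, sunset: dt.datetime, zenith_deg: float) -> ThresholdFix:
    """Locate the twilight pair (sunrise before sunset, same light period).

    Returns the fix, flagged ``latitude_unreliable`` when day
    length is within the equinox window or the latitude equation has no
    solution; longitude is always returned.
    """
    if sunset <= sunrise:
        raise ValueError("sunrise must precede sunset within one light period")
    day_len_min = (sunset - sunrise).total_seconds() / 60.0
    if not 0.0 < day_len_min < 24.0 * 60.0:
        raise ValueError("day length outside (0, 24 h)")

    tmid = sunrise + (sunset - sunrise) / 2
    decl, eot = solar_position(tmid)

    # solar noon occurs at 720 - 4*lon - eot minutes UTC of tmid's day;
    # tmid may spill past midnight relative to sunrise's date, which the
    # longitude wrap absorbs.
    lon = normalize_lon((720.0 - _minutes_of_day_utc(tmid) - eot) / 4.0)

    # latitude from day length: hour angle at the crossings
    ha = math.radians(day_len_min / 2.0 / 4.0)  # minutes -> degrees -> rad
    d = math.radians(decl)
    cosz = math.cos(math.radians(zenith_deg))
    a = math.sin(d)
    b = math.cos(d) * math.cos(ha)
    r = math.hypot(a, b)
    alpha = math.atan2(b, a)
    flag = FLAG_OK
    ratio = cosz / r
    if abs(ratio) > 1.0:
        ratio = max(-1.0, min(1.0, ratio))
        flag = FLAG_LAT_UNRELIABLE
    # the zenith equation admits two latitude roots when zenith != 90;
    # the spurious one sits near a pole, so keep the equator-nearer root
    cands = [math.asin(ratio) - alpha, math.pi - math.asin(ratio) - alpha]
    lats = []
    for phi in cands:
        phi = math.atan2(math.sin(phi), math.cos(phi))  # wrap to (-pi, pi]
        if abs(phi) <= math.pi / 2 + 1e-9:
            resid = abs(math.sin(phi) * a + math.cos(phi) * b - cosz)
            if resid < 1e-6:
                lats.append((abs(phi), math.degrees(phi)))
    if not lats:
        lat = 0.0
        flag = FLAG_LAT_UNRELIABLE
    else:
        lats.sort()
        lat = max(-90.0, min(90.0, lats[0][1]))

    # conditioning: degrees of latitude per minute of day-length error.
    # Near an equinox this blows up (the classic latitude degeneracy).
    phi_r = math.radians(lat)
    dfdphi = math.cos(phi_r) * a - math.sin(phi_r) * b
    dfdh = math.cos(phi_r) * math.cos(d) * math.sin(ha)
    if abs(dfdphi) < 1e-12:
        flag = FLAG_LAT_UNRELIABLE
    else:
        sens = abs(dfdh / dfdphi) / 8.0  # dphi/dH [deg/deg] -> deg per minute
        if sens > MAX_LAT_SENSITIVITY_DEG_PER_MIN:
            flag = FLAG_LAT_UNRELIABLE
    # at zenith 90 a 12-h day means equinox everywhere; at other zeniths
    # a 12-h light day is an ordinary, well-conditioned case
    if abs(zenith_deg - 90.0) < 0.5 and abs(day_len_min - 720.0) < EQUINOX_DAYLENGTH_MIN:
        flag = FLAG_LAT_UNRELIABLE
    return ThresholdFix(GeoPoint(lat, lon), flag)


@dataclass(frozen=True)
class TwilightPair:
    """One light period's sunrise/sunset, keyed to a civil date.

    The date is the local civil date of the light period's midpoint,
    using the midpoint-longitude time offset.
    """

    sunrise: dt.datetime
    sunset: dt.datetime
    date: dt.date


def pair_twilights(events: Sequence[TwilightEvent]) -> List[TwilightPair]:
    """Pair consecutive sunrise->sunset events into daily light periods.

    Excluded events are dropped first; unpaired leading sunsets or
    trailing sunrises are discarded.
    """
    evs = [e for e in events if not e.excluded]
    pairs: List[TwilightPair] = []
    i = 0
    while i < len(evs) - 1:
        if evs[i].kind == "sunrise" and evs[i + 1].kind == "sunset":
            sr, ss = evs[i].time, evs[i + 1].time
            tmid = sr + (ss - sr) / 2
            decl, eot = solar_position(tmid)
            lon = normalize_lon((720.0 - _minutes_of_day_utc(tmid) - eot) / 4.0)
            local = tmid + dt.timedelta(hours=lon / 15.0)
            pairs.append(TwilightPair(sr, ss, local.date()))
            i += 2
        else:
            i += 1
    return pairs


def threshold_path(pairs: Sequence[TwilightPair], zenith_deg: float) -> List[ThresholdFix]:
    """Threshold fixes for a sequence of twilight pairs, flagged latitudes
    linearly interpolated from the neighbouring reliable days."""
    fixes = []
    for p in pairs:
        fix = threshold_location(p.sunrise, p.sunset, zenith_deg)
        fixes.append(ThresholdFix(fix.point, fix.flag, p.date))
    lats = np.array([f.point.lat for f in fixes])
    ok = np.array([f.flag == FLAG_OK for f in fixes])
    if ok.any() and not ok.all():
        idx = np.arange(len(fixes))
        lats[~ok] = np.interp(idx[~ok], idx[ok], lats[ok])
        fixes = [
            ThresholdFix(GeoPoint(float(la), f.point.lon), f.flag, f.date)
            for la, f in zip(lats, fixes)
        ]
    return fixes
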