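"""Low-precision solar geometry (NOAA closed-form) and twilight prediction.

The solar position is computed from the NOAA "general solar position
calculations" Fourier series in the fractional year: declination to
better than 0.3 degrees and equation of time to better than 0.5 minutes.
That accuracy is an order of magnitude below the intrinsic error of
light-level geolocation (0.5-2 degrees), so no ephemeris is needed.

All timestamps are UTC.  Supported years: 1950-2100.
"""

from __future__ import annotations

import datetime as dt
from typing import Optional, Tuple

import numpy as np

__all__ = [
    "solar_position",
    "solar_zenith",
    "predict_twilights",
    "twilight_minutes_utc",
]

_MIN_YEAR, _MAX_YEAR = 1950, 2100


def _to_datetime64(t) -> np.ndarray:
    arr = np.asarray(t, dtype="datetime64[s]")
    years = arr.astype("datetime64[Y]").astype(int) + 1970
    if np.any((years < _MIN_YEAR) | (years > _MAX_YEAR)):
        raise ValueError(f"timestamp outside supported range {_MIN_YEAR}-{_MAX_YEAR}")
    return arr


def _fractional_year(t64: np.ndarray) -> np.ndarray:
    """Fractional year in radians from a datetime64[s] array."""
    year_start = t64.astype("datetime64[Y]")
    doy = (t64.astype("datetime64[D]") - year_start.astype("datetime64[D]")).astype(float)
    day_start = t64.astype("datetime64[D]")
    hour = (t64 - day_start.astype("datetime64[s]")).astype(float) / 3600.0
    return 2.0 * np.pi / 365.0 * (doy + (hour - 12.0) / 24.0)


def solar_position(t):
    """Solar declination (degrees) and equation of time (minutes) at UTC time ``t``.

    Parameters
    ----------
    t : datetime-like or array of datetime64
        UTC timestamp(s) within 1950-2100.

    Returns
    -------
    (declination_deg, eot_min)
        Scalars for scalar input, arrays otherwise.  Declination lies in
        [-23.5, 23.5]; the equation of time in roughly [-15, 17].
    """
    t64 = _to_datetime64(t)
    g = _fractional_year(t64)
    eot = 229.18 * (
        0.000075
        + 0.001868 * np.cos(g)
        - 0.032077 * np.sin(g)
        - 0.014615 * np.cos(2 * g)
        - 0.040849 * np.sin(2 * g)
    )
    decl = (
        0.006918
        - 0.399912 * np.cos(g)
        + 0.070257 * np.sin(g)
        - 0.006758 * np.cos(2 * g)
        + 0.000907 * np.sin(2 * g)
        - 0.002697 * np.cos(3 * g)
        + 0.00148 * np.sin(3 * g)
    )
    decl = np.degrees(decl)
    if t64.ndim == 0:
        return float(decl), float(eot)
    return decl, eot


def _minutes_of_day(t64: np.ndarray) -> np.ndarray:
    day = t64.astype("datetime64[D]").astype("datetime64[s]")
    return (t64 - day).astype(float) / 60.0


def hour_angle_deg(t, lon):
    """Solar hour angle in degrees (0 at local apparent noon, afternoon positive)."""
    t64 = _to_datetime64(t)
    _, eot = solar_position(t)
    tst = _minutes_of_day(t64) + eot + 4.0 * np.asarray(lon, dtype=float)
    return tst / 4.0 - 180.0


def solar_zenith(t, lat, lon):
    """Solar zenith angle in degrees at UTC time ``t`` and position (lat, lon)."""
    decl, _ = solar_position(t)
    h = np.radians(hour_angle_deg(t, lon))
    phi = np.radians(np.asarray(lat, dtype=float))
    d = np.radians(decl)
    cosz = np.sin(phi) * np.sin(d) + np.cos(phi) * np.cos(d) * np.cos(h)
    z = np.degrees(np.arccos(np.clip(cosz, -1.0, 1.0)))
    return float(z) if np.ndim(z) == 0 else z


def twilight_minutes_utc(decl_deg, eot_min, lat, lon, zenith_deg):
    """Sunrise/sunset minutes past UTC midnight for given solar parameters.

    Vectorised core of :func:`predict_twilights`: solves the hour angle at
    which the sun crosses ``zenith_deg``.  Returns (sunrise_min, sunset_min)
    with NaN where there is no crossing (polar day or night at that zenith).
    """
    phi = np.radians(np.asarray(lat, dtype=float))
    d = np.radians(np.asarray(decl_deg, dtype=float))
    cosz = np.cos(np.radians(np.asarray(zenith_deg, dtype=float)))
    with np.errstate(invalid="ignore", divide="ignore"):
        cosh = (cosz - np.sin(phi) * np.sin(d)) / (np.cos(phi) * np.cos(d))
    cosh = np.where(np.abs(cosh) > 1.0, np.nan, cosh)
    ha = np.degrees(np.arccos(cosh))
    lon = np.asarray(lon, dtype=float)
    sunrise = 720.0 - 4.0 * (lon + ha) - eot_min
    sunset = 720.0 - 4.0 * (lon - ha) - eot_min
    return sunrise, sunset


def predict_twilights(
    date, point, zenith_deg: float, *, n_refine: int = 2
) -> Optional[Tuple[dt.datetime, dt.datetime]]:
    """Predicted sunrise and sunset (UTC) for ``date`` at ``point``.

    ``date`` is the UTC calendar date of the event pair; ``point`` any
    (lat, lon) pair.  The crossing is first solved with the solar
    parameters of 12:00 UTC and then refined at the provisional event
    times.  Returns ``None`` when the sun never crosses ``zenith_deg``
    that day (polar day/night for that zenith).
    """
    lat, lon = point
    if not 85.0 <= zenith_deg <= 100.0:
        raise ValueError(f"zenith {zenith_deg} outside calibration bounds [85, 100]")
    d0 = np.datetime64(f"{date:%Y-%m-%d}", "s")
    t_guess_sr = d0 + np.timedelta64(12 * 3600, "s")
    t_guess_ss = t_guess_sr
    sr = ss = np.nan
    for _ in range(1 + n_refine):
        decl_sr, eot_sr = solar_position(t_guess_sr)
        decl_ss, eot_ss = solar_position(t_guess_ss)
        sr, _ = twilight_minutes_utc(decl_sr, eot_sr, lat, lon, zenith_deg)
        _, ss = twilight_minutes_utc(decl_ss, eot_ss, lat, lon, zenith_deg)
        if np.isnan(sr) or np.isnan(ss):
            return None
        t_guess_sr = d0 + np.timedelta64(int(round(sr * 60)), "s")
        t_guess_ss = d0 + np.timedelta64(int(round(ss * 60)), "s")
    base = dt.datetime(date.year, date.month, date.day)
    return (
        base + dt.timedelta(minutes=float(sr)),
        base + dt.timedelta(minutes=float(ss)),
    )
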