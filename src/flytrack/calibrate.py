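"""In-habitat calibration: zenith angle and twilight-error distribution.

While the bird is known to be at the capture site, every observed
twilight can be compared with the twilight predicted by solar geometry.
Shading can only make a sunrise later and a sunset earlier, so the
twilight "delay" is one-sided (>= 0) and is modelled log-normally.

The zenith angle is anchored at the *least shaded* twilight: the
maximum solar zenith observed at any threshold crossing.  Because even
the cleanest twilight carries some residual delay, that anchor is then
shifted by a profile maximum-likelihood estimate of the residual
minimum delay: the additive shift that makes the observed delays most
log-normal.  A median-based zenith would instead absorb the *typical*
delay and sit 1-2 degrees low.
"""

from __future__ import annotations

import datetime as dt
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np

from .geo import GeoPoint
from .light import LightSeries, find_twilights
from .locate import TwilightPair, pair_twilights
from .solar import predict_twilights, solar_zenith

#: delays are floored at this value (minutes) before log-normal fitting
DELAY_FLOOR_MIN = 0.01
#: minimum admissible sdlog when the observed delays are degenerate
SDLOG_FLOOR = 0.05

MIN_TWILIGHT_PAIRS = 10


@dataclass(frozen=True)
class CalibrationModel:
    """Calibrated threshold-method parameters for one logger.

    ``zenith_deg`` is the sun's angle from vertical when light crosses
    the threshold; ``err_meanlog``/``err_sdlog`` parameterise the
    log-normal distribution of twilight delays in minutes (sunrise
    observed late, sunset observed early).
    """

    zenith_deg: float
    err_meanlog: float
    err_sdlog: float
    threshold: float

    def __post_init__(self):
        if not 85.0 <= self.zenith_deg <= 100.0:
            raise ValueError(f"zenith {self.zenith_deg} outside [85, 100]")
        if self.err_sdlog < 0:
            raise ValueError("err_sdlog must be >= 0")
        if self.threshold <= 0:
            raise ValueError("threshold must be > 0")


def _zenith_rate_deg_per_min(t: dt.datetime, point: GeoPoint) -> float:
    """|dZ/dt| at a twilight, by central difference over one minute."""
    t0 = np.datetime64(t.replace(microsecond=0), "s")
    z0 = solar_zenith(t0 - np.timedelta64(30, "s"), point.lat, point.lon)
    z1 = solar_zenith(t0 + np.timedelta64(30, "s"), point.lat, point.lon)
    return abs(float(z1) - float(z0))


def twilight_delays(
    pairs: Sequence[TwilightPair], point, zenith_deg: float
) -> np.ndarray:
    """Observed-minus-predicted twilight delays in minutes, oriented so
    that shading gives positive values (late sunrise, early sunset).
    Days where the zenith is never crossed are skipped."""
    delays = []
    for p in pairs:
        pred = predict_twilights(p.date, point, zenith_deg)
        if pred is None:
            continue
        pred_sr, pred_ss = pred
        delays.append((p.sunrise - pred_sr).total_seconds() / 60.0)
        delays.append((pred_ss - p.sunset).total_seconds() / 60.0)
    return np.asarray(delays)


def _profile_shift(w: np.ndarray) -> float:
    """Profile-MLE additive shift making ``w + m`` most log-normal.

    ``w`` are delays measured from the max-zenith anchor (min ~ 0); the
    true delays are ``w`` plus the residual delay of the cleanest
    twilight.  The shift is profiled over (0, median(w)] - it cannot
    plausibly exceed the median delay - with the log-normal mean/sd at
    their closed-form optima.
    """
    from scipy.optimize import minimize_scalar

    q50 = float(np.quantile(w, 0.5))
    if q50 <= 1e-3:
        return 0.0

    def negll(logm):
        x = w + np.exp(logm)
        logs = np.log(x)
        sd = max(float(np.std(logs)), SDLOG_FLOOR)
        return float(np.sum(logs)) + len(x) * np.log(sd)

    res = minimize_scalar(negll, bounds=(np.log(1e-3), np.log(q50)), method="bounded")
    return float(np.exp(res.x))


def calibrate(
    series: LightSeries,
    known: GeoPoint,
    window: Optional[Tuple[dt.datetime, dt.datetime]] = None,
    threshold: float = 0.5,
    min_dark_minutes: float = 120.0,
) -> CalibrationModel:
    """Fit zenith angle and log-normal twilight-error model at a known site.

    Parameters
    ----------
    series
        Light series recorded while the bird was at ``known``.
    known
        The capture/breeding location.
    window
        Optional (start, end) restriction of the series (the span over
        which the bird is known to have been on site).
    threshold
        Light threshold defining twilights.

    Raises
    ------
    ValueError
        If the window contains fewer than 10 usable twilight pairs.
    """
    if window is not None:
        lo = np.datetime64(window[0], "s")
        hi = np.datetime64(window[1], "s")
        sel = (series.times >= lo) & (series.times <= hi)
        series = LightSeries(series.times[sel], series.light[sel], series.logger_id)
    events = find_twilights(series, threshold, min_dark_minutes)
    pairs = pair_twilights(events)
    if len(pairs) < MIN_TWILIGHT_PAIRS:
        raise ValueError(
            f"calibration window holds {len(pairs)} twilight pairs; "
            f"need at least {MIN_TWILIGHT_PAIRS}"
        )

    # anchor: zenith of the least-shaded crossing
    obs_z = []
    rates = []
    for p in pairs:
        for t in (p.sunrise, p.sunset):
            obs_z.append(float(solar_zenith(np.datetime64(t.replace(microsecond=0), "s"),
                                            known.lat, known.lon)))
            rates.append(_zenith_rate_deg_per_min(t, known))
    z_ref = float(np.max(obs_z))
    z_ref = float(np.clip(z_ref, 85.0, 100.0))

    w = np.maximum(twilight_delays(pairs, known, z_ref), 0.0)
    if float(np.quantile(w, 0.5)) < 0.5:  # delays all ~ 0: noise-free logger
        warnings.warn(
            "twilight delays nearly degenerate; err_sdlog set to floor", stacklevel=2
        )
        meanlog = float(np.log(max(float(np.mean(w)), DELAY_FLOOR_MIN)))
        return CalibrationModel(z_ref, meanlog, SDLOG_FLOOR, threshold)
    m = _profile_shift(w)
    zenith = float(np.clip(z_ref + m * float(np.mean(rates)), 85.0, 100.0))

    # fit the error model on the anchored delays plus the estimated
    # residual shift (equivalent to delays at the fitted zenith, but
    # immune to re-prediction noise near the floor)
    d = np.maximum(w + m, DELAY_FLOOR_MIN)
    logs = np.log(d)
    meanlog = float(np.mean(logs))
    sdlog = float(np.std(logs))
    if sdlog < SDLOG_FLOOR:
        warnings.warn(
            "twilight delays nearly degenerate; err_sdlog set to floor", stacklevel=2
        )
        sdlog = SDLOG_FLOOR
    return CalibrationModel(zenith, meanlog, sdlog, threshold)
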