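"""Metropolis sampler for daily location posteriors from twilight times.

The model mirrors the threshold-geolocation state-space used for
songbird tags: per day, the likelihood of a (lat, lon) state is the
log-normal density of the observed-minus-predicted twilight delays
(sunrise can only be observed late, sunset only early); consecutive
days are tied together by a beta-distributed prior on great-circle
speed; an optional land mask excludes off-mask states.  Sampling is a
Gaussian random-walk Metropolis scheme updated day-by-day in a
checkerboard pattern (even days given odd, then odd given even), which
keeps the single-site conditionals exact while allowing full
vectorisation across chains and days.

Protocol: ``n_runs`` successive runs of ``n_chains`` chains; all runs
but the last serve as burn-in, each run starting from the previous
run's median daily locations; only the final run is retained, thinned
by ``thin``.
"""

from __future__ import annotations

import datetime as dt
import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd

from .calibrate import CalibrationModel, DELAY_FLOOR_MIN
from .geo import great_circle_km_vec, normalize_lon
from .locate import TwilightPair, threshold_path
from .solar import solar_position

_LOG_2PI = math.log(2.0 * math.pi)


@dataclass(frozen=True)
class SpeedPrior:
    """Beta prior on daily travel speed, scaled by ``max_speed_kmh``."""

    shape1: float = 2.2
    shape2: float = 2.0
    max_speed_kmh: float = 80.0

    def __post_init__(self):
        if self.shape1 <= 0 or self.shape2 <= 0 or self.max_speed_kmh <= 0:
            raise ValueError("speed prior parameters must be positive")

    def logpdf(self, speed_kmh):
        from scipy.special import betaln

        x = np.clip(np.asarray(speed_kmh, dtype=float) / self.max_speed_kmh, 1e-6, 1 - 1e-6)
        return (
            (self.shape1 - 1.0) * np.log(x)
            + (self.shape2 - 1.0) * np.log1p(-x)
            - betaln(self.shape1, self.shape2)
        )


@dataclass(frozen=True)
class MCMCConfig:
    """Sampler protocol: runs x chains x iterations, thinning, proposal scale."""

    n_iter: int = 5000
    n_chains: int = 3
    n_runs: int = 3
    thin: int = 2
    proposal_sd_deg: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.n_iter < 1 or self.n_chains < 1 or self.thin < 1 or self.n_runs < 1:
            raise ValueError("n_iter, n_chains, n_runs and thin must all be >= 1")


class LandMask:
    """Polygon set over which positions are permitted (e.g., land)."""

    def __init__(self, geometry):
        import shapely

        self.geometry = shapely.unary_union(geometry) if isinstance(geometry, (list, tuple)) else geometry
        shapely.prepare(self.geometry)

    @classmethod
    def from_geojson(cls, path) -> "LandMask":
        import shapely.geometry

        with open(path) as fh:
            gj = json.load(fh)
        geoms = []
        feats = gj["features"] if gj.get("type") == "FeatureCollection" else [gj]
        for f in feats:
            geom = f.get("geometry", f)
            geoms.append(shapely.geometry.shape(geom))
        return cls(geoms)

    def contains(self, lat, lon):
        import shapely

        return shapely.contains_xy(self.geometry, np.asarray(lon, float), np.asarray(lat, float))


@dataclass
class LocationPosterior:
    """Daily location posterior: per-day samples, medians and 95% CrIs."""

    dates: List[dt.date]
    samples: Optional[np.ndarray]  # (n_days, n_samples, 2) as (lat, lon)
    _summary: Optional[pd.DataFrame] = field(default=None, repr=False)

    @property
    def summary(self) -> pd.DataFrame:
        if self._summary is None:
            self._summary = summarize_posterior(self.samples, self.dates)
        return self._summary

    @classmethod
    def from_summary(cls, df: pd.DataFrame) -> "LocationPosterior":
        df = df.copy()
        dates = [d if isinstance(d, dt.date) and not isinstance(d, dt.datetime)
                 else pd.Timestamp(d).date() for d in df["date"]]
        df["date"] = dates
        return cls(dates, None, df.reset_index(drop=True))

    def to_summary_csv(self, path) -> None:
        self.summary.to_csv(path, index=False)

    @classmethod
    def from_summary_csv(cls, path) -> "LocationPosterior":
        return cls.from_summary(pd.read_csv(path))

    def to_samples_csv(self, path) -> None:
        if self.samples is None:
            raise ValueError("posterior carries no samples")
        n_days, n_samp, _ = self.samples.shape
        df = pd.DataFrame(
            {
                "date": np.repeat([d.isoformat() for d in self.dates], n_samp),
                "sample_id": np.tile(np.arange(n_samp), n_days),
                "lat": self.samples[:, :, 0].ravel(),
                "lon": self.samples[:, :, 1].ravel(),
            }
        )
        df.to_csv(path, index=False)


def summarize_posterior(samples: np.ndarray, dates: Sequence[dt.date]) -> pd.DataFrame:
    """Componentwise median and central 95% credible interval per day.

    ``samples`` has shape (n_days, n_samples, 2); at least 10 retained
    samples per day are required.
    """
    samples = np.asarray(samples, dtype=float)
    if samples.ndim != 3 or samples.shape[1] < 10:
        raise ValueError("need samples of shape (n_days, >=10, 2)")
    qs = np.quantile(samples, [0.5, 0.025, 0.975], axis=1)  # (3, n_days, 2)
    return pd.DataFrame(
        {
            "date": list(dates),
            "lat_med": qs[0, :, 0],
            "lat_lo": qs[1, :, 0],
            "lat_hi": qs[2, :, 0],
            "lon_med": qs[0, :, 1],
            "lon_lo": qs[1, :, 1],
            "lon_hi": qs[2, :, 1],
        }
    )


# ---------------------------------------------------------------------------
# likelihood machinery


class _DayData:
    """Precomputed per-day twilight observations and solar parameters."""

    def __init__(self, pairs: Sequence[TwilightPair]):
        if len(pairs) < 1:
            raise ValueError("no twilight pairs")
        self.pairs = list(pairs)
        self.dates = [p.date for p in pairs]
        n = len(pairs)
        self.obs_sr = np.empty(n)
        self.obs_ss = np.empty(n)
        self.decl_sr = np.empty(n)
        self.eot_sr = np.empty(n)
        self.decl_ss = np.empty(n)
        self.eot_ss = np.empty(n)
        for i, p in enumerate(pairs):
            sr64 = np.datetime64(p.sunrise.replace(microsecond=0), "s")
            ss64 = np.datetime64(p.sunset.replace(microsecond=0), "s")
            self.obs_sr[i] = _minutes_in_day(p.sunrise)
            self.obs_ss[i] = _minutes_in_day(p.sunset)
            self.decl_sr[i], self.eot_sr[i] = solar_position(sr64)
            self.decl_ss[i], self.eot_ss[i] = solar_position(ss64)
        self.day_gaps = np.array(
            [(b - a).days for a, b in zip(self.dates, self.dates[1:])], dtype=float
        )
        if np.any(self.day_gaps <= 0):
            raise ValueError("twilight pairs must be in strictly increasing date order")


def _minutes_in_day(t: dt.datetime) -> float:
    return t.hour * 60.0 + t.minute + t.second / 60.0 + t.microsecond / 6e7


def _wrap_minutes(delta):
    """Wrap a minute difference into [-720, 720) (day-boundary safety)."""
    return (delta + 720.0) % 1440.0 - 720.0


def _twilight_ll_arrays(lat, lon, idx, day: "_DayData", calib: CalibrationModel):
    """Log-likelihood of twilight delays for states at days ``idx``.

    ``lat``/``lon`` are arrays broadcastable against ``idx``.  Returns
    -inf where a predicted twilight does not exist (polar) or a delay is
    non-positive after flooring.
    """
    phi = np.radians(lat)
    cosz = math.cos(math.radians(calib.zenith_deg))

    out = np.zeros(np.broadcast(lat, lon).shape)
    for which in ("sr", "ss"):
        decl = (day.decl_sr if which == "sr" else day.decl_ss)[idx]
        eot = (day.eot_sr if which == "sr" else day.eot_ss)[idx]
        obs = (day.obs_sr if which == "sr" else day.obs_ss)[idx]
        d = np.radians(decl)
        with np.errstate(invalid="ignore", divide="ignore"):
            cosh = (cosz - np.sin(phi) * np.sin(d)) / (np.cos(phi) * np.cos(d))
        valid = np.abs(cosh) <= 1.0
        ha = np.degrees(np.arccos(np.where(valid, cosh, 0.0)))
        if which == "sr":
            pred = 720.0 - 4.0 * (lon + ha) - eot
            delay = _wrap_minutes(obs - pred)
        else:
            pred = 720.0 - 4.0 * (lon - ha) - eot
            delay = _wrap_minutes(pred - obs)
        ok = valid & (delay > DELAY_FLOOR_MIN)
        logd = np.log(np.where(ok, delay, 1.0))
        z = (logd - calib.err_meanlog) / calib.err_sdlog
        ll = -logd - math.log(calib.err_sdlog) - 0.5 * _LOG_2PI - 0.5 * z * z
        out = out + np.where(ok, ll, -np.inf)
    return out


def twilight_loglik(pairs, point, calib: CalibrationModel) -> float:
    """Log-likelihood of one day's twilight pair(s) at ``point``.

    Sum over the supplied twilight pairs of the log-normal log-density
    of the (observed - predicted) delay, oriented so shading delays
    sunrise and advances sunset; -inf if any predicted twilight is
    missing or any delay is non-positive.
    """
    if isinstance(pairs, TwilightPair):
        pairs = [pairs]
    day = _DayData(list(pairs))
    lat, lon = point
    idx = np.arange(len(day.pairs))
    vals = _twilight_ll_arrays(
        np.full(len(idx), float(lat)), np.full(len(idx), float(lon)), idx, day, calib
    )
    return float(np.sum(vals))


def _speed_ll(lat_a, lon_a, lat_b, lon_b, gap_days, prior: SpeedPrior):
    km = great_circle_km_vec(lat_a, lon_a, lat_b, lon_b)
    return prior.logpdf(km / (24.0 * gap_days))


def _reflect_lat(lat):
    lat = np.where(lat > 90.0, 180.0 - lat, lat)
    return np.where(lat < -90.0, -180.0 - lat, lat)


def sample_track_posterior(
    pairs: Sequence[TwilightPair],
    calib: CalibrationModel,
    prior: SpeedPrior = SpeedPrior(),
    mask: Optional[LandMask] = None,
    cfg: MCMCConfig = MCMCConfig(),
    init: Optional[np.ndarray] = None,
) -> LocationPosterior:
    """Sample daily location posteriors for a track of twilight pairs.

    Parameters
    ----------
    pairs
        Chronological twilight pairs (one per day; gaps allowed).
    calib
        Calibration from the known-location period.
    prior
        Beta speed prior between consecutive days.
    mask
        Optional land mask; off-mask states get -inf (applied to all
        days, since stationarity is unknown while sampling).
    cfg
        Sampler protocol; deterministic given ``cfg.seed``.
    init
        Optional (n_days, 2) initial state; defaults to delay-adjusted
        threshold fixes with flagged latitudes interpolated.

    Returns
    -------
    LocationPosterior
        ``n_iter * n_chains / thin`` retained samples per day from the
        final run.
    """
    if len(pairs) < 4:
        raise ValueError("need at least 4 twilight pairs")
    day = _DayData(pairs)
    n_days = len(day.pairs)
    rng = np.random.default_rng(cfg.seed)

    if init is None:
        init = _default_init(day, calib)
    init = np.asarray(init, dtype=float)
    if init.shape != (n_days, 2):
        raise ValueError(f"init must have shape ({n_days}, 2)")

    C = cfg.n_chains
    lat = np.tile(init[:, 0], (C, 1)) + rng.normal(0.0, 0.05, (C, n_days))
    lon = np.tile(init[:, 1], (C, 1)) + rng.normal(0.0, 0.05, (C, n_days))
    lat = _reflect_lat(lat)

    all_idx = np.arange(n_days)
    ll_tw = _twilight_ll_arrays(lat, lon, np.tile(all_idx, (C, 1)), day, calib)
    if mask is not None:
        on = mask.contains(lat.ravel(), lon.ravel()).reshape(lat.shape)
        ll_tw = np.where(on, ll_tw, -np.inf)

    parity_idx = [all_idx[all_idx % 2 == 0], all_idx[all_idx % 2 == 1]]
    n_prop = 0
    n_acc = 0
    kept_lat: List[np.ndarray] = []
    kept_lon: List[np.ndarray] = []

    for run in range(cfg.n_runs):
        final = run == cfg.n_runs - 1
        burn_keep = max(1, cfg.n_iter // 500)
        run_lat: List[np.ndarray] = []
        run_lon: List[np.ndarray] = []
        for it in range(cfg.n_iter):
            for idx in parity_idx:
                k = idx.size
                p_lat = _reflect_lat(lat[:, idx] + rng.normal(0.0, cfg.proposal_sd_deg, (C, k)))
                p_lon = normalize_lon(lon[:, idx] + rng.normal(0.0, cfg.proposal_sd_deg, (C, k)))

                new_tw = _twilight_ll_arrays(p_lat, p_lon, np.tile(idx, (C, 1)), day, calib)
                if mask is not None:
                    on = mask.contains(p_lat.ravel(), p_lon.ravel()).reshape(p_lat.shape)
                    new_tw = np.where(on, new_tw, -np.inf)

                d_speed = np.zeros((C, k))
                left = idx - 1
                has_left = left >= 0
                if has_left.any():
                    j = idx[has_left]
                    gl = day.day_gaps[j - 1]
                    d_speed[:, has_left] += _speed_ll(
                        lat[:, j - 1], lon[:, j - 1], p_lat[:, has_left], p_lon[:, has_left], gl, prior
                    ) - _speed_ll(
                        lat[:, j - 1], lon[:, j - 1], lat[:, j], lon[:, j], gl, prior
                    )
                right = idx + 1
                has_right = right < n_days
                if has_right.any():
                    j = idx[has_right]
                    gr = day.day_gaps[j]
                    d_speed[:, has_right] += _speed_ll(
                        p_lat[:, has_right], p_lon[:, has_right], lat[:, j + 1], lon[:, j + 1], gr, prior
                    ) - _speed_ll(
                        lat[:, j], lon[:, j], lat[:, j + 1], lon[:, j + 1], gr, prior
                    )

                old_tw = ll_tw[:, idx]
                with np.errstate(invalid="ignore"):
                    log_alpha = new_tw - old_tw + d_speed
                # a finite proposal always beats a -inf current state
                log_alpha = np.where(
                    np.isneginf(old_tw) & np.isfinite(new_tw), np.inf, log_alpha
                )
                log_alpha = np.where(np.isnan(log_alpha), -np.inf, log_alpha)
                accept = np.log(rng.random((C, k))) < log_alpha

                lat[:, idx] = np.where(accept, p_lat, lat[:, idx])
                lon[:, idx] = np.where(accept, p_lon, lon[:, idx])
                ll_tw[:, idx] = np.where(accept, new_tw, old_tw)
                if final:
                    n_prop += accept.size
                    n_acc += int(accept.sum())
            if final:
                if (it + 1) % cfg.thin == 0:
                    kept_lat.append(lat.copy())
                    kept_lon.append(lon.copy())
            elif (it + 1) % burn_keep == 0:
                run_lat.append(lat.copy())
                run_lon.append(lon.copy())
        if not final:
            med_lat = np.median(np.array(run_lat), axis=(0, 1))
            med_lon = np.median(np.array(run_lon), axis=(0, 1))
            lat = np.tile(med_lat, (C, 1))
            lon = np.tile(med_lon, (C, 1))
            ll_tw = _twilight_ll_arrays(lat, lon, np.tile(all_idx, (C, 1)), day, calib)
            if mask is not None:
                on = mask.contains(lat.ravel(), lon.ravel()).reshape(lat.shape)
                ll_tw = np.where(on, ll_tw, -np.inf)

    rate = n_acc / max(1, n_prop)
    if not 0.05 <= rate <= 0.80:
        warnings.warn(
            f"Metropolis acceptance rate {rate:.2f} outside [0.05, 0.80]; "
            "consider adjusting proposal_sd_deg",
            stacklevel=2,
        )

    arr_lat = np.array(kept_lat)  # (n_kept, C, D)
    arr_lon = np.array(kept_lon)
    samples = np.empty((n_days, arr_lat.shape[0] * C, 2))
    samples[:, :, 0] = arr_lat.reshape(-1, n_days).T
    samples[:, :, 1] = arr_lon.reshape(-1, n_days).T
    post = LocationPosterior(day.dates, samples)
    post.acceptance_rate = rate
    return post


def _default_init(day: "_DayData", calib: CalibrationModel) -> np.ndarray:
    """Threshold fixes shifted into the interior of the delay support.

    Observed twilights are pulled inward by the typical delay
    exp(err_meanlog) so that the initial state has strictly positive
    delays (the raw threshold fix sits on the support boundary where
    the log-normal density vanishes).
    """
    shift = dt.timedelta(minutes=math.exp(calib.err_meanlog))
    adj = [
        TwilightPair(p.sunrise - shift, p.sunset + shift, p.date) for p in day.pairs
    ]
    fixes = threshold_path(adj, calib.zenith_deg)
    return np.array([[f.point.lat, f.point.lon] for f in fixes])
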