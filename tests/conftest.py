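"""Shared fixtures: simulated deployments reused across the suite.

Expensive simulation/sampling fixtures are session-scoped so each is
computed once.
"""

from __future__ import annotations

import datetime as dt
import warnings

import numpy as np
import pandas as pd
import pytest

from flytrack.calibrate import CalibrationModel
from flytrack.fixtures import table1_fixture
from flytrack.geo import GeoPoint
from flytrack.light import find_twilights
from flytrack.locate import pair_twilights
from flytrack.simulate import NoiseConfig, SimTrack, simulate_light
from flytrack.track import MCMCConfig, sample_track_posterior

TRUE_ZENITH = 96.0
TRUE_MEANLOG = float(np.log(3.0))
TRUE_SDLOG = 0.5

WINTER_POINT = GeoPoint(2.5, -65.0)


def stationary_track(point: GeoPoint, start: dt.date, n_days: int) -> SimTrack:
    """A bird sitting at one point for ``n_days`` (no legs needed)."""
    dates = [start + dt.timedelta(days=i) for i in range(n_days)]
    pos = pd.DataFrame({"date": dates, "lat": point.lat, "lon": point.lon})
    return SimTrack([], pos, {"point": point}, 0)


@pytest.fixture(scope="session")
def table1():
    return table1_fixture()


@pytest.fixture(scope="session")
def true_calibration():
    return CalibrationModel(TRUE_ZENITH, TRUE_MEANLOG, TRUE_SDLOG, 0.5)


@pytest.fixture(scope="session")
def stationary_pairs():
    """Twilight pairs for 30 noisy non-equinox days at the winter point."""
    track = stationary_track(WINTER_POINT, dt.date(2014, 6, 20), 30)
    noise = NoiseConfig(twilight_meanlog=TRUE_MEANLOG, twilight_sdlog=TRUE_SDLOG,
                        shading_rate=0.0)
    series = simulate_light(track, TRUE_ZENITH, noise, seed=11)
    return pair_twilights(find_twilights(series, 0.5))


@pytest.fixture(scope="session")
def stationary_posterior(stationary_pairs, true_calibration):
    """Reduced-protocol posterior for the 30-day stationary bird."""
    cfg = MCMCConfig(n_iter=800, n_chains=3, n_runs=3, thin=2, seed=5)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return sample_track_posterior(stationary_pairs, true_calibration, cfg=cfg)
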