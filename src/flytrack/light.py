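"""Light-series container, twilight detection, and geolocator file dialects.

Twilight events are the instants the light trace crosses a fixed
threshold: an upward crossing is a sunrise, a downward crossing a
sunset.  Detection merges brief dark interludes (shading: a wing or
vegetation over the sensor) so that a shaded patch in the middle of the
day does not spawn a spurious sunset/sunrise pair.
"""

from __future__ import annotations

import datetime as dt
import io
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, List, Optional, Sequence, Union

import numpy as np
import pandas as pd


@dataclass
class LightSeries:
    """Timestamped light measurements from one logger deployment.

    ``times`` must be strictly increasing UTC timestamps at a constant
    nominal interval (gaps are allowed and flagged); ``light`` holds
    finite non-negative readings in arbitrary sensor units.
    """

    times: np.ndarray  # datetime64[s]
    light: np.ndarray
    logger_id: str = ""
    interval_minutes: float = field(init=False)

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype="datetime64[s]")
        self.light = np.asarray(self.light, dtype=float)
        if self.times.size != self.light.size:
            raise ValueError("times and light must have equal length")
        if self.times.size < 2:
            raise ValueError("light series needs at least two samples")
        diffs = np.diff(self.times).astype(float)
        if np.any(diffs <= 0):
            raise ValueError("times must be strictly increasing")
        if not np.all(np.isfinite(self.light)) or np.any(self.light < 0):
            raise ValueError("light values must be finite and non-negative")
        self.interval_minutes = float(np.median(diffs) / 60.0)
        if np.any(diffs > 1.5 * np.median(diffs)):
            warnings.warn("light series contains sampling gaps", stacklevel=2)

    def __len__(self):
        return self.times.size

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time": self.times, "light": self.light})


@dataclass(frozen=True)
class TwilightEvent:
    """A threshold crossing: sunrise (upward) or sunset (downward)."""

    time: dt.datetime
    kind: str  # "sunrise" | "sunset"
    excluded: bool = False

    def __post_init__(self):
        if self.kind not in ("sunrise", "sunset"):
            raise ValueError(f"kind must be sunrise|sunset, got {self.kind!r}")


def check_alternation(events: Sequence[TwilightEvent]) -> List[int]:
    """Indices where consecutive events fail to alternate sunrise/sunset."""
    bad = []
    for i in range(1, len(events)):
        if events[i].kind == events[i - 1].kind:
            bad.append(i)
    return bad


def _interp_crossing(t0, t1, l0, l1, threshold) -> dt.datetime:
    frac = 0.5 if l1 == l0 else (threshold - l0) / (l1 - l0)
    t0s = t0.astype("datetime64[s]").astype(dt.datetime)
    step = (t1 - t0).astype("timedelta64[s]").astype(float)
    return t0s + dt.timedelta(seconds=float(frac) * step)


def find_twilights(
    series: LightSeries,
    threshold: float = 0.5,
    min_dark_minutes: float = 120.0,
    min_light_minutes: float = 120.0,
) -> List[TwilightEvent]:
    """Detect sunrise/sunset threshold crossings in a light series.

    Crossing times are linearly interpolated between adjacent samples.
    Dark spells shorter than ``min_dark_minutes`` (shading events) and
    light spells shorter than ``min_light_minutes`` (night-time
    artefacts) are merged into their surroundings before events are
    emitted, so each surviving light period yields exactly one sunrise
    and one sunset.  Periods truncated by the series boundary yield only
    the crossing that exists.
    """
    lit = series.light >= threshold
    if lit.all() or not lit.any():
        warnings.warn("threshold never crossed; no twilights found", stacklevel=2)
        return []

    # run-length encode the lit/dark state, then absorb short runs
    change = np.flatnonzero(np.diff(lit.astype(np.int8))) + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [lit.size]])
    states = lit[starts].astype(bool)
    dur_min = (series.times[ends - 1] - series.times[starts]).astype(float) / 60.0

    keep_states: List[bool] = []
    keep_starts: List[int] = []
    keep_ends: List[int] = []
    for s, e, st, d in zip(starts, ends, states, dur_min):
        interior = s > 0 and e < lit.size
        too_short = (not st and d < min_dark_minutes) or (st and d < min_light_minutes)
        if interior and too_short and keep_states:
            keep_ends[-1] = e  # absorb into the previous run
            continue
        if keep_states and keep_states[-1] == st:
            keep_ends[-1] = e
            continue
        keep_states.append(bool(st))
        keep_starts.append(int(s))
        keep_ends.append(int(e))

    events: List[TwilightEvent] = []
    for st, s, e in zip(keep_states, keep_starts, keep_ends):
        if not st:
            continue
        if s > 0:
            events.append(
                TwilightEvent(
                    _interp_crossing(
                        series.times[s - 1], series.times[s],
                        series.light[s - 1], series.light[s], threshold,
                    ),
                    "sunrise",
                )
            )
        if e < lit.size:
            events.append(
                TwilightEvent(
                    _interp_crossing(
                        series.times[e - 1], series.times[e],
                        series.light[e - 1], series.light[e], threshold,
                    ),
                    "sunset",
                )
            )
    events.sort(key=lambda ev: ev.time)
    if check_alternation(events):
        warnings.warn("twilight kinds do not strictly alternate", stacklevel=2)
    return events


# ---------------------------------------------------------------------------
# file dialects

PathLike = Union[str, Path]


def read_light_csv(path: PathLike, logger_id: str = "") -> LightSeries:
    """Canonical light CSV: columns ``time`` (ISO 8601 UTC) and ``light``."""
    df = pd.read_csv(path)
    times = pd.to_datetime(df["time"]).dt.tz_localize(None).to_numpy()
    return LightSeries(times, df["light"].to_numpy(), logger_id=logger_id)


def write_light_csv(series: LightSeries, path: PathLike) -> None:
    df = series.to_frame()
    df["time"] = pd.to_datetime(df["time"]).dt.strftime("%Y-%m-%dT%H:%M:%S")
    df.to_csv(path, index=False)


def read_lig(path: PathLike, logger_id: str = "") -> LightSeries:
    """BAS ``.lig`` dialect: ``status,dd/mm/yy hh:mm:ss,seconds,light`` rows."""
    df = pd.read_csv(path, header=None, names=["status", "datetime", "seconds", "light"])
    times = pd.to_datetime(df["datetime"].str.strip(), format="%d/%m/%y %H:%M:%S").to_numpy()
    return LightSeries(times, df["light"].to_numpy(), logger_id=logger_id)


def write_lig(series: LightSeries, path: PathLike) -> None:
    times = pd.to_datetime(series.times)
    epoch = (times - pd.Timestamp("1970-01-01")) // pd.Timedelta("1s")
    with open(path, "w") as fh:
        for t, s, l in zip(times, epoch, series.light):
            fh.write(f"ok,{t:%d/%m/%y %H:%M:%S},{s},{l:g}\n")


def read_lux(path: PathLike, logger_id: str = "") -> LightSeries:
    """Migrate Tech ``.lux`` dialect: comment header, then tab-separated
    ``dd/mm/yyyy hh:mm:ss<TAB>light`` rows."""
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or not line[0].isdigit():
                continue
            stamp, value = line.split("\t")
            rows.append((stamp, float(value)))
    times = pd.to_datetime([r[0] for r in rows], format="%d/%m/%Y %H:%M:%S").to_numpy()
    return LightSeries(times, np.array([r[1] for r in rows]), logger_id=logger_id)


def read_light(path: PathLike, logger_id: str = "") -> LightSeries:
    """Dispatch on extension: ``.lig``, ``.lux``, else canonical CSV."""
    suffix = Path(path).suffix.lower()
    if suffix == ".lig":
        return read_lig(path, logger_id)
    if suffix == ".lux":
        return read_lux(path, logger_id)
    return read_light_csv(path, logger_id)


def twilights_to_frame(events: Iterable[TwilightEvent]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "time": [ev.time for ev in events],
            "kind": [ev.kind for ev in events],
            "excluded": [ev.excluded for ev in events],
        }
    )


def write_twilights_csv(events: Iterable[TwilightEvent], path: PathLike) -> None:
    df = twilights_to_frame(events)
    df["time"] = pd.to_datetime(df["time"]).dt.strftime("%Y-%m-%dT%H:%M:%S.%f")
    df.to_csv(path, index=False)


def read_twilights_csv(path: PathLike) -> List[TwilightEvent]:
    df = pd.read_csv(path)
    return [
        TwilightEvent(pd.Timestamp(row.time).to_pydatetime(), row.kind, bool(row.excluded))
        for row in df.itertuples()
    ]
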