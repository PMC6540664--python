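"""Packaged reference data: the per-individual migration-history table.

28 Fork-tailed Flycatchers tracked from four South American breeding
sites: 17 austral migrants (RED, RPL; Argentina) and 11 intratropical
migrants (DF, EEI; Brazil).  Durations in days, distances in km, rates
in km/day; individual 3 has no detectable spring arrival, so its
duration and rate are missing.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

_DATE_COLS = ["spring_initiation", "spring_arrival"]


def table1_fixture() -> pd.DataFrame:
    """The per-individual migration-history table as a DataFrame.

    Dates are parsed to ``datetime.date``; missing values are NaN/None.
    Loading is side-effect free and returns a fresh copy each call.
    """
    ref = resources.files("flytrack.data").joinpath("table1.csv")
    with ref.open() as fh:
        df = pd.read_csv(fh)
    for col in _DATE_COLS:
        df[col] = pd.to_datetime(df[col]).dt.date
        df[col] = df[col].where(pd.notna(df[col]), None)
    return df


def day_of_year(dates) -> pd.Series:
    """Day-of-year (Jan 1 = 1) of a date column, NaN-preserving."""
    s = pd.to_datetime(pd.Series(list(dates)))
    return s.dt.dayofyear
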