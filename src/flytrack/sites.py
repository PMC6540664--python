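"""Breeding-site configuration for the four study populations.

Two tropical breeding sites in Brazil (DF, EEI; intratropical migrants)
and two south-temperate sites in Argentina (RED, RPL; austral
migrants).  Census first-arrival dates constrain the earliest
detectable spring arrival at the Argentinian sites, where the breeding
site lies directly south of the migration route and the longitude
criterion alone would fire weeks early.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from typing import Dict, Optional

from .geo import GeoPoint

GROUP_AUSTRAL = "austral"
GROUP_INTRATROPICAL = "intratropical"

#: first-arrival census dates from early-spring transect counts
_CENSUS = {
    2010: dt.date(2010, 10, 10),
    2011: dt.date(2011, 9, 29),
    2014: dt.date(2014, 10, 5),
    2015: dt.date(2015, 10, 12),
}


@dataclass(frozen=True)
class SiteConfig:
    """One breeding site: code, coordinates, migrant group, census floor."""

    code: str
    point: GeoPoint
    group: str  # austral | intratropical
    census: Dict[int, dt.date] = field(default_factory=dict)

    def __post_init__(self):
        if self.group not in (GROUP_AUSTRAL, GROUP_INTRATROPICAL):
            raise ValueError(f"unknown group {self.group!r}")
        for year, d in self.census.items():
            if not (9 <= d.month <= 12):
                raise ValueError(f"census date {d} outside Sep-Dec")

    def census_floor(self, year: int) -> Optional[dt.date]:
        """Earliest admissible arrival date for ``year`` (austral sites only)."""
        if self.group != GROUP_AUSTRAL:
            return None
        return self.census.get(year)


SITES: Dict[str, SiteConfig] = {
    "DF": SiteConfig("DF", GeoPoint(-15.8, -47.8), GROUP_INTRATROPICAL),
    "EEI": SiteConfig("EEI", GeoPoint(-22.3, -47.9), GROUP_INTRATROPICAL),
    "RED": SiteConfig("RED", GeoPoint(-35.1, -57.4), GROUP_AUSTRAL, dict(_CENSUS)),
    "RPL": SiteConfig("RPL", GeoPoint(-36.8, -64.3), GROUP_AUSTRAL, dict(_CENSUS)),
}
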