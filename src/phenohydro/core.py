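"""Shared data containers: sites, daily weather series, flowering records.

Weather lives in a plain pandas DataFrame wrapped with its site metadata;
the wrapper only adds validation and the CSV conventions used across the
package (``date,tmax,tmin,tmean,prcp,rh,wind,sunshine``, ISO dates).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

#: canonical CSV column order (tmean is derived, not serialised)
WEATHER_CSV_COLUMNS = ["date", "tmax", "tmin", "prcp", "rh", "wind", "sunshine"]
WEATHER_COLUMNS = ["date", "tmax", "tmin", "tmean", "prcp", "rh", "wind", "sunshine"]

#: latitude envelope of the study region (degrees north)
LAT_MIN, LAT_MAX = 27.0, 44.0


@dataclass(frozen=True)
class SiteMeta:
    """An observation site: identifier, coordinates, elevation (m)."""

    site_id: str
    latitude: float
    longitude: float
    elevation: float

    def __post_init__(self):
        if not LAT_MIN <= self.latitude <= LAT_MAX:
            raise ValueError(
                f"latitude {self.latitude} outside the study envelope "
                f"[{LAT_MIN}, {LAT_MAX}] degN")
        if self.elevation < 0:
            raise ValueError("elevation must be non-negative")


@dataclass
class WeatherSeries:
    """Contiguous daily meteorology for one site.

    ``data`` columns: date (datetime), tmax, tmin, tmean (degC), prcp (mm),
    rh (%), wind (m/s at ``wind_height``), sunshine (h).
    """

    site: SiteMeta
    data: pd.DataFrame
    wind_height: float = 10.5

    def validate(self) -> "WeatherSeries":
        d = self.data
        missing = [c for c in WEATHER_COLUMNS if c not in d.columns]
        if missing:
            raise ValueError(f"weather table missing columns {missing}")
        dates = pd.to_datetime(d["date"])
        if len(dates) == 0:
            raise ValueError("empty weather series")
        gaps = dates.diff().dropna()
        if not (gaps == pd.Timedelta(days=1)).all():
            raise ValueError("weather dates are not contiguous daily")
        if (d["tmin"] > d["tmean"]).any() or (d["tmean"] > d["tmax"]).any():
            raise ValueError("temperature ordering Tmin <= Tmean <= Tmax violated")
        if (d["prcp"] < 0).any():
            raise ValueError("negative precipitation")
        if ((d["rh"] < 0) | (d["rh"] > 100)).any():
            raise ValueError("relative humidity outside [0, 100]")
        if ((d["sunshine"] < 0) | (d["sunshine"] > 24)).any():
            raise ValueError("sunshine hours outside [0, 24]")
        return self

    @property
    def years(self) -> list[int]:
        return sorted(pd.to_datetime(self.data["date"]).dt.year.unique())

    def year_slice(self, year: int) -> pd.DataFrame:
        dates = pd.to_datetime(self.data["date"])
        return self.data.loc[(dates.dt.year == year).to_numpy()].reset_index(drop=True)

    def to_csv(self, path: str | Path) -> None:
        out = self.data.copy()
        out["date"] = pd.to_datetime(out["date"]).dt.strftime("%Y-%m-%d")
        out[WEATHER_CSV_COLUMNS].to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, site: SiteMeta,
                 wind_height: float = 10.5) -> "WeatherSeries":
        d = pd.read_csv(path, parse_dates=["date"])
        if "tmean" not in d.columns:
            d["tmean"] = (d["tmax"] + d["tmin"]) / 2.0
        return cls(site, d, wind_height).validate()


@dataclass(frozen=True)
class PhenologyObservation:
    """One observed first-flowering date: (site, year, day of year)."""

    site_id: str
    year: int
    doy: int

    def __post_init__(self):
        if not 1 <= self.doy <= 366:
            raise ValueError(f"flowering DOY {self.doy} outside [1, 366]")


def observations_to_csv(obs: list[PhenologyObservation], path: str | Path) -> None:
    pd.DataFrame([(o.site_id, o.year, o.doy) for o in obs],
                 columns=["site_id", "year", "doy"]).to_csv(path, index=False)


def observations_from_csv(path: str | Path) -> list[PhenologyObservation]:
    d = pd.read_csv(path)
    return [PhenologyObservation(str(r.site_id), int(r.year), int(r.doy))
            for r in d.itertuples()]


def sites_to_csv(sites: list[SiteMeta], path: str | Path) -> None:
    pd.DataFrame([(s.site_id, s.latitude, s.longitude, s.elevation) for s in sites],
                 columns=["site_id", "lat", "lon", "elev"]).to_csv(path, index=False)


def sites_from_csv(path: str | Path) -> list[SiteMeta]:
    d = pd.read_csv(path)
    return [SiteMeta(str(r.site_id), float(r.lat), float(r.lon), float(r.elev))
            for r in d.itertuples()]
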