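"""Synthetic daily weather and flowering observations.

The generator produces multi-year site weather with the statistical
structure the downstream analysis assumes for mid-latitude (27-44 degN)
orchard country: a sinusoidal annual temperature cycle with its minimum
in mid-January, Gaussian day-to-day noise, a fixed diurnal range,
Markov-chain wet/dry precipitation with exponential wet-day amounts,
and sunshine bounded by the astronomical daylength.  Flowering
observations are drawn from a known-parameter phenology model plus
rounded Gaussian observation noise, so calibration can be exercised as a
parameter-recovery experiment with a known truth.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import SiteMeta, WeatherSeries, PhenologyObservation
from .et0 import daylength
from .phenology_models import (
    PREDICTORS, AlternatingParams, M1Params, SeasonInputs, UnichillParams,
    UniforcParams, season_from_weather)

logger = logging.getLogger(__name__)

#: day of year of the coldest day (mid-January)
COLDEST_DOY = 15

#: plausible mid-latitude apple parameter sets used as the generating
#: truth in recovery experiments (spring flowering around DOY 95-125
#: under the default site climates)
DEFAULT_TRUE_PARAMS = {
    "m1": M1Params(t1=60.0, threshold=5.0, f_star=110.0, k=0.5),
    "uniforc": UniforcParams(t1=60.0, f_star=35.0, b=-0.5, c=6.0),
    "alternating": AlternatingParams(t1=60.0, threshold=5.0, a=60.0,
                                     b=700.0, c=-0.02),
    "unichill": UnichillParams(t0=30.0, c_star=25.0, f_star=30.0, b_f=-0.3,
                               c_f=12.0, a_c=0.02, b_c=-0.2, c_c=2.0),
}
#: lag-1 persistence of precipitation occurrence
WET_PERSISTENCE = 0.3


@dataclass
class WeatherGenConfig:
    """Knobs of the stochastic weather generator.

    Defaults describe a semi-arid temperate orchard climate: 12 degC
    annual mean with a 14 degC seasonal half-amplitude, ~5 degC extra
    elevation/latitude adjustment handled by the caller, one wet day in
    four with 6 mm mean depth, moderate humidity and wind, and 60% of
    astronomically possible sunshine.
    """

    mean_temp: float = 12.0          # annual mean temperature, degC
    seasonal_amplitude: float = 14.0  # half peak-to-trough, degC
    temp_noise_sd: float = 2.5       # day-to-day Gaussian noise, degC
    diurnal_range: float = 10.0      # Tmax - Tmin, degC
    wet_day_prob: float = 0.25       # annual-mean wet-day probability
    mean_wet_mm: float = 6.0         # mean precipitation on wet days, mm
    summer_precip_amp: float = 0.6   # monsoonal modulation of wet-day odds
    rh_mean: float = 60.0            # daily mean relative humidity, %
    rh_sd: float = 12.0
    wind_mean: float = 2.5           # m/s at ``wind_height``
    sunshine_fraction_mean: float = 0.6
    wind_height: float = 10.5        # anemometer height, m
    seed: int = 0

    def __post_init__(self):
        for name in ("wet_day_prob", "sunshine_fraction_mean"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        for name in ("temp_noise_sd", "rh_sd", "diurnal_range", "mean_wet_mm",
                     "wind_mean"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


def _site_rng(cfg_seed: int, site_id: str) -> np.random.Generator:
    # per-site stream, reproducible across processes (stable site hash)
    site_key = zlib.crc32(site_id.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([cfg_seed, site_key]))


def seasonal_tmean(doy: np.ndarray, year_len: np.ndarray | int,
                   mean: float, amplitude: float) -> np.ndarray:
    """Deterministic sinusoid with its minimum at mid-January."""
    return mean - amplitude * np.cos(
        2.0 * np.pi * (doy - COLDEST_DOY) / np.asarray(year_len, dtype=float))


def generate_weather(site: SiteMeta, years: range,
                     cfg: WeatherGenConfig) -> WeatherSeries:
    """Simulate a contiguous daily series covering the given years.

    Deterministic given (cfg.seed, site.site_id).  Precipitation
    occurrence follows a two-state Markov chain whose stationary wet
    probability equals ``cfg.wet_day_prob``; amounts are exponential.
    Sunshine hours are clipped to the daylength for the site latitude.
    """
    years = list(years)
    if not years:
        raise ValueError("empty year range")
    rng = _site_rng(cfg.seed, site.site_id)

    dates = pd.date_range(f"{years[0]}-01-01", f"{years[-1]}-12-31", freq="D")
    doy = dates.dayofyear.to_numpy()
    year_len = np.where(dates.is_leap_year, 366, 365)
    n = len(dates)

    base = seasonal_tmean(doy, year_len, cfg.mean_temp, cfg.seasonal_amplitude)
    tmean = base + (rng.standard_normal(n) * cfg.temp_noise_sd
                    if cfg.temp_noise_sd > 0 else 0.0)
    tmax = tmean + cfg.diurnal_range / 2.0
    tmin = tmean - cfg.diurnal_range / 2.0

    # two-state Markov chain whose day-varying target probability carries
    # the monsoonal cycle (wettest in mid-July, annual mean = wet_day_prob)
    pi_day = np.clip(cfg.wet_day_prob * (1.0 + cfg.summer_precip_amp * np.cos(
        2.0 * np.pi * (doy - (COLDEST_DOY + 182)) / year_len)), 0.0, 0.98)
    u = rng.random(n)
    wet = np.zeros(n, dtype=bool)
    if cfg.wet_day_prob > 0:
        wet[0] = u[0] < pi_day[0]
        for i in range(1, n):
            p = (pi_day[i] + WET_PERSISTENCE * (1.0 - pi_day[i])
                 if wet[i - 1] else pi_day[i] * (1.0 - WET_PERSISTENCE))
            wet[i] = u[i] < p
    amounts = rng.exponential(cfg.mean_wet_mm, n) if cfg.mean_wet_mm > 0 else \
        np.zeros(n)
    prcp = np.where(wet, amounts, 0.0)

    rh = np.clip(cfg.rh_mean + rng.standard_normal(n) * cfg.rh_sd, 5.0, 100.0)
    wind = np.maximum(
        cfg.wind_mean * (1.0 + 0.4 * rng.standard_normal(n)), 0.05)
    nmax = np.asarray(daylength(site.latitude, doy))
    frac = np.clip(cfg.sunshine_fraction_mean
                   + 0.15 * rng.standard_normal(n), 0.0, 1.0)
    sunshine = frac * nmax

    data = pd.DataFrame({
        "date": dates, "tmax": tmax, "tmin": tmin, "tmean": tmean,
        "prcp": prcp, "rh": rh, "wind": wind, "sunshine": sunshine,
    })
    return WeatherSeries(site, data, cfg.wind_height).validate()


def generate_flowering_obs(weather_by_site: dict[str, WeatherSeries],
                           model_id: str, true_params, noise_sd: float,
                           seed: int,
                           years: range | None = None
                           ) -> list[PhenologyObservation]:
    """Noisy flowering observations from a known-parameter model.

    For every site-year with a full chilling+forcing season, the model's
    predicted DOY plus rounded Gaussian(0, noise_sd) noise becomes one
    observation.  Site-years where the model never meets its requirement
    are dropped with a warning.  Deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed)
    predict = PREDICTORS[model_id]
    obs: list[PhenologyObservation] = []
    for site_id in sorted(weather_by_site):
        weather = weather_by_site[site_id]
        site_years = weather.years
        usable = [y for y in site_years if (y - 1) in site_years]
        if years is not None:
            usable = [y for y in usable if y in years]
        for year in usable:
            season = season_from_weather(weather, year)
            doy = predict(season, true_params)
            if doy is None:
                logger.warning("site %s year %d: model %s never flowers; "
                               "observation dropped", site_id, year, model_id)
                continue
            noisy = doy + (round(float(rng.normal(0.0, noise_sd)))
                           if noise_sd > 0 else 0)
            noisy = int(np.clip(noisy, 1, 366))
            obs.append(PhenologyObservation(site_id, year, noisy))
    return obs


def default_sites(n_sites: int = 6) -> list[SiteMeta]:
    """Evenly spread synthetic sites across the 27-44 degN study belt."""
    lats = np.linspace(30.0, 42.0, n_sites)
    lons = np.linspace(80.0, 120.0, n_sites)
    elevs = np.linspace(100.0, 1400.0, n_sites)
    return [SiteMeta(f"S{i + 1:02d}", float(lat), float(lon), float(el))
            for i, (lat, lon, el) in enumerate(zip(lats, lons, elevs))]


def climate_for_site(site: SiteMeta, seed: int = 0, **overrides
                     ) -> WeatherGenConfig:
    """Latitude/elevation-adjusted generator config for a site.

    Annual mean cools ~0.55 degC per degree of latitude north of 35 and
    0.6 degC per 100 m of elevation; seasonality strengthens northward.
    """
    mean = 14.0 - 0.55 * (site.latitude - 35.0) - 0.006 * site.elevation
    amp = 12.0 + 0.35 * (site.latitude - 35.0)
    cfg = dict(mean_temp=mean, seasonal_amplitude=amp, seed=seed)
    cfg.update(overrides)
    return WeatherGenConfig(**cfg)
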