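"""Chilling/forcing flowering-date models and phenophase windows.

Four classic spring-phenology model structures predict the first-flowering
day of year (DOY) from daily mean temperature:

* **M1** (photothermal time): growing-degree-day forcing weighted by
  relative daylength, Sum (L_i/24)^k * max(T_i - T_b, 0) >= F*.
* **Uniforc**: sigmoidal forcing, Sum 1/(1+exp(b (T_i - c))) >= F* from a
  start day t1; b < 0 so forcing increases with temperature.
* **Alternating**: degree-day forcing against a requirement that relaxes
  exponentially with the number of accumulated chill days (days with
  T below the shared threshold), F_req = a + b exp(c * CD).
* **Unichill**: sequential chilling then forcing; a bell-shaped chilling
  response accumulates from an autumn start t0 until C*, after which a
  sigmoidal forcing response accumulates until F*.

Daily mean temperature (Tmax+Tmin)/2 drives every response function.
Chilling (Alternating chill days, Unichill chilling) is counted from
September 1 of the preceding year, the customary start of the dormancy
season in northern-hemisphere versions of these models; Unichill's t0 is
expressed as a day offset from September 1 (t0 = 1 is September 1).

Predictions that never meet their requirement return ``None``; the
calibration module maps that to a penalised pseudo-prediction.

A vectorised batch path (:func:`predict_batch`) evaluates one parameter
vector over many site-years at once; the per-series functions are thin
wrappers around it, so there is a single numerical code path.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, asdict, fields
from typing import Sequence

import numpy as np
import pandas as pd

from .core import SiteMeta, WeatherSeries
from .et0 import daylength

logger = logging.getLogger(__name__)

#: days from Sep 1 to Dec 31 (fixed: Sep..Dec contain no leap day)
CHILL_LEAD_DAYS = 122
#: padded window length: lead + longest year
SEASON_LEN = CHILL_LEAD_DAYS + 366

#: national-average phenophase durations (days): flowering-fruit setting,
#: fruit expansion, coloring-maturity
DEFAULT_STAGE_DURATIONS = (22, 102, 39)

STAGE_NAMES = ("flowering_fruit_set", "fruit_expansion", "coloring_maturity")


# ---------------------------------------------------------------------------
# response functions
# ---------------------------------------------------------------------------

def _expit_neg(x):
    """1/(1+exp(x)) with overflow saturated to 0/1.

    The exponent is clipped at |x| = 80: exp(80) stays finite in single
    precision and the logistic is already 0/1 to ~35 digits there.
    """
    return 1.0 / (1.0 + np.exp(np.clip(x, -80.0, 80.0)))


def forcing_gdd(T, threshold):
    """Growing-degree-day forcing rate max(T - threshold, 0), units/day."""
    return np.maximum(np.asarray(T, dtype=float) - threshold, 0.0)


def forcing_sigmoid(T, b, c):
    """Sigmoidal forcing rate 1/(1+exp(b (T - c))) in [0, 1].

    With b < 0 the rate increases with temperature and crosses 0.5 at c.
    """
    return _expit_neg(b * (np.asarray(T, dtype=float) - c))


def chilling_response(T, a_c, b_c, c_c):
    """Bell-shaped chilling rate 1/(1+exp(a_c dT^2 + b_c dT)), dT = T - c_c.

    For a_c > 0 the rate peaks near the optimum c_c and decays toward
    both hot and freezing temperatures.
    """
    dT = np.asarray(T, dtype=float) - c_c
    return _expit_neg(a_c * dT * dT + b_c * dT)


# ---------------------------------------------------------------------------
# model parameters
# ---------------------------------------------------------------------------

@dataclass
class M1Params:
    t1: float          # DOY forcing starts
    threshold: float   # base temperature T_b, degC
    f_star: float      # total forcing required
    k: float           # daylength exponent; k = 0 is plain thermal time

    def __post_init__(self):
        if self.f_star <= 0:
            raise ValueError("f_star must be positive")


@dataclass
class UniforcParams:
    t1: float
    f_star: float
    b: float           # sigmoid slope, negative
    c: float           # sigmoid midpoint, degC

    def __post_init__(self):
        if self.f_star <= 0:
            raise ValueError("f_star must be positive")


@dataclass
class AlternatingParams:
    t1: float
    threshold: float   # forcing above / chill-day counting below
    a: float           # chill-day curve intercept
    b: float           # chill-day curve slope (> 0)
    c: float           # chill-day curve scale (< 0)


@dataclass
class UnichillParams:
    t0: float          # chilling start, day offset from Sep 1 (1 = Sep 1)
    c_star: float      # total chilling required
    f_star: float      # total forcing required
    b_f: float         # forcing sigmoid slope, negative
    c_f: float         # forcing sigmoid midpoint, degC
    a_c: float         # chilling bell curvature (> 0)
    b_c: float         # chilling bell skew
    c_c: float         # chilling optimum temperature, degC

    def __post_init__(self):
        if self.c_star < 0 or self.f_star <= 0:
            raise ValueError("c_star must be >= 0 and f_star > 0")


MODEL_PARAM_CLASSES = {
    "m1": M1Params,
    "uniforc": UniforcParams,
    "alternating": AlternatingParams,
    "unichill": UnichillParams,
}

MODEL_IDS = tuple(MODEL_PARAM_CLASSES)


def param_names(model_id: str) -> tuple[str, ...]:
    return tuple(f.name for f in fields(MODEL_PARAM_CLASSES[model_id]))


def params_to_dict(params) -> dict:
    return asdict(params)


def params_from_dict(model_id: str, d: dict):
    return MODEL_PARAM_CLASSES[model_id](**d)


# ---------------------------------------------------------------------------
# season inputs
# ---------------------------------------------------------------------------

@dataclass
class SeasonInputs:
    """Daily mean temperature from Sep 1 of the preceding year through
    Dec 31 of the target year, plus the site latitude for daylength."""

    tmean: np.ndarray
    latitude: float
    year: int

    @property
    def ndays_year(self) -> int:
        return len(self.tmean) - CHILL_LEAD_DAYS


def season_from_weather(weather: WeatherSeries, year: int) -> SeasonInputs:
    """Extract the chilling+forcing season for ``year`` from a series."""
    dates = pd.to_datetime(weather.data["date"])
    start = pd.Timestamp(year - 1, 9, 1)
    end = pd.Timestamp(year, 12, 31)
    mask = (dates >= start) & (dates <= end)
    sub = weather.data.loc[mask.to_numpy()]
    ndays = (end - start).days + 1
    if len(sub) != ndays:
        raise ValueError(
            f"site {weather.site.site_id}: weather does not cover "
            f"{start.date()}..{end.date()} ({len(sub)} of {ndays} days)")
    return SeasonInputs(sub["tmean"].to_numpy(float), weather.site.latitude, year)


class SeasonMatrix:
    """A stack of seasons padded to a common width for batch prediction.

    ``dtype`` lets the calibration hot loop trade the last few digits for
    speed (float32); prediction APIs default to float64.
    """

    def __init__(self, seasons: Sequence[SeasonInputs], dtype=np.float64):
        n = len(seasons)
        self.n = n
        self.tmean = np.full((n, SEASON_LEN), np.nan)
        self.ndays = np.empty(n, dtype=int)
        self.latitudes = np.empty(n)
        self.years = np.empty(n, dtype=int)
        for i, s in enumerate(seasons):
            m = len(s.tmean)
            self.tmean[i, :m] = s.tmean
            self.ndays[i] = s.ndays_year
            self.latitudes[i] = s.latitude
            self.years[i] = s.year
        self.valid = ~np.isnan(self.tmean)
        self.valid_f = self.valid.astype(dtype)
        self.tmean_filled = np.where(self.valid, self.tmean, 0.0).astype(dtype)
        # relative daylength (L/24) for the target year, by row latitude
        doys = np.arange(1, 367)
        self._rel_daylength = np.vstack([
            np.asarray(daylength(lat, doys)) / 24.0
            for lat in self.latitudes]).astype(dtype)
        # day validity within the target year
        self.year_valid = self.valid[:, CHILL_LEAD_DAYS:]
        self.year_valid_f = self.valid_f[:, CHILL_LEAD_DAYS:]

    @property
    def rel_daylength(self) -> np.ndarray:
        return self._rel_daylength


def _start_index(t: float) -> int:
    """0-based index of the first day with 1-based day number >= t."""
    return max(int(math.ceil(t)) - 1, 0)


def _first_reach(acc: np.ndarray, need: np.ndarray, valid: np.ndarray) -> np.ndarray:
    """Per row, first valid column where acc >= need; -1 if never."""
    met = (acc >= need) & valid
    idx = met.argmax(axis=1)
    idx[~met.any(axis=1)] = -1
    return idx


def predict_batch(model_id: str, params, sm: SeasonMatrix) -> np.ndarray:
    """Flowering DOY for every season in ``sm``; NaN where unreached."""
    doy = np.full(sm.n, np.nan)
    t_year = sm.tmean_filled[:, CHILL_LEAD_DAYS:]
    yv = sm.year_valid

    if model_id in ("m1", "uniforc"):
        s = _start_index(params.t1)
        if model_id == "m1":
            rates = np.maximum(t_year - params.threshold, 0.0) * \
                sm.rel_daylength ** params.k
        else:
            rates = _expit_neg(params.b * (t_year - params.c))
        rates *= sm.year_valid_f
        rates[:, :s] = 0.0
        acc = np.cumsum(rates, axis=1)
        ok = yv.copy()
        ok[:, :s] = False
        idx = _first_reach(acc, params.f_star, ok)
        hit = idx >= 0
        doy[hit] = idx[hit] + 1
        return doy

    if model_id == "alternating":
        s = _start_index(params.t1)
        chill = (sm.tmean_filled < params.threshold) & sm.valid
        cd_full = np.cumsum(chill, axis=1)
        cd_year = cd_full[:, CHILL_LEAD_DAYS:]
        need = params.a + params.b * np.exp(
            np.clip(params.c * cd_year, -500.0, 500.0))
        rates = np.maximum(t_year - params.threshold, 0.0) * sm.year_valid_f
        rates[:, :s] = 0.0
        acc = np.cumsum(rates, axis=1)
        ok = yv.copy()
        ok[:, :s] = False
        idx = _first_reach(acc, need, ok)
        hit = idx >= 0
        doy[hit] = idx[hit] + 1
        return doy

    if model_id == "unichill":
        s0 = _start_index(params.t0)
        dT = sm.tmean_filled - params.c_c
        rc = _expit_neg(params.a_c * dT * dT + params.b_c * dT) * sm.valid_f
        rc[:, :s0] = 0.0
        acc_c = np.cumsum(rc, axis=1)
        if params.c_star > 0:
            ok_c = sm.valid.copy()
            ok_c[:, :s0] = False
            t_c = _first_reach(acc_c, params.c_star, ok_c)
            chilled = t_c >= 0
        else:
            # no chilling requirement: forcing starts at t0 itself
            t_c = np.full(sm.n, s0 - 1)
            chilled = np.ones(sm.n, dtype=bool)
        rf = _expit_neg(params.b_f * (sm.tmean_filled - params.c_f)) * sm.valid_f
        acc_f = np.cumsum(rf, axis=1)
        cols = np.arange(SEASON_LEN)[None, :]
        base = np.where(t_c >= 0,
                        acc_f[np.arange(sm.n), np.maximum(t_c, 0)], 0.0)
        met = ((acc_f >= base[:, None] + params.f_star) & sm.valid
               & (cols > t_c[:, None]) & chilled[:, None])
        idx = met.argmax(axis=1)
        hit = met.any(axis=1) & (idx >= CHILL_LEAD_DAYS)
        doy[hit] = idx[hit] - CHILL_LEAD_DAYS + 1
        return doy

    raise ValueError(f"unknown model id {model_id!r}")


def _predict_one(model_id: str, season: SeasonInputs, params) -> int | None:
    out = predict_batch(model_id, params, SeasonMatrix([season]))[0]
    return None if np.isnan(out) else int(out)


def predict_m1(season: SeasonInputs, params: M1Params) -> int | None:
    """Photothermal-time flowering DOY, or None if F* is never reached."""
    return _predict_one("m1", season, params)


def predict_uniforc(season: SeasonInputs, params: UniforcParams) -> int | None:
    return _predict_one("uniforc", season, params)


def predict_alternating(season: SeasonInputs, params: AlternatingParams) -> int | None:
    return _predict_one("alternating", season, params)


def predict_unichill(season: SeasonInputs, params: UnichillParams) -> int | None:
    return _predict_one("unichill", season, params)


PREDICTORS = {
    "m1": predict_m1,
    "uniforc": predict_uniforc,
    "alternating": predict_alternating,
    "unichill": predict_unichill,
}


# ---------------------------------------------------------------------------
# ensemble
# ---------------------------------------------------------------------------

@dataclass
class EnsembleWeights:
    """Inverse-validation-RMSE weights over the member models."""

    weights: dict[str, float]
    rmse: dict[str, float]

    def __post_init__(self):
        total = sum(self.weights.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"weights sum to {total}, expected 1")
        if any(w <= 0 for w in self.weights.values()):
            raise ValueError("all weights must be positive")
        # better (smaller) validation error must get the larger weight
        order_w = sorted(self.weights, key=self.weights.get, reverse=True)
        order_r = sorted(self.rmse, key=self.rmse.get)
        if order_w != order_r:
            raise ValueError("weight order must be the reverse of RMSE order")


def round_half_away(x: float) -> int:
    """Round to nearest integer, halves away from zero."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def predict_ensemble(predictions: dict[str, int | None],
                     weights: EnsembleWeights) -> int | None:
    """Weighted-mean flowering DOY across member models, rounded.

    Members that failed to predict are dropped and the remaining weights
    renormalised (with a warning); None only if every member failed.
    """
    avail = {m: d for m, d in predictions.items() if d is not None}
    if not avail:
        logger.warning("ensemble: no member produced a prediction")
        return None
    if len(avail) < len(predictions):
        missing = sorted(set(predictions) - set(avail))
        logger.warning("ensemble: members %s failed; renormalising", missing)
    wsum = sum(weights.weights[m] for m in avail)
    mean = sum(weights.weights[m] * d for m, d in avail.items()) / wsum
    return round_half_away(mean)


# ---------------------------------------------------------------------------
# phenophase windows
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StageWindows:
    """Phenophase boundary days (DOY, one calendar year).

    flowering..fruit_set spans flowering-fruit setting; fruit expansion
    starts the day after fruit set and ends at expansion_end; coloring-
    maturity starts the day after that and ends at maturity.
    """

    flowering: int
    fruit_set: int
    expansion_end: int
    maturity: int

    def __post_init__(self):
        if not (self.flowering < self.fruit_set < self.expansion_end
                < self.maturity):
            raise ValueError("stage boundaries must be strictly increasing")
        if self.flowering < 1 or self.maturity > 366:
            raise ValueError("stage windows leave the calendar year")

    def spans(self) -> dict[str, tuple[int, int]]:
        """Inclusive (start, end) DOY span per stage."""
        return {
            "flowering_fruit_set": (self.flowering, self.fruit_set),
            "fruit_expansion": (self.fruit_set + 1, self.expansion_end),
            "coloring_maturity": (self.expansion_end + 1, self.maturity),
        }


def derive_stage_windows(flowering: int,
                         durations: tuple[int, int, int] = DEFAULT_STAGE_DURATIONS
                         ) -> StageWindows:
    """Chain the three phenophases onto a flowering date.

    Fruit set falls ``durations[0]`` days after flowering (a flowering
    date of April 3 with a 30-day stage puts fruit set on May 3); the
    expansion and coloring stages follow back-to-back with the remaining
    two durations.
    """
    if flowering < 1:
        raise ValueError("flowering DOY must be >= 1")
    d1, d2, d3 = durations
    if min(d1, d2, d3) <= 0:
        raise ValueError("stage durations must be positive")
    fruit_set = flowering + d1
    expansion_end = fruit_set + d2
    maturity = expansion_end + d3
    if maturity > 366:
        raise ValueError(
            f"growing season overruns the calendar year (maturity DOY {maturity})")
    return StageWindows(flowering, fruit_set, expansion_end, maturity)
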