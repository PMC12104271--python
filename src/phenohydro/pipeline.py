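"""End-to-end orchestration: calendar utilities, per-site runs, summaries.

``run_assessment`` walks every configured site-year: ensemble flowering
date -> phenophase windows -> Kc curve -> daily ET0 -> the three
per-stage water assessments.  ``summarize`` aggregates the records into
multi-year site means, grand means across sites, and frequency
histograms of the site means (echoing the usual reporting of county-
scale water requirement bands).

Averaging order: within each site over its years first, then across
sites — the two differ on unbalanced panels, so the order is fixed here.
"""

from __future__ import annotations

import datetime as dt
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .calibration import ensemble_weights
from .core import WeatherSeries
from .et0 import compute_et0
from .phenology_models import (
    DEFAULT_STAGE_DURATIONS, PREDICTORS, EnsembleWeights, derive_stage_windows,
    predict_ensemble, season_from_weather)
from .water_balance import KcAnchors, WaterAssessment, assess, build_kc_curve

logger = logging.getLogger(__name__)

RECORD_COLUMNS = ["site_id", "year", "stage", "wr_mm", "peff_mm", "iwr_mm",
                  "s", "suitability_class"]


# ---------------------------------------------------------------------------
# calendar utilities
# ---------------------------------------------------------------------------

def date_to_doy(date: dt.date) -> int:
    """1-based day of year of a calendar date (leap-aware)."""
    return date.timetuple().tm_yday


def doy_to_date(year: int, doy: int) -> dt.date:
    """Inverse of :func:`date_to_doy` within one year."""
    days_in_year = 366 if _is_leap(year) else 365
    if not 1 <= doy <= days_in_year:
        raise ValueError(f"DOY {doy} outside [1, {days_in_year}] for {year}")
    return dt.date(year, 1, 1) + dt.timedelta(days=doy - 1)


def _is_leap(year: int) -> bool:
    return year % 4 == 0 and (year % 100 != 0 or year % 400 == 0)


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Everything a full assessment run needs besides the weather itself."""

    model_params: dict[str, object]          # model_id -> fitted params
    weights: EnsembleWeights
    years: list[int] | None = None           # None: every year with a season
    stage_durations: tuple[int, int, int] = DEFAULT_STAGE_DURATIONS
    kc_anchors: KcAnchors = field(default_factory=KcAnchors)
    kc_late_decline: bool = False
    strict_printed: bool = False
    delta_variant: str = "cos"
    wr_bin_mm: float = 20.0
    s_bin: float = 0.2


def run_assessment(weather_by_site: dict[str, WeatherSeries],
                   cfg: RunConfig) -> pd.DataFrame:
    """Per (site, year, stage) water assessment records as a DataFrame.

    A site-year without a full chilling+forcing weather season, or where
    no member model flowers, or whose growing season would overrun the
    calendar year, is skipped with a warning — never imputed.
    """
    records: list[WaterAssessment] = []
    for site_id in sorted(weather_by_site):
        weather = weather_by_site[site_id]
        site_years = weather.years
        candidates = [y for y in site_years if (y - 1) in site_years]
        if cfg.years is not None:
            candidates = [y for y in candidates if y in cfg.years]
        et0_table = compute_et0(
            weather.data, weather.site.latitude, weather.site.elevation,
            wind_height=weather.wind_height, strict_printed=cfg.strict_printed,
            delta_variant=cfg.delta_variant)
        et0_years = pd.to_datetime(et0_table["date"]).dt.year.to_numpy()
        for year in candidates:
            season = season_from_weather(weather, year)
            member = {m: PREDICTORS[m](season, p)
                      for m, p in cfg.model_params.items()}
            flowering = predict_ensemble(member, cfg.weights)
            if flowering is None:
                logger.warning("site %s year %d: no model flowered; skipped",
                               site_id, year)
                continue
            try:
                windows = derive_stage_windows(flowering, cfg.stage_durations)
            except ValueError as exc:
                logger.warning("site %s year %d: %s; skipped",
                               site_id, year, exc)
                continue
            kc = build_kc_curve(windows, cfg.kc_anchors,
                                late_decline=cfg.kc_late_decline)
            in_year = et0_table.loc[et0_years == year]
            et0_by_doy = pd.Series(in_year["et0"].to_numpy(),
                                   index=in_year["doy"].to_numpy())
            prcp_by_doy = pd.Series(in_year["prcp"].to_numpy(),
                                    index=in_year["doy"].to_numpy())
            records.extend(assess(site_id, year, et0_by_doy, prcp_by_doy,
                                  windows, kc))
    return pd.DataFrame(
        [(r.site_id, r.year, r.stage, r.wr_mm, r.peff_mm, r.iwr_mm, r.s,
          r.suitability_class) for r in records],
        columns=RECORD_COLUMNS)


# ---------------------------------------------------------------------------
# aggregation
# ---------------------------------------------------------------------------

@dataclass
class SummaryTable:
    """Multi-year site means, grand means, and site-mean histograms."""

    site_means: pd.DataFrame       # per (site_id, stage) mean WR/Peff/IWR/S
    stage_means: pd.DataFrame      # per stage, means across sites
    histograms: dict[str, dict[str, tuple[np.ndarray, np.ndarray]]]
    # histograms[stage][quantity] = (bin_edges, counts)


def _edges(vals: np.ndarray, width: float) -> np.ndarray:
    lo = np.floor(vals.min() / width) * width
    hi = np.ceil(vals.max() / width) * width
    if hi <= lo:
        hi = lo + width
    return np.arange(lo, hi + width / 2, width)


def summarize(records: pd.DataFrame, wr_bin_mm: float = 20.0,
              s_bin: float = 0.2) -> SummaryTable:
    """Aggregate assessment records into the reporting summary.

    Site means are taken over each site's years first; stage-level grand
    means average those site means.  Histograms are equal-width and
    right-open over the site means of WR, IWR and S per stage.
    """
    if records.empty:
        raise ValueError("no assessment records to summarise")
    if wr_bin_mm <= 0 or s_bin <= 0:
        raise ValueError("histogram bin widths must be positive")
    value_cols = ["wr_mm", "peff_mm", "iwr_mm", "s"]
    site_means = (records.groupby(["site_id", "stage"], as_index=False)
                  [value_cols].mean())
    stage_means = site_means.groupby("stage", as_index=False)[value_cols].mean()

    histograms: dict[str, dict[str, tuple[np.ndarray, np.ndarray]]] = {}
    for stage, group in site_means.groupby("stage"):
        per_stage = {}
        for col, width in (("wr_mm", wr_bin_mm), ("iwr_mm", wr_bin_mm),
                           ("s", s_bin)):
            vals = group[col].to_numpy(float)
            edges = _edges(vals, width)
            counts, edges = np.histogram(vals, bins=edges)
            per_stage[col] = (edges, counts)
        histograms[str(stage)] = per_stage
    return SummaryTable(site_means, stage_means, histograms)


def member_predictions(weather_by_site: dict[str, WeatherSeries],
                       model_params: dict[str, object],
                       years: list[int] | None = None) -> pd.DataFrame:
    """Per-model flowering DOY for every usable site-year.

    Columns ``site_id,year,model,doy``; site-years a model cannot bring
    to flowering are omitted for that model.
    """
    rows = []
    for site_id in sorted(weather_by_site):
        weather = weather_by_site[site_id]
        site_years = weather.years
        usable = [y for y in site_years if (y - 1) in site_years]
        if years is not None:
            usable = [y for y in usable if y in years]
        for year in usable:
            season = season_from_weather(weather, year)
            for model, params in model_params.items():
                doy = PREDICTORS[model](season, params)
                if doy is not None:
                    rows.append((site_id, year, model, doy))
    return pd.DataFrame(rows, columns=["site_id", "year", "model", "doy"])


def weights_from_reports(reports: dict[str, "object"]) -> EnsembleWeights:
    """Ensemble weights from per-model fit reports (validation RMSE)."""
    rmses = {m: rep.rmse_v for m, rep in reports.items()}
    if any(r is None for r in rmses.values()):
        raise ValueError("every fit report needs a validation RMSE")
    return ensemble_weights(rmses)
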