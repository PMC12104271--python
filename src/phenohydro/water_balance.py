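"""Crop-coefficient curve, water requirement, irrigation need, suitability.

The crop coefficient Kc converts reference evapotranspiration into crop
evapotranspiration.  For apple the curve starts the pre-season at 0.33,
rises to 0.45 just before flowering, jumps to 0.75 at flowering onset,
ramps to the 0.95 mid-season plateau by fruit set, holds 0.95 through
fruit expansion and (by default) through coloring-maturity, and relaxes
back to the 0.33 dormant value after maturity.  An optional late-season
linear decline across coloring-maturity is available via
``late_decline=True``.

Stage water requirement WR_j = sum over the stage of Kc(i) * ET0(i);
effective precipitation follows the USDA-SCS piecewise daily formula;
irrigation water requirement IWR_j = max(WR_j - Peff_j, 0); suitability
S_j = Peff_j / WR_j is classified into six bands from "Worst
suitability" (S < 0.4) to "Excessive moisture" (S >= 2.0).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .phenology_models import STAGE_NAMES, StageWindows

#: suitability classification bands, upper-exclusive except the last
SUITABILITY_LEVELS = (
    (2.0, float("inf"), "Excessive moisture"),
    (1.0, 2.0, "High suitability"),
    (0.7, 1.0, "Good suitability"),
    (0.5, 0.7, "Suitability"),
    (0.4, 0.5, "Not suitability"),
    (float("-inf"), 0.4, "Worst suitability"),
)

#: daily precipitation breakpoint (mm) of the USDA-SCS formula
PEFF_BREAK_MM = 8.2


@dataclass
class KcAnchors:
    """Named anchor values of the apple Kc trajectory."""

    k_dormant: float = 0.33
    k_early_end: float = 0.45
    k_flower: float = 0.75
    k_mid: float = 0.95
    k_late_end: float = 0.75   # only used when late_decline is enabled

    def __post_init__(self):
        for name in ("k_dormant", "k_early_end", "k_flower", "k_mid",
                     "k_late_end"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.5:
                raise ValueError(f"Kc anchor {name}={v} outside (0, 1.5]")


@dataclass
class KcCurve:
    """Daily crop-coefficient curve tied to one year's stage windows.

    ``early_season_days`` sets how long before flowering the 0.33->0.45
    green-up ramp runs; ``post_decline_days`` how long after maturity the
    curve relaxes back to the dormant value.
    """

    windows: StageWindows
    anchors: KcAnchors = field(default_factory=KcAnchors)
    early_season_days: int = 60
    post_decline_days: int = 30
    late_decline: bool = False

    def values(self, doys) -> np.ndarray:
        """Kc evaluated at integer days of year (vectorised)."""
        d = np.asarray(doys, dtype=float)
        w, a = self.windows, self.anchors
        early_start = w.flowering - self.early_season_days
        out = np.full(d.shape, a.k_dormant)

        # pre-season green-up: k_dormant -> k_early_end, ending the day
        # before flowering
        m = (d >= early_start) & (d < w.flowering)
        if self.early_season_days > 1:
            frac = (d - early_start) / (self.early_season_days - 1)
            out = np.where(m, a.k_dormant
                           + np.clip(frac, 0, 1) * (a.k_early_end - a.k_dormant),
                           out)
        else:
            out = np.where(m, a.k_early_end, out)

        # flowering-fruit setting: k_flower ramping to k_mid at fruit set
        m = (d >= w.flowering) & (d <= w.fruit_set)
        span = max(w.fruit_set - w.flowering, 1)
        out = np.where(m, a.k_flower + (d - w.flowering) / span
                       * (a.k_mid - a.k_flower), out)

        # fruit expansion plateau
        m = (d > w.fruit_set) & (d <= w.expansion_end)
        out = np.where(m, a.k_mid, out)

        # coloring-maturity: hold the plateau, or decline if configured
        m = (d > w.expansion_end) & (d <= w.maturity)
        if self.late_decline:
            span = max(w.maturity - w.expansion_end, 1)
            out = np.where(m, a.k_mid + (d - w.expansion_end) / span
                           * (a.k_late_end - a.k_mid), out)
            k_at_maturity = a.k_late_end
        else:
            out = np.where(m, a.k_mid, out)
            k_at_maturity = a.k_mid

        # post-maturity relaxation back to dormancy
        m = (d > w.maturity) & (d <= w.maturity + self.post_decline_days)
        out = np.where(m, k_at_maturity + (d - w.maturity)
                       / self.post_decline_days
                       * (a.k_dormant - k_at_maturity), out)
        return out

    def __call__(self, doy: int) -> float:
        return float(self.values(np.array([doy]))[0])


def build_kc_curve(windows: StageWindows,
                   anchors: KcAnchors | None = None, **kwargs) -> KcCurve:
    """Construct the daily Kc curve for one year's phenophase windows."""
    return KcCurve(windows, anchors or KcAnchors(), **kwargs)


# ---------------------------------------------------------------------------
# water accounting
# ---------------------------------------------------------------------------

def stage_water_requirement(et0_by_doy: pd.Series | dict, kc: KcCurve,
                            span: tuple[int, int]) -> float:
    """WR over an inclusive DOY span: sum of Kc(i) * ET0(i), mm."""
    start, end = span
    doys = np.arange(start, end + 1)
    series = pd.Series(et0_by_doy)
    missing = [int(d) for d in doys if d not in series.index]
    if missing:
        raise ValueError(f"ET0 missing for days {missing[:5]}"
                         + ("..." if len(missing) > 5 else ""))
    et0 = series.loc[doys].to_numpy(float)
    return float(np.sum(kc.values(doys) * et0))


def effective_precip_day(p: float | np.ndarray) -> float | np.ndarray:
    """USDA-SCS daily effective precipitation (mm).

    Peff = P (4.17 - 0.2 P) / 4.17 for P < 8.2 mm, else 4.17 + 0.1 P.
    The two pieces meet within ~0.015 mm at the breakpoint.
    """
    p_arr = np.asarray(p, dtype=float)
    if np.any(p_arr < 0):
        raise ValueError("negative precipitation")
    low = p_arr * (4.17 - 0.2 * p_arr) / 4.17
    high = 4.17 + 0.1 * p_arr
    out = np.where(p_arr < PEFF_BREAK_MM, low, high)
    return float(out) if np.isscalar(p) or out.ndim == 0 else out


def stage_effective_precip(prcp_by_doy: pd.Series | dict,
                           span: tuple[int, int]) -> float:
    """Cumulative daily effective precipitation over an inclusive span."""
    start, end = span
    doys = np.arange(start, end + 1)
    series = pd.Series(prcp_by_doy)
    missing = [int(d) for d in doys if d not in series.index]
    if missing:
        raise ValueError(f"precipitation missing for days {missing[:5]}")
    return float(np.sum(effective_precip_day(series.loc[doys].to_numpy(float))))


def irrigation_requirement(wr: float, p_eff: float) -> float:
    """IWR = WR - Peff when the requirement exceeds supply, else 0."""
    return wr - p_eff if wr > p_eff else 0.0


def suitability(wr: float, p_eff: float) -> float:
    """Water suitability S = Peff / WR (requires WR > 0)."""
    if wr <= 0:
        raise ValueError("water requirement must be positive for suitability")
    return p_eff / wr


def classify_suitability(s: float) -> str:
    """Map a suitability value onto the six-band label scheme."""
    for lo, hi, label in SUITABILITY_LEVELS:
        if lo <= s < hi or (hi == float("inf") and s >= lo):
            return label
    raise AssertionError("unreachable: bands cover the real line")


@dataclass(frozen=True)
class WaterAssessment:
    """Water balance of one site, year and phenophase."""

    site_id: str
    year: int
    stage: str
    wr_mm: float
    peff_mm: float
    iwr_mm: float
    s: float
    suitability_class: str


def assess(site_id: str, year: int, et0_by_doy: pd.Series | dict,
           prcp_by_doy: pd.Series | dict, windows: StageWindows,
           kc: KcCurve | None = None) -> list[WaterAssessment]:
    """Three per-stage water assessments for one site-year."""
    kc = kc or build_kc_curve(windows)
    records = []
    for stage in STAGE_NAMES:
        span = windows.spans()[stage]
        wr = stage_water_requirement(et0_by_doy, kc, span)
        p_eff = stage_effective_precip(prcp_by_doy, span)
        iwr = irrigation_requirement(wr, p_eff)
        s = suitability(wr, p_eff)
        records.append(WaterAssessment(site_id, year, stage, wr, p_eff, iwr,
                                       s, classify_suitability(s)))
    return records
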