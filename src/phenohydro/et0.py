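"""Daily FAO-56 Penman-Monteith reference evapotranspiration.

Every intermediate quantity (vapour pressures, psychrometric constant,
solar geometry, radiation terms) is exposed so that each step can be
tested in isolation and the full stack can be audited against the
published parameterisation.

Two deliberate corrections are applied by default (both can be switched
off with ``strict_printed=True`` for audit purposes):

* the slope of the saturation vapour-pressure curve is computed from
  ``e(Tmean)``, not from the actual vapour pressure ``e_a`` — the latter
  would make the slope depend on humidity, which contradicts its
  definition;
* net longwave radiation uses ``sqrt(e_a)`` in the emissivity term, the
  standard FAO-56 form (the constant 2.45e-9 = sigma/2 together with the
  sum of the two fourth powers identifies the formula as the FAO one).

The solar declination defaults to the cosine approximation
``delta = -0.4093 cos(2 pi J / 365)``; the FAO-56 sine form is available
via ``delta_variant="fao"`` (the two differ by < 0.02 rad).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, fields

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: solar constant in MJ m-2 min-1
GSC = 0.082
#: default anemometer height (m); the station standard assumed throughout
DEFAULT_WIND_HEIGHT = 10.5


# ---------------------------------------------------------------------------
# thermodynamic helpers
# ---------------------------------------------------------------------------

def saturation_vp(T):
    """Saturation vapour pressure e(T) in kPa (Tetens / FAO-56 form)."""
    T = np.asarray(T, dtype=float)
    return 0.6108 * np.exp(17.27 * T / (T + 237.3))


def vapor_pressures(tmax, tmin, rh):
    """Mean saturation (e_s) and actual (e_a) vapour pressure, kPa.

    e_s averages the saturation pressures at the daily extremes;
    e_a = RH/100 * e_s with RH the daily mean relative humidity.
    """
    e_s = (saturation_vp(tmax) + saturation_vp(tmin)) / 2.0
    e_a = np.asarray(rh, dtype=float) / 100.0 * e_s
    return e_s, e_a


def slope_delta(tmean, *, strict_printed=False, e_a=None):
    """Slope of the saturation vapour-pressure curve, kPa/degC.

    Default: 4098 * e(Tmean) / (Tmean + 237.3)^2.  In strict-printed
    mode the numerator uses the actual vapour pressure ``e_a`` instead
    (an audit mode reproducing a humidity-dependent variant).
    """
    tmean = np.asarray(tmean, dtype=float)
    if strict_printed:
        if e_a is None:
            raise ValueError("strict_printed slope requires e_a")
        num = 4098.0 * np.asarray(e_a, dtype=float)
    else:
        num = 4098.0 * saturation_vp(tmean)
    return num / (tmean + 237.3) ** 2


def atm_pressure(z):
    """Atmospheric pressure (kPa) at elevation z (m)."""
    z = np.asarray(z, dtype=float)
    return 101.3 * ((293.0 - 0.0065 * z) / 293.0) ** 5.26


def latent_heat(tmean):
    """Latent heat of vaporisation, MJ/kg."""
    return 2.501 - 2.361e-3 * np.asarray(tmean, dtype=float)


def psychrometric(p_atm, lam):
    """Psychrometric constant gamma = 0.00163 P / lambda, kPa/degC."""
    return 0.00163 * np.asarray(p_atm, dtype=float) / np.asarray(lam, dtype=float)


def wind_2m(u_meas, z_h=DEFAULT_WIND_HEIGHT):
    """Wind speed adjusted to 2 m via the logarithmic profile.

    u2 = u_h * 4.87 / ln(67.8 z_h - 5.42).  At the 10.5 m station height
    the factor is 0.7424 (commonly rounded to 0.743); at 2 m it is 1.
    """
    if z_h <= 5.42 / 67.8:
        raise ValueError(f"measurement height {z_h} m below profile validity")
    return np.asarray(u_meas, dtype=float) * 4.87 / math.log(67.8 * z_h - 5.42)


# ---------------------------------------------------------------------------
# solar geometry
# ---------------------------------------------------------------------------

def solar_declination(doy, variant="cos"):
    """Solar declination (rad).

    variant="cos": -0.4093 cos(2 pi J / 365) (default).
    variant="fao": 0.409 sin(2 pi J / 365 - 1.39) (FAO-56).
    """
    j = np.asarray(doy, dtype=float)
    if variant == "cos":
        return -0.4093 * np.cos(2.0 * math.pi * j / 365.0)
    if variant == "fao":
        return 0.409 * np.sin(2.0 * math.pi * j / 365.0 - 1.39)
    raise ValueError(f"unknown declination variant {variant!r}")


def solar_geometry(latitude, doy, delta_variant="cos"):
    """Inverse-distance factor, declination, sunset angle, R_a and N.

    Returns (d_r, delta, w_s, R_a, N) with R_a in MJ m-2 day-1 and the
    maximum possible sunshine duration N in hours.  The arccos argument
    is clamped to [-1, 1] (with a warning) outside the polar-safe range.
    """
    j = np.asarray(doy, dtype=float)
    phi = math.radians(latitude)
    d_r = 1.0 + 0.033 * np.cos(2.0 * math.pi * j / 365.0)
    delta = solar_declination(j, delta_variant)
    arg = -math.tan(phi) * np.tan(delta)
    if np.any(np.abs(arg) > 1.0):
        logger.warning("sunset-angle argument clamped at latitude %.2f", latitude)
    w_s = np.arccos(np.clip(arg, -1.0, 1.0))
    r_a = (24.0 * 60.0 / math.pi) * GSC * d_r * (
        w_s * math.sin(phi) * np.sin(delta)
        + math.cos(phi) * np.cos(delta) * np.sin(w_s)
    )
    r_a = np.maximum(r_a, 0.0)
    n_hours = 24.0 / math.pi * w_s
    return d_r, delta, w_s, r_a, n_hours


def daylength(latitude, doy, delta_variant="cos"):
    """Maximum possible sunshine hours N = 24 w_s / pi."""
    if abs(latitude) >= 66.5:
        raise ValueError("latitude outside the polar-safe envelope (|lat| < 66.5)")
    return solar_geometry(latitude, doy, delta_variant)[4]


# ---------------------------------------------------------------------------
# radiation balance
# ---------------------------------------------------------------------------

def net_radiation(tmax, tmin, e_a, n, n_max, r_a, *, albedo_factor=0.77,
                  strict_printed=False):
    """Net shortwave, net longwave and net radiation (MJ m-2 day-1).

    R_ns = albedo_factor * (0.25 + 0.5 n/N) * R_a
    R_nl = 2.45e-9 * (0.1 + 0.9 n/N) * (0.34 - 0.14 sqrt(e_a))
           * ((Tmax+273)^4 + (Tmin+273)^4)
    R_n  = R_ns - R_nl (soil heat flux handled by the caller).

    strict_printed uses e_a in place of sqrt(e_a) in the emissivity term.
    """
    rel = np.asarray(n, dtype=float) / np.asarray(n_max, dtype=float)
    r_ns = albedo_factor * (0.25 + 0.5 * rel) * np.asarray(r_a, dtype=float)
    humid = np.asarray(e_a, dtype=float) if strict_printed else np.sqrt(
        np.maximum(e_a, 0.0))
    tmax_k = np.asarray(tmax, dtype=float) + 273.0
    tmin_k = np.asarray(tmin, dtype=float) + 273.0
    r_nl = (2.45e-9 * (0.1 + 0.9 * rel) * (0.34 - 0.14 * humid)
            * (tmax_k ** 4 + tmin_k ** 4))
    return r_ns, r_nl, r_ns - r_nl


# ---------------------------------------------------------------------------
# full stack
# ---------------------------------------------------------------------------

@dataclass
class ET0Inputs:
    """One day of meteorology plus the site constants the formula needs."""

    tmax: float
    tmin: float
    rh: float            # daily mean relative humidity, %
    u_meas: float        # wind speed at height ``wind_height``, m/s
    sunshine: float      # bright sunshine duration, h
    latitude: float      # degrees north
    elevation: float     # m above sea level
    doy: int
    tmean: float | None = None
    wind_height: float = DEFAULT_WIND_HEIGHT

    def __post_init__(self):
        if self.tmean is None:
            self.tmean = (self.tmax + self.tmin) / 2.0
        if self.tmin > self.tmax:
            raise ValueError("Tmin exceeds Tmax")
        if not 0.0 <= self.rh <= 100.0:
            raise ValueError("relative humidity outside [0, 100] %")
        if self.u_meas < 0 or self.sunshine < 0:
            raise ValueError("wind speed and sunshine must be non-negative")
        if not 1 <= self.doy <= 366:
            raise ValueError("day of year outside [1, 366]")


@dataclass
class ET0Diagnostics:
    """All intermediates of the reference-ET computation for one day."""

    e_tmax: float
    e_tmin: float
    e_s: float
    e_a: float
    delta: float
    p_atm: float
    lam: float
    gamma: float
    u2: float
    d_r: float
    decl: float
    w_s: float
    r_a: float
    n_max: float
    r_ns: float
    r_nl: float
    r_n: float
    g: float
    et0: float
    clamped: bool  # True when a negative numerator was floored to zero


def et0_penman_monteith(inputs: ET0Inputs, *, strict_printed=False,
                        delta_variant="cos", albedo_factor=0.77) -> ET0Diagnostics:
    """Daily reference evapotranspiration (mm/day) with full diagnostics.

    ET0 = [0.408 Delta (R_n - G) + gamma 900/(T+273) u2 (e_s - e_a)]
          / [Delta + gamma (1 + 0.34 u2)]
    with G = 0 at the daily timestep.  A negative numerator (possible on
    cold overcast days) is floored to ET0 = 0 and flagged.
    """
    e_tmax = float(saturation_vp(inputs.tmax))
    e_tmin = float(saturation_vp(inputs.tmin))
    e_s, e_a = vapor_pressures(inputs.tmax, inputs.tmin, inputs.rh)
    e_s, e_a = float(e_s), float(e_a)
    delta = float(slope_delta(inputs.tmean, strict_printed=strict_printed, e_a=e_a))
    p_atm = float(atm_pressure(inputs.elevation))
    lam = float(latent_heat(inputs.tmean))
    gamma = float(psychrometric(p_atm, lam))
    u2 = float(wind_2m(inputs.u_meas, inputs.wind_height))
    d_r, decl, w_s, r_a, n_max = (float(x) for x in solar_geometry(
        inputs.latitude, inputs.doy, delta_variant))
    r_ns, r_nl, r_n = (float(x) for x in net_radiation(
        inputs.tmax, inputs.tmin, e_a, inputs.sunshine, n_max, r_a,
        albedo_factor=albedo_factor, strict_printed=strict_printed))
    g = 0.0
    numer = (0.408 * delta * (r_n - g)
             + gamma * 900.0 / (inputs.tmean + 273.0) * u2 * (e_s - e_a))
    denom = delta + gamma * (1.0 + 0.34 * u2)
    et0 = numer / denom
    clamped = et0 < 0.0
    if clamped:
        et0 = 0.0
    return ET0Diagnostics(e_tmax, e_tmin, e_s, e_a, delta, p_atm, lam, gamma,
                          u2, d_r, decl, w_s, r_a, n_max, r_ns, r_nl, r_n, g,
                          et0, clamped)


def compute_et0(weather: pd.DataFrame, latitude: float, elevation: float, *,
                wind_height: float = DEFAULT_WIND_HEIGHT, strict_printed=False,
                delta_variant="cos", albedo_factor=0.77) -> pd.DataFrame:
    """Vectorised daily ET0 over a weather table.

    ``weather`` needs columns date, tmax, tmin, rh, wind, sunshine (a
    tmean column is used if present, otherwise derived).  Returns a copy
    with a ``doy`` column, every diagnostic of :class:`ET0Diagnostics`
    and the ``et0`` column in mm/day.
    """
    out = weather.copy()
    dates = pd.to_datetime(out["date"])
    out["doy"] = dates.dt.dayofyear.to_numpy()
    tmax = out["tmax"].to_numpy(float)
    tmin = out["tmin"].to_numpy(float)
    if np.any(tmin > tmax):
        raise ValueError("Tmin exceeds Tmax on some days")
    rh = out["rh"].to_numpy(float)
    if np.any((rh < 0) | (rh > 100)):
        raise ValueError("relative humidity outside [0, 100] %")
    tmean = (out["tmean"].to_numpy(float) if "tmean" in out
             else (tmax + tmin) / 2.0)
    e_s, e_a = vapor_pressures(tmax, tmin, rh)
    delta = slope_delta(tmean, strict_printed=strict_printed, e_a=e_a)
    p_atm = atm_pressure(elevation)
    lam = latent_heat(tmean)
    gamma = psychrometric(p_atm, lam)
    u2 = wind_2m(out["wind"].to_numpy(float), wind_height)
    d_r, decl, w_s, r_a, n_max = solar_geometry(latitude, out["doy"].to_numpy(),
                                                delta_variant)
    r_ns, r_nl, r_n = net_radiation(tmax, tmin, e_a,
                                    out["sunshine"].to_numpy(float), n_max, r_a,
                                    albedo_factor=albedo_factor,
                                    strict_printed=strict_printed)
    numer = (0.408 * delta * r_n
             + gamma * 900.0 / (tmean + 273.0) * u2 * (e_s - e_a))
    denom = delta + gamma * (1.0 + 0.34 * u2)
    et0 = numer / denom
    clamped = et0 < 0.0
    et0 = np.maximum(et0, 0.0)
    diag = dict(e_s=e_s, e_a=e_a, delta=delta, p_atm=p_atm, lam=lam,
                gamma=gamma, u2=u2, d_r=d_r, decl=decl, w_s=w_s, r_a=r_a,
                n_max=n_max, r_ns=r_ns, r_nl=r_nl, r_n=r_n,
                et0=et0, et0_clamped=clamped)
    for key, val in diag.items():
        out[key] = val
    return out


DIAGNOSTIC_FIELDS = tuple(f.name for f in fields(ET0Diagnostics))
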