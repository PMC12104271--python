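"""Independent brute-force oracles used to cross-check the package.

Everything here is written as plain day-stepping loops / straight-line
scalar arithmetic, deliberately sharing no code with the package's
vectorised implementations.
"""

from __future__ import annotations

import math

CHILL_LEAD = 122  # days Sep 1 .. Dec 31


# ---------------------------------------------------------------------------
# solar / ET0
# ---------------------------------------------------------------------------

def oracle_daylength(lat_deg: float, doy: int) -> float:
    phi = math.radians(lat_deg)
    delta = -0.4093 * math.cos(2.0 * math.pi * doy / 365.0)
    x = -math.tan(phi) * math.tan(delta)
    x = min(1.0, max(-1.0, x))
    ws = math.acos(x)
    return 24.0 * ws / math.pi


def oracle_et0(tmax, tmin, rh, u_meas, sunshine, lat_deg, elev, doy,
               wind_height=10.5):
    """Straight-line scalar transcription of the daily reference-ET stack."""
    tmean = (tmax + tmin) / 2.0

    def e(T):
        return 0.6108 * math.exp(17.27 * T / (T + 237.3))

    es = (e(tmax) + e(tmin)) / 2.0
    ea = rh / 100.0 * es
    delta_slope = 4098.0 * e(tmean) / (tmean + 237.3) ** 2
    p = 101.3 * ((293.0 - 0.0065 * elev) / 293.0) ** 5.26
    lam = 2.501 - 2.361e-3 * tmean
    gamma = 0.00163 * p / lam
    u2 = u_meas * 4.87 / math.log(67.8 * wind_height - 5.42)

    dr = 1.0 + 0.033 * math.cos(2.0 * math.pi * doy / 365.0)
    decl = -0.4093 * math.cos(2.0 * math.pi * doy / 365.0)
    phi = math.radians(lat_deg)
    x = min(1.0, max(-1.0, -math.tan(phi) * math.tan(decl)))
    ws = math.acos(x)
    ra = (24.0 * 60.0 / math.pi) * 0.082 * dr * (
        ws * math.sin(phi) * math.sin(decl)
        + math.cos(phi) * math.cos(decl) * math.sin(ws))
    ra = max(ra, 0.0)
    nmax = 24.0 * ws / math.pi

    rns = 0.77 * (0.25 + 0.5 * sunshine / nmax) * ra
    rnl = (2.45e-9 * (0.1 + 0.9 * sunshine / nmax)
           * (0.34 - 0.14 * math.sqrt(ea))
           * ((tmax + 273.0) ** 4 + (tmin + 273.0) ** 4))
    rn = rns - rnl

    numer = (0.408 * delta_slope * rn
             + gamma * 900.0 / (tmean + 273.0) * u2 * (es - ea))
    denom = delta_slope + gamma * (1.0 + 0.34 * u2)
    return max(numer / denom, 0.0)


# ---------------------------------------------------------------------------
# phenology (day stepping over a Sep-1-anchored season window)
# ---------------------------------------------------------------------------

def _start_day(t):
    return max(int(math.ceil(t)) - 1, 0)


def oracle_m1(tmean_season, lat_deg, p):
    """tmean_season: list from Sep 1 prev year through Dec 31."""
    year = tmean_season[CHILL_LEAD:]
    s = _start_day(p.t1)
    acc = 0.0
    for i in range(s, len(year)):
        doy = i + 1
        L = oracle_daylength(lat_deg, doy)
        rate = max(year[i] - p.threshold, 0.0)
        acc += (L / 24.0) ** p.k * rate
        if acc >= p.f_star:
            return doy
    return None


def oracle_uniforc(tmean_season, p):
    year = tmean_season[CHILL_LEAD:]
    s = _start_day(p.t1)
    acc = 0.0
    for i in range(s, len(year)):
        acc += 1.0 / (1.0 + math.exp(min(max(p.b * (year[i] - p.c), -500), 500)))
        if acc >= p.f_star:
            return i + 1
    return None


def oracle_alternating(tmean_season, p):
    year = tmean_season[CHILL_LEAD:]
    s = _start_day(p.t1)
    cd = sum(1 for t in tmean_season[:CHILL_LEAD] if t < p.threshold)
    acc = 0.0
    for i in range(len(year)):
        if year[i] < p.threshold:
            cd += 1
        if i < s:
            continue
        acc += max(year[i] - p.threshold, 0.0)
        need = p.a + p.b * math.exp(min(max(p.c * cd, -500), 500))
        if acc >= need:
            return i + 1
    return None


def oracle_unichill(tmean_season, p):
    def rc(T):
        dT = T - p.c_c
        x = min(max(p.a_c * dT * dT + p.b_c * dT, -500), 500)
        return 1.0 / (1.0 + math.exp(x))

    def rf(T):
        x = min(max(p.b_f * (T - p.c_f), -500), 500)
        return 1.0 / (1.0 + math.exp(x))

    s0 = _start_day(p.t0)
    n = len(tmean_season)
    if p.c_star > 0:
        acc_c = 0.0
        t_c = None
        for i in range(s0, n):
            acc_c += rc(tmean_season[i])
            if acc_c >= p.c_star:
                t_c = i
                break
        if t_c is None:
            return None
    else:
        t_c = s0 - 1
    acc_f = 0.0
    for i in range(t_c + 1, n):
        acc_f += rf(tmean_season[i])
        if acc_f >= p.f_star:
            if i < CHILL_LEAD:
                return None
            return i - CHILL_LEAD + 1
    return None
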