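"""Independent higher-precision ephemeris used only as a test oracle.

This is a separate code path from ``kratkit.ephemeris``: it uses the
segmented polynomial fit for the TT-UT offset, the explicit leading terms
of the 1980 nutation theory (rather than a fixed-coefficient shortcut),
aberration proportional to 1/R, and a rigorous topocentric transformation
of the lunar position (observer geocentric coordinates with Earth
flattening) instead of the altitude-domain parallax approximation.  Its
absolute accuracy is anchored in tests against published worked-example
positions and almanac new/full-moon instants.
"""

from __future__ import annotations

import numpy as np

DEG = np.pi / 180.0
ARCSEC = DEG / 3600.0
J2000 = 2451545.0
AU_KM = 149597870.7


def delta_t_seconds(jd: float) -> float:
    """Segmented polynomial fit to TT-UT over 1900-2150."""
    y = 2000.0 + (jd - J2000) / 365.25
    if y < 1920:
        t = y - 1900
        return -2.79 + 1.494119 * t - 0.0598939 * t**2 + 0.0061966 * t**3 - 0.000197 * t**4
    if y < 1941:
        t = y - 1920
        return 21.20 + 0.84493 * t - 0.076100 * t**2 + 0.0020936 * t**3
    if y < 1961:
        t = y - 1950
        return 29.07 + 0.407 * t - t**2 / 233 + t**3 / 2547
    if y < 1986:
        t = y - 1975
        return 45.45 + 1.067 * t - t**2 / 260 - t**3 / 718
    if y < 2005:
        t = y - 2000
        return (
            63.86
            + 0.3345 * t
            - 0.060374 * t**2
            + 0.0017275 * t**3
            + 0.000651814 * t**4
            + 0.00002373599 * t**5
        )
    if y < 2050:
        t = y - 2000
        return 62.92 + 0.32217 * t + 0.005589 * t**2
    return -20 + 32 * ((y - 1820) / 100) ** 2 - 0.5628 * (2150 - y)


def _fundamental_args(T: float):
    Lp = (
        218.3164477
        + 481267.88123421 * T
        - 0.0015786 * T**2
        + T**3 / 538841.0
        - T**4 / 65194000.0
    )
    D = (
        297.8501921
        + 445267.1114034 * T
        - 0.0018819 * T**2
        + T**3 / 545868.0
        - T**4 / 113065000.0
    )
    M = 357.5291092 + 35999.0502909 * T - 0.0001536 * T**2 + T**3 / 24490000.0
    Mp = (
        134.9633964
        + 477198.8675055 * T
        + 0.0087414 * T**2
        + T**3 / 69699.0
        - T**4 / 14712000.0
    )
    F = (
        93.2720950
        + 483202.0175233 * T
        - 0.0036539 * T**2
        - T**3 / 3526000.0
        + T**4 / 863310000.0
    )
    return Lp, D, M, Mp, F


def nutation(T: float) -> tuple[float, float]:
    """Nutation in longitude and obliquity (degrees), leading 1980-theory terms."""
    omega = 125.04452 - 1934.136261 * T + 0.0020708 * T**2
    Ls = 280.4665 + 36000.7698 * T
    Lm = 218.3165 + 481267.8813 * T
    o, ls, lm = omega * DEG, Ls * DEG, Lm * DEG
    dpsi = (
        -17.20 * np.sin(o)
        - 1.32 * np.sin(2 * ls)
        - 0.23 * np.sin(2 * lm)
        + 0.21 * np.sin(2 * o)
    ) / 3600.0
    deps = (
        9.20 * np.cos(o)
        + 0.57 * np.cos(2 * ls)
        + 0.10 * np.cos(2 * lm)
        - 0.09 * np.cos(2 * o)
    ) / 3600.0
    return dpsi, deps


def mean_obliquity(T: float) -> float:
    return (
        23.0
        + 26.0 / 60.0
        + (21.448 - 46.8150 * T - 0.00059 * T**2 + 0.001813 * T**3) / 3600.0
    )


def sun_position(jd_tt: float):
    """Apparent ecliptic longitude (deg) and distance (au)."""
    T = (jd_tt - J2000) / 36525.0
    L0 = 280.46646 + 36000.76983 * T + 0.0003032 * T**2
    M = (357.52911 + 35999.05029 * T - 0.0001537 * T**2) * DEG
    e = 0.016708634 - 0.000042037 * T - 0.0000001267 * T**2
    C = (
        (1.914602 - 0.004817 * T - 0.000014 * T**2) * np.sin(M)
        + (0.019993 - 0.000101 * T) * np.sin(2 * M)
        + 0.000289 * np.sin(3 * M)
    )
    true_lon = L0 + C
    nu = M + C * DEG
    R = 1.000001018 * (1 - e**2) / (1 + e * np.cos(nu))
    dpsi, _ = nutation(T)
    aberration = -20.4898 / R / 3600.0
    return (true_lon + dpsi + aberration) % 360.0, R


# Full set of terms kept in this oracle (the package keeps a shorter list
# internally; the comparison tolerances absorb the truncation difference).
_LR = [
    (0, 0, 1, 0, 6288774, -20905355),
    (2, 0, -1, 0, 1274027, -3699111),
    (2, 0, 0, 0, 658314, -2955968),
    (0, 0, 2, 0, 213618, -569925),
    (0, 1, 0, 0, -185116, 48888),
    (0, 0, 0, 2, -114332, -3149),
    (2, 0, -2, 0, 58793, 246158),
    (2, -1, -1, 0, 57066, -152138),
    (2, 0, 1, 0, 53322, -170733),
    (2, -1, 0, 0, 45758, -204586),
    (0, 1, -1, 0, -40923, -129620),
    (1, 0, 0, 0, -34720, 108743),
    (0, 1, 1, 0, -30383, 104755),
    (2, 0, 0, -2, 15327, 10321),
    (0, 0, 1, 2, -12528, 0),
    (0, 0, 1, -2, 10980, 79661),
    (4, 0, -1, 0, 10675, -34782),
    (0, 0, 3, 0, 10034, -23210),
    (4, 0, -2, 0, 8548, -21636),
    (2, 1, -1, 0, -7888, 24208),
    (2, 1, 0, 0, -6766, 30824),
    (1, 0, -1, 0, -5163, -8379),
    (1, 1, 0, 0, 4987, -16675),
    (2, -1, 1, 0, 4036, -12831),
    (2, 0, 2, 0, 3994, -10445),
    (4, 0, 0, 0, 3861, -11650),
    (2, 0, -3, 0, 3665, 14403),
]

_B = [
    (0, 0, 0, 1, 5128122),
    (0, 0, 1, 1, 280602),
    (0, 0, 1, -1, 277693),
    (2, 0, 0, -1, 173237),
    (2, 0, -1, 1, 55413),
    (2, 0, -1, -1, 46271),
    (2, 0, 0, 1, 32573),
    (0, 0, 2, 1, 17198),
    (2, 0, 1, -1, 9266),
    (0, 0, 2, -1, 8822),
    (2, -1, 0, -1, 8216),
    (2, 0, -2, -1, 4324),
    (2, 0, 1, 1, 4200),
    (2, 1, 0, -1, -3359),
    (2, -1, -1, 1, 2463),
    (2, -1, 0, 1, 2211),
    (2, -1, -1, -1, 2065),
    (0, 1, -1, -1, -1870),
    (4, 0, -1, -1, 1828),
    (0, 1, 0, 1, -1794),
]


def moon_position(jd_tt: float):
    """Geocentric apparent lunar longitude/latitude (deg) and distance (km)."""
    T = (jd_tt - J2000) / 36525.0
    Lp, D, M, Mp, F = _fundamental_args(T)
    E = 1.0 - 0.002516 * T - 0.0000074 * T**2
    sl = sr = 0.0
    for d, m, mp, f, a_sin, a_cos in _LR:
        arg = (d * D + m * M + mp * Mp + f * F) * DEG
        ef = E ** abs(m)
        sl += a_sin * ef * np.sin(arg)
        sr += a_cos * ef * np.cos(arg)
    sb = 0.0
    for d, m, mp, f, a_sin in _B:
        arg = (d * D + m * M + mp * Mp + f * F) * DEG
        sb += a_sin * E ** abs(m) * np.sin(arg)
    A1 = (119.75 + 131.849 * T) * DEG
    A2 = (53.09 + 479264.290 * T) * DEG
    A3 = (313.45 + 481266.484 * T) * DEG
    sl += 3958 * np.sin(A1) + 1962 * np.sin((Lp - F) * DEG) + 318 * np.sin(A2)
    sb += (
        -2235 * np.sin(Lp * DEG)
        + 382 * np.sin(A3)
        + 175 * np.sin(A1 - F * DEG)
        + 175 * np.sin(A1 + F * DEG)
        + 127 * np.sin((Lp - Mp) * DEG)
        - 115 * np.sin((Lp + Mp) * DEG)
    )
    dpsi, _ = nutation(T)
    lam = (Lp + sl * 1e-6 + dpsi) % 360.0
    beta = sb * 1e-6
    dist = 385000.56 + sr * 1e-3
    return lam, beta, dist


def _to_equatorial(lam: float, beta: float, eps: float):
    l, b, e = lam * DEG, beta * DEG, eps * DEG
    ra = np.arctan2(np.sin(l) * np.cos(e) - np.tan(b) * np.sin(e), np.cos(l))
    dec = np.arcsin(np.sin(b) * np.cos(e) + np.cos(b) * np.sin(e) * np.sin(l))
    return (ra / DEG) % 360.0, dec / DEG


def _apparent_sidereal(jd_ut: float) -> float:
    T = (jd_ut - J2000) / 36525.0
    theta = (
        280.46061837
        + 360.98564736629 * (jd_ut - J2000)
        + 0.000387933 * T**2
        - T**3 / 38710000.0
    )
    dpsi, deps = nutation(T)
    eps = mean_obliquity(T) + deps
    return (theta + dpsi * np.cos(eps * DEG)) % 360.0


def sun_altitude(jd_ut: float, lat: float, lon: float) -> float:
    jd_tt = jd_ut + delta_t_seconds(jd_ut) / 86400.0
    T = (jd_tt - J2000) / 36525.0
    lam, _ = sun_position(jd_tt)
    _, deps = nutation(T)
    ra, dec = _to_equatorial(lam, 0.0, mean_obliquity(T) + deps)
    H = (_apparent_sidereal(jd_ut) + lon - ra) * DEG
    phi, d = lat * DEG, dec * DEG
    sinh = np.sin(phi) * np.sin(d) + np.cos(phi) * np.cos(d) * np.cos(H)
    return float(np.arcsin(np.clip(sinh, -1, 1)) / DEG)


def moon_topocentric_altitude(jd_ut: float, lat: float, lon: float) -> float:
    """Topocentric geometric lunar altitude via a rigorous parallax transform."""
    jd_tt = jd_ut + delta_t_seconds(jd_ut) / 86400.0
    T = (jd_tt - J2000) / 36525.0
    lam, beta, dist = moon_position(jd_tt)
    _, deps = nutation(T)
    ra, dec = _to_equatorial(lam, beta, mean_obliquity(T) + deps)
    # observer geocentric position (Earth flattening 1/298.257)
    u = np.arctan(0.99664719 * np.tan(lat * DEG))
    rho_sin = 0.99664719 * np.sin(u)
    rho_cos = np.cos(u)
    pi_moon = np.arcsin(6378.14 / dist)
    H = (_apparent_sidereal(jd_ut) + lon - ra) * DEG
    d = dec * DEG
    num = -rho_cos * np.sin(pi_moon) * np.sin(H)
    den = np.cos(d) - rho_cos * np.sin(pi_moon) * np.cos(H)
    dA = np.arctan2(num, den)
    ra_t = ra * DEG + dA
    dec_t = np.arctan2(
        (np.sin(d) - rho_sin * np.sin(pi_moon)) * np.cos(dA),
        np.cos(d) - rho_cos * np.sin(pi_moon) * np.cos(H),
    )
    H_t = (_apparent_sidereal(jd_ut) + lon) * DEG - ra_t
    phi = lat * DEG
    sinh = np.sin(phi) * np.sin(dec_t) + np.cos(phi) * np.cos(dec_t) * np.cos(H_t)
    return float(np.arcsin(np.clip(sinh, -1, 1)) / DEG)


def illuminated_fraction(jd_ut: float) -> float:
    jd_tt = jd_ut + delta_t_seconds(jd_ut) / 86400.0
    lam_s, R = sun_position(jd_tt)
    lam_m, beta_m, dist = moon_position(jd_tt)
    cos_psi = np.clip(
        np.cos(beta_m * DEG) * np.cos((lam_m - lam_s) * DEG), -1.0, 1.0
    )
    psi = np.arccos(cos_psi)
    R_km = R * AU_KM
    i = np.arctan2(R_km * np.sin(psi), dist - R_km * cos_psi)
    return float((1.0 + np.cos(i)) / 2.0)


def crossings(alt_fn, jd0: float, jd1: float, threshold: float = 0.0):
    """(jd, rising) threshold crossings found on a 4-minute grid + bisection."""
    n = int(np.ceil((jd1 - jd0) * 360)) + 1
    grid = np.linspace(jd0, jd1, n)
    vals = np.array([alt_fn(j) for j in grid]) - threshold
    out = []
    for i in range(n - 1):
        if (vals[i] < 0) != (vals[i + 1] < 0):
            lo, hi, flo = grid[i], grid[i + 1], vals[i]
            for _ in range(40):
                mid = 0.5 * (lo + hi)
                fmid = alt_fn(mid) - threshold
                if (flo < 0) != (fmid < 0):
                    hi = mid
                else:
                    lo, flo = mid, fmid
                if (hi - lo) * 86400 < 0.5:
                    break
            out.append((0.5 * (lo + hi), vals[i] < 0))
    return out
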