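"""Solar and lunar ephemeris for diel-phase and moonlight annotation.

Positions are computed from compact trigonometric series: the standard
low-precision solar theory (geometric mean longitude plus equation of
center, with the leading nutation/aberration correction) and a truncated
lunar theory (the dominant periodic terms in longitude, latitude and
distance, plus the planetary additive terms).  Altitudes are geometric
(airless); lunar altitude is topocentric (corrected for horizontal
parallax, which reaches a degree for the Moon).  Documented accuracy over
1900-2100: solar altitude within 0.5 degrees and lunar illuminated
fraction within 0.02 of a high-precision ephemeris; rise/set crossing
instants within 5 minutes.

The eight-phase diel classification assigns every instant exactly one
phase: altitude bands below the horizon (0-6, 6-18, >18 degrees depression,
split into evening/morning sides by the sign of the altitude rate) and,
above the horizon, the first hour after sunrise (morning), the last hour
before sunset (evening), and day in between.  Phase banding uses geometric
0-degree horizon crossings; the separately reported sunrise/sunset
*instants* apply the conventional -0.833 degree refraction altitude by
default (configurable).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from datetime import date, datetime, timedelta, timezone
from typing import Callable, Iterable

import numpy as np
import pandas as pd

from .core import LightPhase, as_utc

__all__ = [
    "SiteContext",
    "MoonIntensity",
    "MoonState",
    "sun_altitude",
    "classify_light_phase",
    "moon_illuminated_fraction",
    "moon_intensity",
    "moon_state",
    "moon_altitude",
    "nightly_moon_value",
    "sun_events",
    "moon_events",
    "annotate_times",
    "night_id",
    "solar_midnight",
    "UnsupportedLatitudeError",
]

_DEG = np.pi / 180.0
_J2000 = 2451545.0
_EARTH_RADIUS_KM = 6378.14
_AU_KM = 149597870.7


class UnsupportedLatitudeError(ValueError):
    """Raised when a site/date has no sunrise or sunset (polar day/night)."""


@dataclass(frozen=True)
class SiteContext:
    """Study-site location. Longitude is east-positive; timezone is an IANA name."""

    latitude: float
    longitude: float
    timezone: str = "UTC"

    def __post_init__(self) -> None:
        if not -90.0 <= self.latitude <= 90.0:
            raise ValueError("latitude must lie in [-90, 90] degrees")
        if not -180.0 <= self.longitude <= 180.0:
            raise ValueError("longitude must lie in [-180, 180] degrees")


class MoonIntensity(str, enum.Enum):
    LOW = "low"
    MEDIUM = "medium"
    HIGH = "high"


@dataclass(frozen=True)
class MoonState:
    illumination: float
    intensity: MoonIntensity
    is_up: bool
    altitude: float


# --- time scales -----------------------------------------------------------


def _to_jd_ut(t) -> np.ndarray:
    """Convert datetimes (datetime / datetime64 / DatetimeIndex) to UT Julian day."""
    if isinstance(t, datetime):
        t = np.datetime64(as_utc(t).replace(tzinfo=None), "ns")
    arr = np.asarray(pd.to_datetime(np.asarray(t)), dtype="datetime64[ns]")
    sec = (arr - np.datetime64("2000-01-01T12:00:00", "ns")) / np.timedelta64(1, "s")
    return _J2000 + np.asarray(sec, dtype=float) / 86400.0


def _jd_to_datetime(jd: float) -> datetime:
    sec = (jd - _J2000) * 86400.0
    base = datetime(2000, 1, 1, 12, tzinfo=timezone.utc)
    return base + timedelta(seconds=float(sec))


def _delta_t_seconds(jd: np.ndarray) -> np.ndarray:
    # long-term parabolic fit to the observed TT-UT series; errors of a few
    # tens of seconds over 1900-2100 are far below the altitude tolerance
    y = 2000.0 + (np.asarray(jd) - _J2000) / 365.25
    return -20.0 + 32.0 * ((y - 1820.0) / 100.0) ** 2


def _jd_tt(jd_ut: np.ndarray) -> np.ndarray:
    return jd_ut + _delta_t_seconds(jd_ut) / 86400.0


# --- solar position --------------------------------------------------------


def _sun_ecliptic(jd_tt: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Apparent ecliptic longitude (deg) and distance (au) of the Sun."""
    T = (jd_tt - _J2000) / 36525.0
    L0 = 280.46646 + 36000.76983 * T + 0.0003032 * T**2
    M = 357.52911 + 35999.05029 * T - 0.0001537 * T**2
    e = 0.016708634 - 0.000042037 * T - 0.0000001267 * T**2
    Mr = M * _DEG
    C = (
        (1.914602 - 0.004817 * T - 0.000014 * T**2) * np.sin(Mr)
        + (0.019993 - 0.000101 * T) * np.sin(2 * Mr)
        + 0.000289 * np.sin(3 * Mr)
    )
    true_lon = L0 + C
    nu = Mr + C * _DEG
    R = 1.000001018 * (1 - e**2) / (1 + e * np.cos(nu))
    omega = (125.04 - 1934.136 * T) * _DEG
    lam_app = true_lon - 0.00569 - 0.00478 * np.sin(omega)
    return lam_app % 360.0, R


def _obliquity(jd_tt: np.ndarray, apparent: bool = True) -> np.ndarray:
    T = (jd_tt - _J2000) / 36525.0
    eps0 = 23.43929111 - 0.01300417 * T - 1.639e-7 * T**2 + 5.036e-7 * T**3
    if apparent:
        omega = (125.04 - 1934.136 * T) * _DEG
        eps0 = eps0 + 0.00256 * np.cos(omega)
    return eps0


def _ecl_to_equatorial(lam_deg, beta_deg, eps_deg):
    lam, beta, eps = lam_deg * _DEG, beta_deg * _DEG, eps_deg * _DEG
    sa = np.sin(lam) * np.cos(eps) - np.tan(beta) * np.sin(eps)
    ra = np.arctan2(sa, np.cos(lam))
    dec = np.arcsin(
        np.sin(beta) * np.cos(eps) + np.cos(beta) * np.sin(eps) * np.sin(lam)
    )
    return (ra / _DEG) % 360.0, dec / _DEG


def _gmst_deg(jd_ut: np.ndarray) -> np.ndarray:
    T = (jd_ut - _J2000) / 36525.0
    theta = (
        280.46061837
        + 360.98564736629 * (jd_ut - _J2000)
        + 0.000387933 * T**2
        - T**3 / 38710000.0
    )
    return theta % 360.0

def _altitude_deg(ra_deg, dec_deg, jd_ut, lat, lon) -> np.ndarray:
    H = (_gmst_deg(jd_ut) + lon - ra_deg) * _DEG
    phi, dec = lat * _DEG, dec_deg * _DEG
    sinh = np.sin(phi) * np.sin(dec) + np.cos(phi) * np.cos(dec) * np.cos(H)
    return np.arcsin(np.clip(sinh, -1.0, 1.0)) / _DEG


def _sun_altitude_jd(jd_ut: np.ndarray, lat: float, lon: float) -> np.ndarray:
    tt = _jd_tt(jd_ut)
    lam, _ = _sun_ecliptic(tt)
    ra, dec = _ecl_to_equatorial(lam, np.zeros_like(lam), _obliquity(tt))
    return _altitude_deg(ra, dec, jd_ut, lat, lon)


def sun_altitude(site: SiteContext, t) -> float | np.ndarray:
    """Geometric (airless) solar altitude in degrees at UTC time(s) ``t``."""
    jd = _to_jd_ut(t)
    alt = _sun_altitude_jd(jd, site.latitude, site.longitude)
    return float(alt) if np.isscalar(alt) or alt.ndim == 0 else alt


# --- lunar position --------------------------------------------------------

# Dominant periodic terms of the lunar theory. Columns: multiples of
# (D, M, M', F); amplitude of the sine (longitude, 1e-6 deg) or cosine
# (distance, 1e-3 km) term. Terms involving M scale by the eccentricity
# factor E once per power of M.
_LUNAR_LR = [
    # D  M  Mp  F     sin(1e-6 deg)  cos(1e-3 km)
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

_LUNAR_B = [
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


def _moon_ecliptic(jd_tt: np.ndarray):
    """Geocentric lunar longitude/latitude (deg) and distance (km)."""
    T = (jd_tt - _J2000) / 36525.0
    Lp = 218.3164477 + 481267.88123421 * T - 0.0015786 * T**2 + T**3 / 538841.0
    D = 297.8501921 + 445267.1114034 * T - 0.0018819 * T**2 + T**3 / 545868.0
    M = 357.5291092 + 35999.0502909 * T - 0.0001536 * T**2
    Mp = 134.9633964 + 477198.8675055 * T + 0.0087414 * T**2 + T**3 / 69699.0
    F = 93.2720950 + 483202.0175233 * T - 0.0036539 * T**2 - T**3 / 3526000.0
    E = 1.0 - 0.002516 * T - 0.0000074 * T**2

    sl = np.zeros_like(np.asarray(T, dtype=float))
    sr = np.zeros_like(sl)
    for d, m, mp, f, a_sin, a_cos in _LUNAR_LR:
        arg = (d * D + m * M + mp * Mp + f * F) * _DEG
        efac = E ** abs(m)
        sl = sl + a_sin * efac * np.sin(arg)
        sr = sr + a_cos * efac * np.cos(arg)
    sb = np.zeros_like(sl)
    for d, m, mp, f, a_sin in _LUNAR_B:
        arg = (d * D + m * M + mp * Mp + f * F) * _DEG
        sb = sb + a_sin * E ** abs(m) * np.sin(arg)

    # planetary / flattening additive terms
    A1 = (119.75 + 131.849 * T) * _DEG
    A2 = (53.09 + 479264.290 * T) * _DEG
    A3 = (313.45 + 481266.484 * T) * _DEG
    sl = sl + 3958 * np.sin(A1) + 1962 * np.sin((Lp - F) * _DEG) + 318 * np.sin(A2)
    sb = (
        sb
        - 2235 * np.sin(Lp * _DEG)
        + 382 * np.sin(A3)
        + 175 * np.sin(A1 - F * _DEG)
        + 175 * np.sin(A1 + F * _DEG)
        + 127 * np.sin((Lp - Mp) * _DEG)
        - 115 * np.sin((Lp + Mp) * _DEG)
    )

    lam = (Lp + sl * 1e-6) % 360.0
    beta = sb * 1e-6
    dist = 385000.56 + sr * 1e-3
    return lam, beta, dist


def _moon_topo_altitude_jd(jd_ut: np.ndarray, lat: float, lon: float) -> np.ndarray:
    tt = _jd_tt(jd_ut)
    lam, beta, dist = _moon_ecliptic(tt)
    ra, dec = _ecl_to_equatorial(lam, beta, _obliquity(tt))
    h = _altitude_deg(ra, dec, jd_ut, lat, lon)
    parallax = np.arcsin(_EARTH_RADIUS_KM / dist) / _DEG
    return h - parallax * np.cos(h * _DEG)


def moon_altitude(site: SiteContext, t) -> float | np.ndarray:
    """Topocentric geometric lunar altitude in degrees (no refraction)."""
    jd = _to_jd_ut(t)
    alt = _moon_topo_altitude_jd(jd, site.latitude, site.longitude)
    return float(alt) if np.isscalar(alt) or alt.ndim == 0 else alt


def _illuminated_fraction_jd(jd_ut: np.ndarray) -> np.ndarray:
    tt = _jd_tt(jd_ut)
    lam_s, R = _sun_ecliptic(tt)
    lam_m, beta_m, dist = _moon_ecliptic(tt)
    cos_psi = np.cos(beta_m * _DEG) * np.cos((lam_m - lam_s) * _DEG)
    cos_psi = np.clip(cos_psi, -1.0, 1.0)
    psi = np.arccos(cos_psi)
    R_km = R * _AU_KM
    i = np.arctan2(R_km * np.sin(psi), dist - R_km * cos_psi)
    return (1.0 + np.cos(i)) / 2.0


def moon_illuminated_fraction(t) -> float | np.ndarray:
    """Illuminated fraction of the lunar disk: 0.00 (new) to 1.00 (full)."""
    frac = _illuminated_fraction_jd(_to_jd_ut(t))
    return float(frac) if np.isscalar(frac) or frac.ndim == 0 else frac


_INTENSITY_LOW_BOUND = 0.33
_INTENSITY_HIGH_BOUND = 0.66


def moon_intensity(fraction: float) -> MoonIntensity:
    """Categorical moon intensity: <0.33 low, 0.33-0.66 medium, >0.66 high.

    Boundary values 0.33 and 0.66 fall in the medium category (the stated
    range is inclusive).
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("moon illumination fraction must lie in [0, 1]")
    if fraction < _INTENSITY_LOW_BOUND:
        return MoonIntensity.LOW
    if fraction <= _INTENSITY_HIGH_BOUND:
        return MoonIntensity.MEDIUM
    return MoonIntensity.HIGH


def moon_state(site: SiteContext, t: datetime) -> MoonState:
    """Moon illumination, intensity category, altitude and up/down flag."""
    alt = float(moon_altitude(site, t))
    frac = float(moon_illuminated_fraction(t))
    return MoonState(
        illumination=frac,
        intensity=moon_intensity(frac),
        is_up=alt > 0.0,
        altitude=alt,
    )


# --- horizon crossings -----------------------------------------------------

#: Conventional refraction altitude for reported sunrise/sunset instants.
RISE_SET_ALTITUDE_DEG = -0.833


def _find_crossings(
    alt_fn: Callable[[np.ndarray], np.ndarray],
    jd0: float,
    jd1: float,
    threshold: float,
    step_minutes: float = 10.0,
) -> list[tuple[float, bool]]:
    """Threshold crossings of an altitude function on [jd0, jd1].

    Returns (jd, rising) pairs, bisected to ~1 s.  The coarse scan step must
    be shorter than any excursion above/below the threshold, which holds for
    sun and moon away from polar latitudes.
    """
    n = max(int(np.ceil((jd1 - jd0) * 24 * 60 / step_minutes)), 2)
    grid = np.linspace(jd0, jd1, n + 1)
    vals = np.asarray(alt_fn(grid)) - threshold
    out: list[tuple[float, bool]] = []
    for i in range(n):
        a, b = vals[i], vals[i + 1]
        if a == 0.0:
            continue
        if (a < 0) != (b < 0) or b == 0.0:
            lo, hi = grid[i], grid[i + 1]
            flo = a
            for _ in range(40):
                mid = 0.5 * (lo + hi)
                fmid = float(alt_fn(np.array([mid]))[0]) - threshold
                if (flo < 0) != (fmid < 0):
                    hi = mid
                else:
                    lo, flo = mid, fmid
                if (hi - lo) * 86400.0 < 0.005:
                    break
            out.append((0.5 * (lo + hi), a < 0))
    return out


def sun_events(
    site: SiteContext,
    start: datetime,
    end: datetime,
    rise_set_altitude: float = RISE_SET_ALTITUDE_DEG,
) -> list[tuple[datetime, str]]:
    """Sunrise/sunset instants in [start, end] at the given altitude threshold."""
    jd0, jd1 = float(_to_jd_ut(as_utc(start))), float(_to_jd_ut(as_utc(end)))
    fn = lambda jd: _sun_altitude_jd(jd, site.latitude, site.longitude)
    return [
        (_jd_to_datetime(jd), "sunrise" if rising else "sunset")
        for jd, rising in _find_crossings(fn, jd0, jd1, rise_set_altitude)
    ]


def moon_events(
    site: SiteContext, start: datetime, end: datetime
) -> list[tuple[datetime, str]]:
    """Moonrise/moonset instants (topocentric altitude crossing 0)."""
    jd0, jd1 = float(_to_jd_ut(as_utc(start))), float(_to_jd_ut(as_utc(end)))
    fn = lambda jd: _moon_topo_altitude_jd(jd, site.latitude, site.longitude)
    return [
        (_jd_to_datetime(jd), "moonrise" if rising else "moonset")
        for jd, rising in _find_crossings(fn, jd0, jd1, 0.0)
    ]


# --- diel phase classification ---------------------------------------------


def _geometric_sun_crossings(site: SiteContext, jd0: float, jd1: float):
    fn = lambda jd: _sun_altitude_jd(jd, site.latitude, site.longitude)
    events = _find_crossings(fn, jd0, jd1, 0.0)
    rises = np.array([jd for jd, r in events if r])
    sets = np.array([jd for jd, r in events if not r])
    return rises, sets


def classify_light_phase(site: SiteContext, t) -> LightPhase | np.ndarray:
    """Assign each timestamp to exactly one of the eight diel light phases."""
    scalar = isinstance(t, (datetime, str))
    jd = np.atleast_1d(_to_jd_ut(t))
    phases = _classify_jd(site, jd)
    if scalar:
        return phases[0]
    return phases


def _classify_jd(site: SiteContext, jd: np.ndarray) -> np.ndarray:
    lat, lon = site.latitude, site.longitude
    alt = _sun_altitude_jd(jd, lat, lon)
    dt_min = 1.0 / 1440.0
    rising = _sun_altitude_jd(jd + dt_min, lat, lon) > _sun_altitude_jd(
        jd - dt_min, lat, lon
    )

    out = np.empty(jd.shape, dtype=object)
    below = alt < 0.0
    out[below & (alt < -18.0)] = LightPhase.NIGHT
    band_tw = below & (alt >= -18.0) & (alt < -6.0)
    out[band_tw & rising] = LightPhase.MORNING_TWILIGHT
    out[band_tw & ~rising] = LightPhase.EVENING_TWILIGHT
    band_dd = below & (alt >= -6.0)
    out[band_dd & rising] = LightPhase.DAWN
    out[band_dd & ~rising] = LightPhase.DUSK

    above = ~below
    if np.any(above):
        jd0, jd1 = float(jd.min()) - 1.5, float(jd.max()) + 1.5
        rises, sets = _geometric_sun_crossings(site, jd0, jd1)
        if rises.size == 0 or sets.size == 0:
            raise UnsupportedLatitudeError(
                "no geometric sunrise/sunset near this date; polar day/night "
                f"is unsupported (site latitude {lat:.2f})"
            )
        ja = jd[above]
        idx_r = np.searchsorted(rises, ja, side="right") - 1
        last_rise = rises[np.clip(idx_r, 0, rises.size - 1)]
        idx_s = np.searchsorted(sets, ja, side="left")
        next_set = sets[np.clip(idx_s, 0, sets.size - 1)]
        ok = (idx_r >= 0) & (idx_s < sets.size)
        if not np.all(ok):
            raise UnsupportedLatitudeError(
                "timestamp above horizon without a bracketing sunrise/sunset"
            )
        one_hour = 1.0 / 24.0
        sub = np.empty(ja.shape, dtype=object)
        sub[:] = LightPhase.DAY
        sub[next_set - ja < one_hour] = LightPhase.EVENING
        sub[ja - last_rise < one_hour] = LightPhase.MORNING
        out[above] = sub
    return out


# --- nights ----------------------------------------------------------------


def night_id(site: SiteContext, t: datetime) -> date:
    """Night identifier: the site-local date of the preceding local noon.

    Noon-to-noon grouping keeps one continuous dark period on a single
    night id instead of splitting it at civil midnight.
    """
    from zoneinfo import ZoneInfo

    local = as_utc(t).astimezone(ZoneInfo(site.timezone))
    if local.hour < 12:
        return (local - timedelta(days=1)).date()
    return local.date()


def solar_midnight(site: SiteContext, night: date) -> datetime:
    """Approximate local solar midnight (UTC) of the given night id.

    Mean solar midnight follows the site longitude: 00:00 local mean solar
    time on the morning after ``night``.
    """
    base = datetime(night.year, night.month, night.day, tzinfo=timezone.utc)
    return base + timedelta(hours=24.0 - site.longitude / 15.0)


def nightly_moon_value(site: SiteContext, night: date) -> float:
    """Nightly continuous moon illumination: the fraction at local solar midnight."""
    return float(moon_illuminated_fraction(solar_midnight(site, night)))


# --- bulk annotation -------------------------------------------------------


def annotate_times(site: SiteContext, times: Iterable) -> pd.DataFrame:
    """Per-timestamp diel/moon annotation table.

    Columns: timestamp, sun_altitude, light_phase, moon_altitude, moon_up,
    moon_illumination, moon_intensity, night.
    """
    idx = pd.DatetimeIndex(pd.to_datetime(list(times)))
    if idx.tz is not None:
        idx = idx.tz_convert("UTC").tz_localize(None)
    jd = _to_jd_ut(idx)
    sun_alt = _sun_altitude_jd(jd, site.latitude, site.longitude)
    phases = _classify_jd(site, jd)
    m_alt = _moon_topo_altitude_jd(jd, site.latitude, site.longitude)
    frac = _illuminated_fraction_jd(jd)
    frac = np.clip(frac, 0.0, 1.0)
    intensity = np.where(
        frac < _INTENSITY_LOW_BOUND,
        MoonIntensity.LOW.value,
        np.where(
            frac <= _INTENSITY_HIGH_BOUND,
            MoonIntensity.MEDIUM.value,
            MoonIntensity.HIGH.value,
        ),
    )
    nights = [night_id(site, ts.to_pydatetime().replace(tzinfo=timezone.utc)) for ts in idx]
    return pd.DataFrame(
        {
            "timestamp": idx,
            "sun_altitude": sun_alt,
            "light_phase": [p.value for p in phases],
            "moon_altitude": m_alt,
            "moon_up": m_alt > 0.0,
            "moon_illumination": frac,
            "moon_intensity": intensity,
            "night": nights,
        }
    )
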