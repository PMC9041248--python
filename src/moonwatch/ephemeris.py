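"""Topocentric lunar ephemeris.

Analysis of moon-disk transits needs the moon's azimuth, altitude and
angular diameter as a function of wall time and site, accurate to a few
hundredths of a degree — far better than the 0.2 deg required to rotate
flight-direction references.  No ephemeris library is assumed: the
geocentric position comes from a truncated ELP-2000/82 periodic series
(the dominant ~30 longitude/distance and ~30 latitude terms, plus the
Venus/Jupiter/flattening additive terms), good to ~0.01 deg in longitude
and ~0.003 deg in latitude over several centuries around J2000.  Nutation
uses the four largest 1980-theory terms.  Diurnal parallax (up to ~1 deg)
is applied rigorously from the geodetic observer position; atmospheric
refraction is deliberately ignored (direction references, not pointing).

Times are UTC; Terrestrial Time is obtained with a low-order Delta-T
model adequate for 1980-2050.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from datetime import datetime, timezone

import numpy as np

__all__ = ["MoonPosition", "moon_topocentric", "julian_day"]

EARTH_RADIUS_KM = 6378.137
EARTH_FLATTENING = 1.0 / 298.257
MOON_RADIUS_KM = 1737.4

# Periodic terms for lunar longitude (1e-6 deg) and distance (1e-3 km);
# columns: multiples of (D, M, M', F), coeff_lon, coeff_dist.
_LR_TERMS = [
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
    (0, 1, -2, 0, -2689, -7003),
    (2, 0, -1, 2, -2602, 0),
    (2, -1, -2, 0, 2390, 10056),
    (1, 0, 1, 0, -2348, 6322),
    (2, -2, 0, 0, 2236, -9884),
]

# Periodic terms for lunar latitude (1e-6 deg).
_B_TERMS = [
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
    (0, 0, 0, 3, -1749),
    (0, 1, -1, 1, -1565),
    (1, 0, 0, 1, -1491),
    (0, 1, 1, 1, -1475),
    (0, 1, 1, -1, -1410),
    (0, 1, 0, -1, -1344),
    (1, 0, 0, -1, -1335),
    (0, 0, 3, 1, 1107),
    (4, 0, 0, -1, 1021),
    (4, 0, -1, 1, 833),
]


@dataclass(frozen=True)
class MoonPosition:
    """Topocentric lunar position at one instant."""

    azimuth_deg: float  # compass, clockwise from north
    altitude_deg: float  # above horizon, refraction-free
    angular_diameter_deg: float
    distance_km: float  # topocentric


def julian_day(t: datetime | float) -> float:
    """Julian day (UT) from an aware/naive-UTC datetime or unix seconds."""
    if isinstance(t, datetime):
        if t.tzinfo is None:
            t = t.replace(tzinfo=timezone.utc)
        unix = t.timestamp()
    else:
        unix = float(t)
    return 2440587.5 + unix / 86400.0


def _delta_t_seconds(jd: float) -> float:
    # Espenak & Meeus polynomial pieces; crude outside 1980-2050 but the
    # moon moves only 0.55 deg/h so tens of seconds of Delta-T are ~0.005 deg.
    y = 2000.0 + (jd - 2451545.0) / 365.25
    t = y - 2000.0
    if y < 2005.0:
        return 63.86 + 0.3345 * t - 0.060374 * t**2 + 0.0017275 * t**3
    return 62.92 + 0.32217 * t + 0.005589 * t**2


def _moon_geocentric_ecliptic(jd_tt: float) -> tuple[float, float, float]:
    """Geocentric ecliptic lon/lat (deg, of date) and distance (km)."""
    T = (jd_tt - 2451545.0) / 36525.0
    Lp = 218.3164477 + 481267.88123421 * T - 0.0015786 * T**2 + T**3 / 538841 - T**4 / 65194000
    D = 297.8501921 + 445267.1114034 * T - 0.0018819 * T**2 + T**3 / 545868 - T**4 / 113065000
    M = 357.5291092 + 35999.0502909 * T - 0.0001536 * T**2 + T**3 / 24490000
    Mp = 134.9633964 + 477198.8675055 * T + 0.0087414 * T**2 + T**3 / 69699 - T**4 / 14712000
    F = 93.2720950 + 483202.0175233 * T - 0.0036539 * T**2 - T**3 / 3526000 + T**4 / 863310000
    E = 1.0 - 0.002516 * T - 0.0000074 * T**2

    rad = math.radians
    sum_l = 0.0
    sum_r = 0.0
    for d, m, mp, f, cl, cr in _LR_TERMS:
        arg = rad(d * D + m * M + mp * Mp + f * F)
        e = E ** abs(m)
        sum_l += cl * e * math.sin(arg)
        sum_r += cr * e * math.cos(arg)
    sum_b = 0.0
    for d, m, mp, f, cb in _B_TERMS:
        arg = rad(d * D + m * M + mp * Mp + f * F)
        sum_b += cb * (E ** abs(m)) * math.sin(arg)

    # additive terms: Venus (A1), Jupiter (A2), Earth-flattening (A3)
    A1 = 119.75 + 131.849 * T
    A2 = 53.09 + 479264.290 * T
    A3 = 313.45 + 481266.484 * T
    sum_l += 3958 * math.sin(rad(A1)) + 1962 * math.sin(rad(Lp - F)) + 318 * math.sin(rad(A2))
    sum_b += (
        -2235 * math.sin(rad(Lp))
        + 382 * math.sin(rad(A3))
        + 175 * math.sin(rad(A1 - F))
        + 175 * math.sin(rad(A1 + F))
        + 127 * math.sin(rad(Lp - Mp))
        - 115 * math.sin(rad(Lp + Mp))
    )

    lon = (Lp + sum_l / 1e6) % 360.0
    lat = sum_b / 1e6
    dist = 385000.56 + sum_r / 1e3
    return lon, lat, dist


def _nutation(jd_tt: float) -> tuple[float, float]:
    """(dpsi, deps) in degrees — four largest 1980-theory terms."""
    T = (jd_tt - 2451545.0) / 36525.0
    om = math.radians(125.04452 - 1934.136261 * T)
    ls = math.radians(280.4665 + 36000.7698 * T)
    lm = math.radians(218.3165 + 481267.8813 * T)
    dpsi = (-17.20 * math.sin(om) - 1.32 * math.sin(2 * ls)
            - 0.23 * math.sin(2 * lm) + 0.21 * math.sin(2 * om)) / 3600.0
    deps = (9.20 * math.cos(om) + 0.57 * math.cos(2 * ls)
            + 0.10 * math.cos(2 * lm) - 0.09 * math.cos(2 * om)) / 3600.0
    return dpsi, deps


def _gmst_deg(jd_ut: float) -> float:
    d = jd_ut - 2451545.0
    T = d / 36525.0
    return (280.46061837 + 360.98564736629 * d + 0.000387933 * T**2 - T**3 / 38710000) % 360.0


def moon_topocentric(t: datetime | float, latitude_deg: float, longitude_deg: float) -> MoonPosition:
    """Topocentric moon azimuth/altitude/angular diameter for a site.

    Parameters
    ----------
    t
        UTC wall time — aware/naive-UTC :class:`~datetime.datetime` or
        unix seconds.
    latitude_deg, longitude_deg
        Geodetic site coordinates; east longitude positive.
    """
    jd_ut = julian_day(t)
    jd_tt = jd_ut + _delta_t_seconds(jd_ut) / 86400.0
    T = (jd_tt - 2451545.0) / 36525.0

    lon, lat, dist = _moon_geocentric_ecliptic(jd_tt)
    dpsi, deps = _nutation(jd_tt)
    lon += dpsi  # apparent longitude
    eps = math.radians(23.43929111 - 0.01300417 * T - 1.64e-7 * T**2 + deps)

    # geocentric rectangular, equatorial frame of date (km)
    lam, bet = math.radians(lon), math.radians(lat)
    x = dist * math.cos(bet) * math.cos(lam)
    y_ecl = dist * math.cos(bet) * math.sin(lam)
    z_ecl = dist * math.sin(bet)
    y = y_ecl * math.cos(eps) - z_ecl * math.sin(eps)
    z = y_ecl * math.sin(eps) + z_ecl * math.cos(eps)

    # observer geocentric position (geodetic latitude, Earth flattening)
    gast = _gmst_deg(jd_ut) + dpsi * math.cos(eps)
    lst = math.radians((gast + longitude_deg) % 360.0)
    phi = math.radians(latitude_deg)
    u = math.atan((1.0 - EARTH_FLATTENING) * math.tan(phi))
    ox = EARTH_RADIUS_KM * math.cos(u) * math.cos(lst)
    oy = EARTH_RADIUS_KM * math.cos(u) * math.sin(lst)
    oz = EARTH_RADIUS_KM * (1.0 - EARTH_FLATTENING) * math.sin(u)

    # topocentric vector -> apparent RA/Dec -> alt/az
    dx, dy, dz = x - ox, y - oy, z - oz
    d_top = math.sqrt(dx * dx + dy * dy + dz * dz)
    ra = math.atan2(dy, dx)
    dec = math.asin(dz / d_top)
    H = lst - ra  # hour angle, positive west

    sin_alt = math.sin(phi) * math.sin(dec) + math.cos(phi) * math.cos(dec) * math.cos(H)
    alt = math.asin(max(-1.0, min(1.0, sin_alt)))
    az = math.atan2(
        -math.cos(dec) * math.sin(H),
        math.sin(dec) * math.cos(phi) - math.cos(dec) * math.cos(H) * math.sin(phi),
    )

    diameter = 2.0 * math.degrees(math.asin(MOON_RADIUS_KM / d_top))
    return MoonPosition(
        azimuth_deg=math.degrees(az) % 360.0,
        altitude_deg=math.degrees(alt),
        angular_diameter_deg=diameter,
        distance_km=d_top,
    )
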