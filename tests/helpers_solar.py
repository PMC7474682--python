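"""Independent reference ephemeris for sunrise/sunset tests.

Uses the Astronomical Almanac low-precision solar position (mean longitude /
mean anomaly -> ecliptic longitude -> RA/declination) together with GMST to
evaluate the solar elevation on a minute grid and locate the -0.833 deg
crossings by linear interpolation.  Deliberately a different formulation
from the package's NOAA/Spencer implementation.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

SUNRISE_ELEVATION_DEG = -0.833


def _sun_ra_dec(jd: float) -> tuple[float, float]:
    n = jd - 2451545.0
    L = math.radians((280.460 + 0.9856474 * n) % 360.0)
    g = math.radians((357.528 + 0.9856003 * n) % 360.0)
    lam = L + math.radians(1.915) * math.sin(g) + math.radians(0.020) * math.sin(2 * g)
    eps = math.radians(23.439 - 0.0000004 * n)
    alpha = math.atan2(math.cos(eps) * math.sin(lam), math.cos(lam))
    delta = math.asin(math.sin(eps) * math.sin(lam))
    return alpha, delta


def solar_elevation_deg(latitude: float, longitude: float, t: pd.Timestamp) -> float:
    jd = pd.Timestamp(t).to_julian_date()
    alpha, delta = _sun_ra_dec(jd)
    gmst_h = (18.697374558 + 24.06570982441908 * (jd - 2451545.0)) % 24.0
    lha = math.radians((gmst_h * 15.0 + longitude) % 360.0) - alpha
    lat = math.radians(latitude)
    sin_el = math.sin(lat) * math.sin(delta) + math.cos(lat) * math.cos(delta) * math.cos(lha)
    return math.degrees(math.asin(max(-1.0, min(1.0, sin_el))))


def reference_sun_events(
    latitude: float, longitude: float, date
) -> tuple[pd.Timestamp, pd.Timestamp]:
    """(sunrise, sunset) by minute-scan + interpolation of the elevation.

    Scans the *local solar* day (local apparent noon +/- 12 h) so events
    match the per-calendar-date convention of the NOAA-style formulas at any
    longitude.
    """
    day = pd.Timestamp(date).normalize()
    noon_utc = day + pd.Timedelta(hours=12.0 - longitude / 15.0)
    times = pd.date_range(
        noon_utc - pd.Timedelta(hours=12), noon_utc + pd.Timedelta(hours=12), freq="1min"
    )
    el = np.array([solar_elevation_deg(latitude, longitude, t) for t in times])
    above = el > SUNRISE_ELEVATION_DEG
    sunrise = sunset = None
    for i in range(len(times) - 1):
        if not above[i] and above[i + 1]:
            frac = (SUNRISE_ELEVATION_DEG - el[i]) / (el[i + 1] - el[i])
            sunrise = times[i] + frac * pd.Timedelta(minutes=1)
        elif above[i] and not above[i + 1]:
            frac = (el[i] - SUNRISE_ELEVATION_DEG) / (el[i] - el[i + 1])
            sunset = times[i] + frac * pd.Timedelta(minutes=1)
    if sunrise is None or sunset is None:
        raise ValueError("no sunrise/sunset on this date (polar day or night?)")
    return sunrise, sunset
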