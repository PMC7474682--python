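"""Sunrise/sunset computation and sunrise-to-sunrise diel cycle segmentation.

Sun event times come from the NOAA solar-position equations (Spencer Fourier
series for declination and the equation of time, hour angle at the standard
-0.833 deg solar elevation).  All timestamps are naive UTC; ``utc_offset`` is
only used downstream when clock-hour (local time) figures are needed.
"""

from __future__ import annotations

import datetime as dt
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

#: solar zenith angle at sunrise/sunset: 90 deg + refraction + solar radius
SUN_ZENITH_DEG = 90.833

#: latitudes poleward of this can have polar day/night and are unsupported
MAX_ABS_LATITUDE = 66.5


class PolarDayNightError(ValueError):
    """Raised when sunrise/sunset is undefined (polar day or night)."""


@dataclass(frozen=True)
class DielCycle:
    """One sunrise-to-sunrise interval with its sunset and light period."""

    lake_id: str
    cycle_index: int
    t_sunrise: pd.Timestamp
    t_sunset: pd.Timestamp
    t_next_sunrise: pd.Timestamp
    light_period_h: float

    def __post_init__(self) -> None:
        if not (self.t_sunrise < self.t_sunset < self.t_next_sunrise):
            raise ValueError(
                f"cycle {self.cycle_index}: require sunrise < sunset < next sunrise"
            )
        if not 0.0 < self.light_period_h < 24.0:
            raise ValueError("light_period_h must lie in (0, 24)")

    @property
    def duration_h(self) -> float:
        return (self.t_next_sunrise - self.t_sunrise) / pd.Timedelta(hours=1)

    @property
    def dark_period_h(self) -> float:
        return (self.t_next_sunrise - self.t_sunset) / pd.Timedelta(hours=1)

    def contains(self, t: pd.Timestamp) -> bool:
        return self.t_sunrise <= t < self.t_next_sunrise

    def is_day(self, t: pd.Timestamp) -> bool:
        return self.t_sunrise <= t < self.t_sunset


def _solar_terms(jd: float) -> tuple[float, float]:
    """Equation of time [min] and solar declination [rad] at a Julian date.

    NOAA solar-calculator formulation (Julian centuries from J2000).
    """
    jc = (jd - 2451545.0) / 36525.0
    l0 = math.radians((280.46646 + jc * (36000.76983 + 0.0003032 * jc)) % 360.0)
    m = math.radians(357.52911 + jc * (35999.05029 - 0.0001537 * jc))
    ecc = 0.016708634 - jc * (0.000042037 + 0.0000001267 * jc)
    center = (
        math.sin(m) * (1.914602 - jc * (0.004817 + 0.000014 * jc))
        + math.sin(2 * m) * (0.019993 - 0.000101 * jc)
        + math.sin(3 * m) * 0.000289
    )
    true_long = math.degrees(l0) + center
    omega = math.radians(125.04 - 1934.136 * jc)
    app_long = math.radians(true_long - 0.00569 - 0.00478 * math.sin(omega))
    obliq0 = 23.0 + (26.0 + (21.448 - jc * (46.815 + jc * (0.00059 - jc * 0.001813))) / 60.0) / 60.0
    obliq = math.radians(obliq0 + 0.00256 * math.cos(omega))
    decl = math.asin(math.sin(obliq) * math.sin(app_long))
    var_y = math.tan(obliq / 2.0) ** 2
    eqtime = 4.0 * math.degrees(
        var_y * math.sin(2 * l0)
        - 2.0 * ecc * math.sin(m)
        + 4.0 * ecc * var_y * math.sin(m) * math.cos(2 * l0)
        - 0.5 * var_y * var_y * math.sin(4 * l0)
        - 1.25 * ecc * ecc * math.sin(2 * m)
    )
    return eqtime, decl


def _event_minutes_utc(
    latitude: float, longitude: float, jd_midnight: float, hour_guess: float, rising: bool
) -> float:
    eqtime, decl = _solar_terms(jd_midnight + hour_guess / 24.0)
    lat = math.radians(latitude)
    cos_ha = math.cos(math.radians(SUN_ZENITH_DEG)) / (
        math.cos(lat) * math.cos(decl)
    ) - math.tan(lat) * math.tan(decl)
    if abs(cos_ha) > 1.0:
        kind = "polar day" if cos_ha < -1.0 else "polar night"
        raise PolarDayNightError(
            f"{kind} at latitude {latitude:.2f} on day-of-year {day_of_year}: "
            "sunrise/sunset undefined"
        )
    ha_deg = math.degrees(math.acos(cos_ha))
    if not rising:
        ha_deg = -ha_deg
    return 720.0 - 4.0 * (longitude + ha_deg) - eqtime


def sun_events(
    latitude: float,
    longitude: float,
    date: dt.date | str | pd.Timestamp,
    utc_offset: float = 0.0,
) -> tuple[pd.Timestamp, pd.Timestamp]:
    """Sunrise and sunset (UTC) for the given calendar date.

    Parameters
    ----------
    latitude, longitude
        Degrees; longitude positive east.  ``|latitude|`` must be below
        :data:`MAX_ABS_LATITUDE`.
    date
        Calendar date the events belong to (UTC-referenced day).
    utc_offset
        Accepted for interface symmetry; events are always returned in UTC.

    Returns
    -------
    (sunrise, sunset) : tuple of pandas.Timestamp
    """
    if not -90.0 <= latitude <= 90.0:
        raise ValueError(f"latitude {latitude} out of range [-90, 90]")
    if not -180.0 <= longitude <= 180.0:
        raise ValueError(f"longitude {longitude} out of range [-180, 180]")
    if abs(latitude) >= MAX_ABS_LATITUDE:
        raise PolarDayNightError(
            f"latitude {latitude:.2f} is poleward of {MAX_ABS_LATITUDE} deg; "
            "polar day/night is unsupported"
        )
    date = pd.Timestamp(date).normalize()
    jd_midnight = date.to_julian_date()

    events = []
    for rising in (True, False):
        # one refinement pass: re-evaluate the slowly varying solar terms at
        # the first-pass event time instead of local noon
        minutes = _event_minutes_utc(latitude, longitude, jd_midnight, 12.0, rising)
        minutes = _event_minutes_utc(
            latitude, longitude, jd_midnight, minutes / 60.0, rising
        )
        events.append(date + pd.Timedelta(minutes=minutes))
    sunrise, sunset = events
    return sunrise, sunset


def build_cycles(
    lake,
    span: tuple[pd.Timestamp | str, pd.Timestamp | str],
) -> list[DielCycle]:
    """Segment ``span`` into consecutive sunrise-to-sunrise diel cycles.

    ``lake`` needs ``lake_id``, ``latitude`` and ``longitude`` attributes.
    Cycles run from the first sunrise at or after the span start to the last
    sunrise at or before the span end, tiling the interval with no gaps.
    """
    t0, t1 = (pd.Timestamp(t) for t in span)
    if t1 <= t0:
        raise ValueError("span end must be after span start")

    day = pd.Timedelta(days=1)
    date = (t0 - day).normalize()
    sunrises: list[pd.Timestamp] = []
    sunsets: dict[pd.Timestamp, pd.Timestamp] = {}
    while date <= (t1 + day).normalize():
        rise, set_ = sun_events(lake.latitude, lake.longitude, date)
        if t0 <= rise <= t1:
            sunrises.append(rise)
            sunsets[rise] = set_
        date += day

    cycles: list[DielCycle] = []
    for i, (rise, next_rise) in enumerate(zip(sunrises, sunrises[1:])):
        set_ = sunsets[rise]
        cycles.append(
            DielCycle(
                lake_id=lake.lake_id,
                cycle_index=i,
                t_sunrise=rise,
                t_sunset=set_,
                t_next_sunrise=next_rise,
                light_period_h=(set_ - rise) / pd.Timedelta(hours=1),
            )
        )
    if not cycles:
        warnings.warn(
            f"span {t0}..{t1} is shorter than one full diel cycle for lake "
            f"{lake.lake_id}; no cycles built",
            stacklevel=2,
        )
    return cycles


def _overlap_h(
    a0: pd.Timestamp, a1: pd.Timestamp, b0: pd.Timestamp, b1: pd.Timestamp
) -> float:
    lo, hi = max(a0, b0), min(a1, b1)
    if hi <= lo:
        return 0.0
    return (hi - lo) / pd.Timedelta(hours=1)


def split_day_night(
    t_start: pd.Timestamp, t_end: pd.Timestamp, cycle: DielCycle
) -> tuple[float, float]:
    """Hours of ``[t_start, t_end]`` overlapping the cycle's day and night."""
    t_start, t_end = pd.Timestamp(t_start), pd.Timestamp(t_end)
    if t_end < t_start:
        raise ValueError("t_end before t_start")
    day = _overlap_h(t_start, t_end, cycle.t_sunrise, cycle.t_sunset)
    night = _overlap_h(t_start, t_end, cycle.t_sunset, cycle.t_next_sunrise)
    return day, night


def assign_day_night(flux, cycle: DielCycle) -> tuple[float, float]:
    """Day/night overlap hours for a flux record (``t_start``/``t_end``)."""
    return split_day_night(flux.t_start, flux.t_end, cycle)


def cycles_frame(cycles: list[DielCycle]) -> pd.DataFrame:
    """Tabular view of cycles (one row per cycle) for CSV export."""
    return pd.DataFrame(
        {
            "lake_id": [c.lake_id for c in cycles],
            "cycle_index": [c.cycle_index for c in cycles],
            "sunrise": [c.t_sunrise for c in cycles],
            "sunset": [c.t_sunset for c in cycles],
            "next_sunrise": [c.t_next_sunrise for c in cycles],
            "light_period_h": [c.light_period_h for c in cycles],
        }
    )


def find_cycle(cycles: list[DielCycle], t: pd.Timestamp) -> DielCycle | None:
    for c in cycles:
        if c.contains(t):
            return c
    return None
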