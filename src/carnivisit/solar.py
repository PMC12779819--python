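"""Sunrise/sunset and day/night classification from solar position.

Implements the NOAA solar-position equations (fractional-year Fourier
expansions for the equation of time and solar declination, zenith 90.833
degrees for rise/set so that atmospheric refraction and the solar radius
are accounted for). Accuracy is about one minute at mid-latitudes, which
is ample for classifying wildlife reports as daytime or nighttime.
"""

from __future__ import annotations

import datetime as dt
import math
from typing import Optional, Tuple

#: Solar zenith angle defining sunrise/sunset (sun centre at -0.833 deg).
RISE_SET_ZENITH_DEG = 90.833


def _fractional_year(t_utc: dt.datetime) -> float:
    doy = t_utc.timetuple().tm_yday
    hours = t_utc.hour + t_utc.minute / 60.0 + t_utc.second / 3600.0
    return 2.0 * math.pi / 365.0 * (doy - 1 + (hours - 12.0) / 24.0)


def _equation_of_time_min(gamma: float) -> float:
    return 229.18 * (0.000075
                     + 0.001868 * math.cos(gamma)
                     - 0.032077 * math.sin(gamma)
                     - 0.014615 * math.cos(2 * gamma)
                     - 0.040849 * math.sin(2 * gamma))


def _declination_rad(gamma: float) -> float:
    return (0.006918
            - 0.399912 * math.cos(gamma) + 0.070257 * math.sin(gamma)
            - 0.006758 * math.cos(2 * gamma) + 0.000907 * math.sin(2 * gamma)
            - 0.002697 * math.cos(3 * gamma) + 0.00148 * math.sin(3 * gamma))


def solar_elevation_deg(t: dt.datetime, lon: float, lat: float) -> float:
    """Solar elevation angle (degrees) at a timezone-aware instant."""
    t_utc = _to_utc(t)
    gamma = _fractional_year(t_utc)
    eqtime = _equation_of_time_min(gamma)
    decl = _declination_rad(gamma)
    minutes = t_utc.hour * 60.0 + t_utc.minute + t_utc.second / 60.0
    tst = minutes + eqtime + 4.0 * lon  # true solar time, minutes
    ha = math.radians(tst / 4.0 - 180.0)  # hour angle
    phi = math.radians(lat)
    cos_zen = (math.sin(phi) * math.sin(decl)
               + math.cos(phi) * math.cos(decl) * math.cos(ha))
    cos_zen = min(1.0, max(-1.0, cos_zen))
    return 90.0 - math.degrees(math.acos(cos_zen))


def sun_events_utc(date: dt.date, lon: float, lat: float
                   ) -> Optional[Tuple[dt.datetime, dt.datetime]]:
    """Sunrise and sunset (UTC) for a calendar date at (lon, lat).

    Returns None during polar day or polar night (the sun never crosses
    the rise/set zenith on that date).
    """
    noon = dt.datetime(date.year, date.month, date.day, 12, tzinfo=dt.timezone.utc)
    gamma = _fractional_year(noon)
    eqtime = _equation_of_time_min(gamma)
    decl = _declination_rad(gamma)
    phi = math.radians(lat)
    cos_ha = (math.cos(math.radians(RISE_SET_ZENITH_DEG))
              / (math.cos(phi) * math.cos(decl))
              - math.tan(phi) * math.tan(decl))
    if cos_ha < -1.0 or cos_ha > 1.0:
        return None
    ha_deg = math.degrees(math.acos(cos_ha))
    sunrise_min = 720.0 - 4.0 * (lon + ha_deg) - eqtime
    sunset_min = 720.0 - 4.0 * (lon - ha_deg) - eqtime
    midnight = dt.datetime(date.year, date.month, date.day, tzinfo=dt.timezone.utc)
    return (midnight + dt.timedelta(minutes=sunrise_min),
            midnight + dt.timedelta(minutes=sunset_min))


def classify_daynight(timestamp: dt.datetime, lon: float, lat: float) -> str:
    """Classify an instant as ``"day"`` or ``"night"``.

    Day iff the timestamp falls in [sunrise, sunset) for that location on
    the local calendar date of the timestamp. Under polar day/night the
    sign of the solar elevation decides.
    """
    t_utc = _to_utc(timestamp)
    # Rise/set pairs are anchored to UTC dates; near the antimeridian the
    # instant may belong to the solar day of an adjacent UTC date, so test
    # membership in the daylight interval of all three candidates.
    found_any = False
    for offset in (-1, 0, 1):
        events = sun_events_utc(t_utc.date() + dt.timedelta(days=offset),
                                lon, lat)
        if events is None:
            continue
        found_any = True
        sunrise, sunset = events
        if sunrise <= t_utc < sunset:
            return "day"
    if not found_any:  # polar day or night
        return "day" if solar_elevation_deg(timestamp, lon, lat) > 0 else "night"
    return "night"


def _to_utc(t: dt.datetime) -> dt.datetime:
    if t.tzinfo is None:
        raise ValueError("timestamp must be timezone-aware")
    return t.astimezone(dt.timezone.utc)
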