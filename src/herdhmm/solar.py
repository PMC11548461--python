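"""Sunrise and sunset from the NOAA solar-position equations.

Used to split fixes into day and night relative to the sun at the survey's
geographic centre.  Accuracy of the NOAA low-precision algorithm is a couple
of minutes, ample for labelling 30-min fixes.  Valid for |latitude| <= 60
degrees; the polar day/night cases a tropical cattle survey never meets are
rejected rather than handled.
"""

from __future__ import annotations

import datetime as dt

import numpy as np

_ZENITH_OFFICIAL_DEG = 90.833  # refraction + solar radius


def _fractional_year(when: dt.datetime) -> float:
    doy = when.timetuple().tm_yday
    hours = when.hour + when.minute / 60.0 + when.second / 3600.0
    year_len = 366 if when.year % 4 == 0 and (when.year % 100 != 0 or when.year % 400 == 0) else 365
    return 2.0 * np.pi / year_len * (doy - 1 + (hours - 12.0) / 24.0)


def equation_of_time_min(when: dt.datetime) -> float:
    """Equation of time in minutes (apparent minus mean solar time)."""
    g = _fractional_year(when)
    return 229.18 * (
        0.000075
        + 0.001868 * np.cos(g)
        - 0.032077 * np.sin(g)
        - 0.014615 * np.cos(2 * g)
        - 0.040849 * np.sin(2 * g)
    )


def solar_declination_rad(when: dt.datetime) -> float:
    g = _fractional_year(when)
    return (
        0.006918
        - 0.399912 * np.cos(g)
        + 0.070257 * np.sin(g)
        - 0.006758 * np.cos(2 * g)
        + 0.000907 * np.sin(2 * g)
        - 0.002697 * np.cos(3 * g)
        + 0.00148 * np.sin(3 * g)
    )


def sunrise_sunset_utc(date: dt.date, lat: float, lon: float) -> tuple[dt.datetime, dt.datetime]:
    """Sunrise and sunset instants (UTC, tz-naive) for a calendar date.

    ``lon`` follows the geographic convention: positive east.
    """
    if abs(lat) > 60.0:
        raise ValueError(f"latitude {lat} outside supported band (|lat| <= 60)")
    noon_guess = dt.datetime(date.year, date.month, date.day, 12)
    decl = solar_declination_rad(noon_guess)
    eqt = equation_of_time_min(noon_guess)
    phi = np.radians(lat)
    cos_ha = (
        np.cos(np.radians(_ZENITH_OFFICIAL_DEG)) / (np.cos(phi) * np.cos(decl))
        - np.tan(phi) * np.tan(decl)
    )
    if not -1.0 <= cos_ha <= 1.0:
        raise ValueError("sun never rises/sets on this date at this latitude")
    ha_deg = np.degrees(np.arccos(cos_ha))
    # minutes after 00:00 UTC
    sunrise_min = 720.0 - 4.0 * (lon + ha_deg) - eqt
    sunset_min = 720.0 - 4.0 * (lon - ha_deg) - eqt
    day0 = dt.datetime(date.year, date.month, date.day)
    return (
        day0 + dt.timedelta(minutes=float(sunrise_min)),
        day0 + dt.timedelta(minutes=float(sunset_min)),
    )


def is_daytime(when: dt.datetime, lat: float, lon: float) -> bool:
    """True iff sunrise <= when (UTC) < sunset at the given location."""
    rise, set_ = sunrise_sunset_utc(when.date(), lat, lon)
    return rise <= when < set_
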