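"""Compact solar-position routine (NOAA spreadsheet algorithm).

Gives the sun's altitude above the horizon for a UTC time and WGS84
position, accurate to ~0.1 degrees over the satellite-tag era — ample for
splitting dives into day and night.  Atmospheric refraction is ignored
(it moves the terminator crossing by ~3 minutes).
"""

from __future__ import annotations

import numpy as np

_UNIX_JD0 = 2440587.5  # Julian day of 1970-01-01T00:00Z


def solar_altitude_deg(epoch_s, lat_deg, lon_deg):
    """Solar altitude (degrees) at UTC epoch seconds; vectorised."""
    t_epoch = np.asarray(epoch_s, dtype=float)
    lat = np.radians(np.asarray(lat_deg, dtype=float))
    lon = np.asarray(lon_deg, dtype=float)

    jd = _UNIX_JD0 + t_epoch / 86400.0
    t = (jd - 2451545.0) / 36525.0  # Julian centuries from J2000

    l0 = np.mod(280.46646 + t * (36000.76983 + 0.0003032 * t), 360.0)
    m = np.radians(357.52911 + t * (35999.05029 - 0.0001537 * t))
    ecc = 0.016708634 - t * (0.000042037 + 0.0000001267 * t)
    c = (np.sin(m) * (1.914602 - t * (0.004817 + 0.000014 * t))
         + np.sin(2 * m) * (0.019993 - 0.000101 * t)
         + np.sin(3 * m) * 0.000289)
    true_lon = l0 + c
    omega = np.radians(125.04 - 1934.136 * t)
    app_lon = np.radians(true_lon - 0.00569 - 0.00478 * np.sin(omega))

    obliq0 = 23.0 + (26.0 + (21.448 - t * (46.815 + t * (0.00059 - t * 0.001813))) / 60.0) / 60.0
    obliq = np.radians(obliq0 + 0.00256 * np.cos(omega))

    decl = np.arcsin(np.sin(obliq) * np.sin(app_lon))

    y = np.tan(obliq / 2.0) ** 2
    l0r, mr = np.radians(l0), m
    eqtime_min = 4.0 * np.degrees(
        y * np.sin(2 * l0r) - 2 * ecc * np.sin(mr)
        + 4 * ecc * y * np.sin(mr) * np.cos(2 * l0r)
        - 0.5 * y * y * np.sin(4 * l0r) - 1.25 * ecc * ecc * np.sin(2 * mr))

    minutes_utc = np.mod(t_epoch, 86400.0) / 60.0
    true_solar_min = np.mod(minutes_utc + eqtime_min + 4.0 * lon, 1440.0)
    ha = np.radians(true_solar_min / 4.0 - 180.0)

    sin_alt = np.sin(lat) * np.sin(decl) + np.cos(lat) * np.cos(decl) * np.cos(ha)
    return np.degrees(np.arcsin(np.clip(sin_alt, -1.0, 1.0)))
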