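"""Solar elevation via the NOAA solar-position equations.

Used only for the day/night split of behavioural time budgets: a fix is
"day" when the solar elevation at its position and UTC time exceeds the
standard refraction-corrected horizon at -0.833 degrees.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

HORIZON_DEG = -0.833


def solar_elevation(times, lat, lon) -> np.ndarray:
    """Solar elevation angle in degrees at UTC instants and positions."""
    t = pd.DatetimeIndex(np.atleast_1d(np.asarray(times, dtype="datetime64[ns]")))
    lat = np.broadcast_to(np.radians(np.asarray(lat, dtype=float)), t.shape)
    lon = np.broadcast_to(np.asarray(lon, dtype=float), t.shape)

    # Julian century from J2000
    jd = t.to_julian_date().values
    jc = (jd - 2451545.0) / 36525.0

    gml = (280.46646 + jc * (36000.76983 + jc * 0.0003032)) % 360.0
    gma = 357.52911 + jc * (35999.05029 - 0.0001537 * jc)
    ecc = 0.016708634 - jc * (0.000042037 + 0.0000001267 * jc)
    ctr = (
        np.sin(np.radians(gma)) * (1.914602 - jc * (0.004817 + 0.000014 * jc))
        + np.sin(np.radians(2 * gma)) * (0.019993 - 0.000101 * jc)
        + np.sin(np.radians(3 * gma)) * 0.000289
    )
    true_long = gml + ctr
    app_long = true_long - 0.00569 - 0.00478 * np.sin(
        np.radians(125.04 - 1934.136 * jc)
    )
    mean_obliq = 23.0 + (26.0 + (21.448 - jc * (46.815 + jc * (0.00059 - jc * 0.001813))) / 60.0) / 60.0
    obliq = mean_obliq + 0.00256 * np.cos(np.radians(125.04 - 1934.136 * jc))
    decl = np.arcsin(
        np.sin(np.radians(obliq)) * np.sin(np.radians(app_long))
    )

    vary = np.tan(np.radians(obliq / 2.0)) ** 2
    eqtime = 4.0 * np.degrees(
        vary * np.sin(2 * np.radians(gml))
        - 2 * ecc * np.sin(np.radians(gma))
        + 4 * ecc * vary * np.sin(np.radians(gma)) * np.cos(2 * np.radians(gml))
        - 0.5 * vary**2 * np.sin(4 * np.radians(gml))
        - 1.25 * ecc**2 * np.sin(2 * np.radians(gma))
    )

    minutes = (
        t.hour.values * 60.0
        + t.minute.values
        + t.second.values / 60.0
        + t.microsecond.values / 6e7
    )
    tst = (minutes + eqtime + 4.0 * lon) % 1440.0
    ha = np.radians(tst / 4.0 - 180.0)
    elev = np.arcsin(
        np.sin(lat) * np.sin(decl) + np.cos(lat) * np.cos(decl) * np.cos(ha)
    )
    return np.degrees(elev)


def is_day(times, lat, lon, horizon_deg: float = HORIZON_DEG) -> np.ndarray:
    """Boolean day mask: solar elevation above the given horizon."""
    return solar_elevation(times, lat, lon) > horizon_deg
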