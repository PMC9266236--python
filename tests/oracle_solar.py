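"""Independent solar-position reference: Michalsky (1988) Astronomical
Almanac algorithm.

Used only as a cross-check oracle for the package's NOAA-style solar
zenith computation.  Different algorithm, different series expansions,
written from the published almanac formulas; stated accuracy ~0.01 deg
for 1950-2050.  No refraction correction (the package also reports
unrefracted zenith).
"""

import math

import numpy as np
import pandas as pd


def solar_zenith_michalsky(lat_deg, lon_deg, when_utc):
    """True (unrefracted) solar zenith angle in degrees.

    Parameters: latitude deg N, longitude deg E, UTC timestamp
    (anything pandas.Timestamp accepts).
    """
    t = pd.Timestamp(when_utc)
    # days since J2000.0 epoch (2000-01-01 12:00 UT)
    n = (t - pd.Timestamp("2000-01-01 12:00:00")) / pd.Timedelta(days=1)
    hour_ut = t.hour + t.minute / 60.0 + t.second / 3600.0

    # mean longitude and mean anomaly of the sun (deg)
    mnlong = (280.460 + 0.9856474 * n) % 360.0
    mnanom = math.radians((357.528 + 0.9856003 * n) % 360.0)

    # ecliptic longitude (deg -> rad) and obliquity (rad)
    eclong = (mnlong + 1.915 * math.sin(mnanom)
              + 0.020 * math.sin(2.0 * mnanom)) % 360.0
    eclong = math.radians(eclong)
    oblqec = math.radians(23.439 - 0.0000004 * n)

    # right ascension and declination
    num = math.cos(oblqec) * math.sin(eclong)
    den = math.cos(eclong)
    ra = math.atan2(num, den)  # rad, -pi..pi
    dec = math.asin(math.sin(oblqec) * math.sin(eclong))

    # Greenwich mean sidereal time (hours) -> local mean sidereal time
    gmst = (6.697375 + 0.0657098242 * n + hour_ut) % 24.0
    lmst = (gmst + lon_deg / 15.0) % 24.0

    # hour angle (rad, -pi..pi)
    ha = math.radians(lmst * 15.0) - ra
    ha = (ha + math.pi) % (2.0 * math.pi) - math.pi

    lat = math.radians(lat_deg)
    sin_el = (math.sin(dec) * math.sin(lat)
              + math.cos(dec) * math.cos(lat) * math.cos(ha))
    el = math.asin(min(1.0, max(-1.0, sin_el)))
    return 90.0 - math.degrees(el)


def solar_zenith_michalsky_many(lats, lons, times):
    """Vector convenience wrapper over the scalar almanac routine."""
    return np.array([solar_zenith_michalsky(la, lo, tt)
                     for la, lo, tt in zip(lats, lons, times)])
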