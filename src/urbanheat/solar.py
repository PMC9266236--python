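"""Solar zenith angle from the NOAA solar-position algorithm.

Implements the standard NOAA General Solar Position Calculations
(Julian century, geometric mean longitude/anomaly, equation of center,
apparent longitude, obliquity with nutation correction, equation of
time, hour angle).  Accuracy is a few hundredths of a degree over
1900-2100, far better than the 0.5 deg this pipeline needs.

Refraction is ignored: it matters only within ~0.6 deg of the horizon
and all radiative uses of the zenith are capped well above it.

All functions broadcast over numpy arrays; times are UTC.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["solar_zenith", "solar_zenith_grid", "hour_midpoint"]

_J2000 = np.datetime64("2000-01-01T12:00:00")


def _julian_century(times: np.ndarray) -> np.ndarray:
    """Julian centuries since J2000.0 for an array of datetime64[ns]."""
    days = (times - _J2000) / np.timedelta64(1, "D")
    return days / 36525.0


def _declination_eqtime(times: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Solar declination (radians) and equation of time (minutes)."""
    jc = _julian_century(times)

    geom_mean_long = np.deg2rad((280.46646 + jc * (36000.76983 + 0.0003032 * jc)) % 360.0)
    geom_mean_anom = np.deg2rad(357.52911 + jc * (35999.05029 - 0.0001537 * jc))
    ecc = 0.016708634 - jc * (0.000042037 + 0.0000001267 * jc)

    eq_center = (np.sin(geom_mean_anom) * (1.914602 - jc * (0.004817 + 0.000014 * jc))
                 + np.sin(2.0 * geom_mean_anom) * (0.019993 - 0.000101 * jc)
                 + np.sin(3.0 * geom_mean_anom) * 0.000289)
    true_long = np.rad2deg(geom_mean_long) + eq_center
    omega = np.deg2rad(125.04 - 1934.136 * jc)
    app_long = np.deg2rad(true_long - 0.00569 - 0.00478 * np.sin(omega))

    mean_obliq = 23.0 + (26.0 + (21.448 - jc * (46.815 + jc * (0.00059 - jc * 0.001813))) / 60.0) / 60.0
    obliq = np.deg2rad(mean_obliq + 0.00256 * np.cos(omega))

    decl = np.arcsin(np.sin(obliq) * np.sin(app_long))

    var_y = np.tan(obliq / 2.0) ** 2
    eqtime = 4.0 * np.rad2deg(
        var_y * np.sin(2.0 * geom_mean_long)
        - 2.0 * ecc * np.sin(geom_mean_anom)
        + 4.0 * ecc * var_y * np.sin(geom_mean_anom) * np.cos(2.0 * geom_mean_long)
        - 0.5 * var_y * var_y * np.sin(4.0 * geom_mean_long)
        - 1.25 * ecc * ecc * np.sin(2.0 * geom_mean_anom)
    )
    return decl, eqtime


def _to_datetime64(times) -> np.ndarray:
    arr = np.asarray(times)
    if not np.issubdtype(arr.dtype, np.datetime64):
        if arr.ndim == 0:
            arr = np.datetime64(pd.Timestamp(times.item() if hasattr(times, "item") else times), "ns")
        else:
            arr = pd.to_datetime(arr.ravel()).to_numpy(dtype="datetime64[ns]").reshape(arr.shape)
    arr = arr.astype("datetime64[ns]")
    years = arr.astype("datetime64[Y]").astype(int) + 1970
    if np.any(years < 1900) or np.any(years > 2100):
        raise ValueError("timestamps must fall within 1900-2100 "
                         "(solar algorithm validity range)")
    return arr


def solar_zenith(latitude, longitude, times):
    """Solar zenith angle in degrees (0 = overhead, >90 = sun below horizon).

    Parameters
    ----------
    latitude : float or array, degrees north, in [-90, 90].
    longitude : float or array, degrees east.
    times : datetime-like or array, UTC.

    Inputs broadcast against each other; the result has the broadcast shape.
    """
    lat = np.asarray(latitude, dtype=float)
    lon = np.asarray(longitude, dtype=float)
    if np.any(lat < -90.0) or np.any(lat > 90.0):
        raise ValueError("latitude out of range [-90, 90]")
    t64 = _to_datetime64(times)

    decl, eqtime = _declination_eqtime(t64)
    minutes = ((t64 - t64.astype("datetime64[D]")) / np.timedelta64(1, "m"))

    lat, lon, decl, eqtime, minutes = np.broadcast_arrays(
        lat, lon, decl, eqtime, np.asarray(minutes, dtype=float))

    true_solar_min = (minutes + eqtime + 4.0 * lon) % 1440.0
    ha = true_solar_min / 4.0
    ha = np.where(ha < 0.0, ha + 180.0, ha - 180.0)
    ha = np.deg2rad(ha)

    lat_r = np.deg2rad(lat)
    cos_zen = (np.sin(lat_r) * np.sin(decl)
               + np.cos(lat_r) * np.cos(decl) * np.cos(ha))
    cos_zen = np.clip(cos_zen, -1.0, 1.0)
    zen = np.rad2deg(np.arccos(cos_zen))
    if zen.ndim == 0:
        return float(zen)
    return zen


def solar_zenith_grid(latitudes, longitudes, times) -> np.ndarray:
    """Zenith on a (time, latitude, longitude) grid from 1-D coordinate axes."""
    lat = np.asarray(latitudes, dtype=float)[np.newaxis, :, np.newaxis]
    lon = np.asarray(longitudes, dtype=float)[np.newaxis, np.newaxis, :]
    t = pd.DatetimeIndex(times).to_numpy(dtype="datetime64[ns]")[:, np.newaxis, np.newaxis]
    return solar_zenith(lat, lon, t)


def hour_midpoint(times):
    """Shift hourly interval-start stamps to the interval midpoint.

    Hourly fields are treated as interval means stamped at the interval
    start; solar geometry for an interval is evaluated at its midpoint.
    """
    return pd.DatetimeIndex(times) + pd.Timedelta(minutes=30)
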