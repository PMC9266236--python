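"""Reading and validating meteorology files.

Accepts CF-style NetCDF with either the short variable names used
throughout this package (t2m, d2m, uwd, vwd, msdwswrt) or the common
ERA5 archive names (u10, v10, msdwswrf, ssrd, lsm/land_mask), checks
units attributes and converts where a safe conversion is known
(degC -> K, accumulated J m-2 -> mean W m-2).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import xarray as xr

__all__ = ["read_met_netcdf", "validate_met"]

# canonical name -> accepted aliases
_ALIASES = {
    "t2m": ("t2m", "2t", "temperature_2m"),
    "d2m": ("d2m", "2d", "dewpoint_2m"),
    "uwd": ("uwd", "u10", "10u"),
    "vwd": ("vwd", "v10", "10v"),
    "msdwswrt": ("msdwswrt", "msdwswrf", "ssrd", "swdown"),
    "lsm": ("lsm", "land_mask", "landmask"),
}

_COORD_ALIASES = {"latitude": ("latitude", "lat"), "longitude": ("longitude", "lon"),
                  "time": ("time",)}

_EXPECTED_UNITS = {
    "t2m": ("K", "kelvin"),
    "d2m": ("K", "kelvin"),
    "uwd": ("m s-1", "m s**-1", "m/s"),
    "vwd": ("m s-1", "m s**-1", "m/s"),
    "msdwswrt": ("W m-2", "W m**-2", "W/m2", "W/m^2"),
    "lsm": ("1", "(0 - 1)", "fraction", ""),
}


def _find(ds: xr.Dataset, canonical: str, aliases: tuple) -> str:
    for a in aliases:
        if a in ds.variables:
            return a
    raise KeyError(f"input file is missing required variable '{canonical}' "
                   f"(accepted names: {', '.join(aliases)})")


def _convert_units(da: xr.DataArray, canonical: str) -> xr.DataArray:
    units = str(da.attrs.get("units", "")).strip()
    if units in _EXPECTED_UNITS[canonical] or units == "":
        return da
    if canonical in ("t2m", "d2m") and units.lower() in ("degc", "c", "celsius"):
        out = da + 273.15
        out.attrs["units"] = "K"
        return out
    if canonical == "msdwswrt" and units in ("J m-2", "J m**-2", "J/m2"):
        # accumulated flux over the stamp interval -> interval-mean W/m2
        seconds = float(da.attrs.get("accumulation_period_s", 3600.0))
        out = da / seconds
        out.attrs["units"] = "W m-2"
        return out
    raise ValueError(f"variable '{canonical}' has units {units!r} with no "
                     "known conversion")


def validate_met(ds: xr.Dataset) -> xr.Dataset:
    """Check the dataset invariants shared by synthetic and real input:
    common grid/time coordinates, d2m <= t2m, non-negative flux."""
    for v in ("t2m", "d2m", "uwd", "vwd", "msdwswrt"):
        if v not in ds:
            raise KeyError(f"dataset is missing variable '{v}'")
        if ds[v].dims != ("time", "latitude", "longitude"):
            raise ValueError(f"variable '{v}' has dims {ds[v].dims}, expected "
                             "(time, latitude, longitude)")
    finite = np.isfinite(ds.t2m.values) & np.isfinite(ds.d2m.values)
    if np.any(ds.d2m.values[finite] > ds.t2m.values[finite] + 1e-6):
        raise ValueError("dewpoint exceeds air temperature somewhere")
    flux = ds.msdwswrt.values
    if np.any(flux[np.isfinite(flux)] < -1e-9):
        raise ValueError("negative short-wave flux")
    return ds


def read_met_netcdf(path) -> xr.Dataset:
    """Read a meteorology file into the canonical in-memory form.

    Returns a dataset with variables t2m, d2m, uwd, vwd, msdwswrt (plus
    lsm when present), coordinates (time, latitude, longitude), SI
    units, invariants validated.
    """
    ds = xr.open_dataset(path, engine="scipy").load()
    renames = {}
    for canon, aliases in _COORD_ALIASES.items():
        found = next((a for a in aliases if a in ds.dims or a in ds.coords), None)
        if found is None:
            raise KeyError(f"input file is missing coordinate '{canon}'")
        if found != canon:
            renames[found] = canon
    for canon, aliases in _ALIASES.items():
        if canon == "lsm" and not any(a in ds.variables for a in aliases):
            continue  # land mask is optional in the reader
        found = _find(ds, canon, aliases)
        if found != canon:
            renames[found] = canon
    ds = ds.rename(renames)
    for canon in _EXPECTED_UNITS:
        if canon in ds:
            ds[canon] = _convert_units(ds[canon], canon)
    ds["time"] = pd.DatetimeIndex(ds.time.values)
    return validate_met(ds)
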