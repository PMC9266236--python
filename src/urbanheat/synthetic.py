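"""Synthetic ERA5-like hourly meteorology with known statistical structure.

Generates the five raw fields the WBGT* pipeline consumes (t2m, d2m, uwd,
vwd, msdwswrt) plus a land mask, on a regular latitude-longitude grid at
hourly resolution, so every downstream stage can be exercised offline
with controlled warming offsets, diurnal cycles and noise.

The generator targets the *statistical* structure the analysis needs —
a sinusoidal diurnal temperature cycle peaking in the early afternoon
(local solar time), dewpoint always at or below air temperature, solar
flux following the clear-sky cosine of the zenith and exactly zero at
night, configurable additive warming between year periods — not
physically consistent synoptic weather.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xarray as xr
import yaml
from scipy import ndimage

from .solar import hour_midpoint, solar_zenith_grid

__all__ = ["ClimateScenario", "generate_fields", "generate_land_mask",
           "write_met_netcdf"]

#: local solar hour at which the diurnal temperature sinusoid peaks
DIURNAL_PEAK_HOUR = 14.0

#: std-dev of the dewpoint depression as a fraction of its mean
DEPRESSION_SPREAD = 0.3

#: std-dev of the wind speed as a fraction of its mean
WIND_SPREAD = 0.3


@dataclass(frozen=True)
class ClimateScenario:
    """Configuration of one synthetic climate realisation.

    grid_extent : (lat_min, lat_max, lon_min, lon_max) in degrees.
    grid_step : grid spacing in degrees (ERA5-like default 0.25).
    date_range : hourly UTC timestamps (interval starts), strictly
        increasing.
    base_temperature : daily-mean 2 m temperature, degC.
    diurnal_amplitude : semi-amplitude of the diurnal sinusoid, degC.
    dewpoint_depression_mean : mean of the non-negative dewpoint
        depression Ta - Td, degC.
    wind_mean : mean 10 m wind speed, m/s.
    clear_sky_peak_flux : downward short-wave flux for an overhead sun,
        W/m2; the generated flux is peak * max(0, cos(zenith)).
    period_offsets : mapping from a year-range label "YYYY-YYYY" to an
        additive degC temperature offset for those years.
    noise_sd : std-dev of Gaussian temperature noise, degC.
    seed : RNG seed; identical scenario + seed is bit-reproducible.
    diurnal_peak_hour : local solar hour of the temperature maximum.
    """

    grid_extent: tuple = (20.0, 24.0, 70.0, 74.0)
    grid_step: float = 0.25
    date_range: pd.DatetimeIndex = field(
        default_factory=lambda: pd.date_range("2012-06-01", periods=72, freq="h"))
    base_temperature: float = 28.0
    diurnal_amplitude: float = 6.0
    dewpoint_depression_mean: float = 6.0
    wind_mean: float = 2.0
    clear_sky_peak_flux: float = 950.0
    period_offsets: dict = field(default_factory=dict)
    noise_sd: float = 0.5
    seed: int = 0
    diurnal_peak_hour: float = DIURNAL_PEAK_HOUR

    def __post_init__(self):
        lat0, lat1, lon0, lon1 = self.grid_extent
        if not (-90.0 <= lat0 < lat1 <= 90.0):
            raise ValueError(f"grid_extent: invalid latitude bounds ({lat0}, {lat1})")
        if not lon0 < lon1:
            raise ValueError(f"grid_extent: invalid longitude bounds ({lon0}, {lon1})")
        if self.grid_step <= 0.0:
            raise ValueError("grid_step must be > 0")
        if self.dewpoint_depression_mean < 0.0:
            raise ValueError("dewpoint_depression_mean must be >= 0")
        if self.wind_mean < 0.0:
            raise ValueError("wind_mean must be >= 0")
        if self.clear_sky_peak_flux < 0.0:
            raise ValueError("clear_sky_peak_flux must be >= 0")
        times = pd.DatetimeIndex(self.date_range)
        if len(times) < 1:
            raise ValueError("date_range is empty")
        if len(times) > 1:
            deltas = np.diff(times.values)
            if not (deltas == np.timedelta64(1, "h")).all():
                raise ValueError("date_range must be strictly increasing and "
                                 "hourly spaced")
        for label in self.period_offsets:
            _parse_period_label(label)

    @property
    def latitudes(self) -> np.ndarray:
        lat0, lat1, _, _ = self.grid_extent
        n = int(round((lat1 - lat0) / self.grid_step)) + 1
        return lat0 + self.grid_step * np.arange(n)

    @property
    def longitudes(self) -> np.ndarray:
        _, _, lon0, lon1 = self.grid_extent
        n = int(round((lon1 - lon0) / self.grid_step)) + 1
        return lon0 + self.grid_step * np.arange(n)

    def replace(self, **kw) -> "ClimateScenario":
        from dataclasses import replace
        return replace(self, **kw)

    @classmethod
    def from_file(cls, path) -> "ClimateScenario":
        """Load a scenario from a YAML/JSON config file."""
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if "date_range" in raw and isinstance(raw["date_range"], dict):
            raw["date_range"] = pd.date_range(**raw["date_range"])
        if "grid_extent" in raw:
            raw["grid_extent"] = tuple(raw["grid_extent"])
        return cls(**raw)


def _parse_period_label(label: str) -> tuple[int, int]:
    m = re.fullmatch(r"(\d{4})\s*[-–]\s*(\d{4})", str(label))
    if not m:
        raise ValueError(f"period label {label!r} is not of the form 'YYYY-YYYY'")
    y0, y1 = int(m.group(1)), int(m.group(2))
    if y1 < y0:
        raise ValueError(f"period label {label!r} has end year before start year")
    return y0, y1


def _offset_for_years(years: np.ndarray, period_offsets: dict) -> np.ndarray:
    """Per-timestamp additive offset from year-range labelled periods."""
    out = np.zeros(len(years), dtype=float)
    for label, off in period_offsets.items():
        y0, y1 = _parse_period_label(label)
        out[(years >= y0) & (years <= y1)] += float(off)
    return out


def generate_land_mask(grid_extent, land_fraction_target: float, seed: int,
                       grid_step: float = 0.25,
                       smooth_sigma: float = 2.0) -> xr.DataArray:
    """Binary land mask (1 = land) with spatially contiguous continents.

    Gaussian-smoothed white noise thresholded at the (1 - target)
    quantile, so the spatial mean matches the target to within one cell's
    weight, and land forms connected blobs rather than salt-and-pepper
    cells.  target 0 and 1 give exactly all-ocean / all-land.
    """
    if not 0.0 <= land_fraction_target <= 1.0:
        raise ValueError("land_fraction_target must be in [0, 1]")
    scn = ClimateScenario(grid_extent=grid_extent, grid_step=grid_step)
    lats, lons = scn.latitudes, scn.longitudes
    rng = np.random.default_rng(seed)
    noise = rng.standard_normal((len(lats), len(lons)))
    smooth = ndimage.gaussian_filter(noise, sigma=smooth_sigma, mode="wrap")
    if land_fraction_target >= 1.0:
        mask = np.ones_like(smooth)
    elif land_fraction_target <= 0.0:
        mask = np.zeros_like(smooth)
    else:
        thr = np.quantile(smooth, 1.0 - land_fraction_target)
        mask = (smooth >= thr).astype(float)
    return xr.DataArray(mask, dims=("latitude", "longitude"),
                        coords={"latitude": lats, "longitude": lons},
                        name="lsm", attrs={"units": "1",
                                           "long_name": "land fraction"})


def generate_fields(scenario: ClimateScenario) -> xr.Dataset:
    """Generate the full hourly meteorology dataset for a scenario.

    Temperature is base + period offset + diurnal sinusoid (peak at the
    configured local solar hour) + Gaussian noise; dewpoint is
    temperature minus a truncated-Gaussian non-negative depression; wind
    components come from a truncated-Gaussian speed with uniform random
    direction; short-wave flux is clear_sky_peak_flux * max(0,
    cos(zenith)) evaluated at each hourly interval's midpoint, hence
    exactly zero whenever the midpoint sun is below the horizon.
    """
    times = pd.DatetimeIndex(scenario.date_range)
    lats, lons = scenario.latitudes, scenario.longitudes
    nt, ny, nx = len(times), len(lats), len(lons)
    rng = np.random.default_rng(scenario.seed)

    # local solar hour per (time, lon)
    utc_hours = (times.hour + times.minute / 60.0).values
    local_hour = utc_hours[:, None] + lons[None, :] / 15.0
    diurnal = np.cos(2.0 * np.pi * (local_hour - scenario.diurnal_peak_hour) / 24.0)
    offsets = _offset_for_years(times.year.values, scenario.period_offsets)

    t2m_c = (scenario.base_temperature
             + offsets[:, None, None]
             + scenario.diurnal_amplitude * diurnal[:, None, :]
             + scenario.noise_sd * rng.standard_normal((nt, ny, nx)))

    depression = scenario.dewpoint_depression_mean \
        + DEPRESSION_SPREAD * scenario.dewpoint_depression_mean \
        * rng.standard_normal((nt, ny, nx))
    depression = np.maximum(depression, 0.0)
    d2m_c = t2m_c - depression

    speed = scenario.wind_mean \
        + WIND_SPREAD * scenario.wind_mean * rng.standard_normal((nt, ny, nx))
    speed = np.maximum(speed, 0.0)
    angle = rng.uniform(0.0, 2.0 * np.pi, (nt, ny, nx))
    uwd = speed * np.cos(angle)
    vwd = speed * np.sin(angle)

    zen_mid = solar_zenith_grid(lats, lons, hour_midpoint(times))
    msdwswrt = scenario.clear_sky_peak_flux * np.maximum(
        0.0, np.cos(np.deg2rad(zen_mid)))

    dims = ("time", "latitude", "longitude")
    ds = xr.Dataset(
        {
            "t2m": (dims, t2m_c + 273.15, {"units": "K", "long_name": "2 metre temperature"}),
            "d2m": (dims, d2m_c + 273.15, {"units": "K", "long_name": "2 metre dewpoint temperature"}),
            "uwd": (dims, uwd, {"units": "m s-1", "long_name": "10 metre U wind component"}),
            "vwd": (dims, vwd, {"units": "m s-1", "long_name": "10 metre V wind component"}),
            "msdwswrt": (dims, msdwswrt,
                         {"units": "W m-2",
                          "long_name": "mean surface downward short-wave radiation flux"}),
        },
        coords={"time": times, "latitude": ("latitude", lats, {"units": "degrees_north"}),
                "longitude": ("longitude", lons, {"units": "degrees_east"})},
        attrs={"source": "urbanheat synthetic generator", "seed": scenario.seed},
    )
    ds["lsm"] = generate_land_mask(scenario.grid_extent, 1.0, scenario.seed,
                                   grid_step=scenario.grid_step)
    return ds


def write_met_netcdf(ds: xr.Dataset, path, land_mask: xr.DataArray | None = None):
    """Write meteorology to a CF-style NetCDF file (classic format).

    Variables are stored under the common ERA5 short names (t2m, d2m,
    u10, v10, msdwswrf, lsm) with units attributes, dimensions
    (time, latitude, longitude).
    """
    out = ds.rename({"uwd": "u10", "vwd": "v10", "msdwswrt": "msdwswrf"})
    if land_mask is not None:
        out["lsm"] = land_mask
    out.to_netcdf(path, engine="scipy")
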