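"""City analysis windows on the grid and land-only areal averaging.

A metropolitan area is represented by a square window of grid cells
centred on the nearest grid point to the city center: 8x8 cells
(~200 km at 0.25 deg) for the asia_na class, 4x4 (~100 km) for europe.
A window qualifies for analysis when its mean land fraction is at least
70 %; the cells entering the average are those with land fraction above
a per-cell cutoff (default 0.5).  All meteorology is averaged
(unweighted) over the selected land cells BEFORE the WBGT* computation
— the solvers are nonlinear, so the order matters and is asserted by
the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import xarray as xr
import yaml

__all__ = ["CityDomain", "REGION_WINDOW_CELLS", "load_cities",
           "make_domain", "land_filter", "terrain_filter", "areal_average",
           "daily_extreme_dispersion"]

#: window edge length in grid cells per region class
REGION_WINDOW_CELLS = {"asia_na": 8, "europe": 4}


@dataclass
class CityDomain:
    """A named analysis window: inclusive index slices into the grid,
    plus selection state filled in by :func:`land_filter`."""

    name: str
    country: str
    center_lat: float
    center_lon: float
    region_class: str
    population: float
    lat_slice: slice = None
    lon_slice: slice = None
    selected_cells: list = field(default_factory=list)
    valid: bool = False
    window_land_fraction: float = np.nan

    @property
    def window_cells(self) -> int:
        n = REGION_WINDOW_CELLS[self.region_class]
        return n * n


def load_cities(path=None) -> list[dict]:
    """City config entries; defaults to the packaged 22-city list."""
    if path is None:
        text = resources.files("urbanheat.data").joinpath("cities.yaml").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    cities = yaml.safe_load(text)
    for c in cities:
        if c["region_class"] not in REGION_WINDOW_CELLS:
            raise ValueError(f"city {c['name']!r}: unknown region class "
                             f"{c['region_class']!r}")
    return cities


def make_domain(city: dict, latitudes, longitudes) -> CityDomain:
    """Build the class-sized window centred on the nearest grid cell.

    For the even window size n, the window spans indices
    [i_nearest - n//2 + 1, i_nearest + n//2] on each axis.  A window
    that would extend past the grid edge is rejected, naming the axis.
    """
    lats = np.asarray(latitudes, dtype=float)
    lons = np.asarray(longitudes, dtype=float)
    n = REGION_WINDOW_CELLS[city["region_class"]]

    lat0, lon0 = float(city["lat"]), float(city["lon"])
    if not (lats.min() <= lat0 <= lats.max()) or not (lons.min() <= lon0 <= lons.max()):
        raise ValueError(f"city {city['name']!r}: center ({lat0}, {lon0}) "
                         "lies outside the grid")

    iy = int(np.argmin(np.abs(lats - lat0)))
    ix = int(np.argmin(np.abs(lons - lon0)))
    y0, y1 = iy - n // 2 + 1, iy + n // 2      # inclusive
    x0, x1 = ix - n // 2 + 1, ix + n // 2
    if y0 < 0 or y1 >= len(lats):
        raise ValueError(f"city {city['name']!r}: window exceeds grid "
                         "latitude bounds")
    if x0 < 0 or x1 >= len(lons):
        raise ValueError(f"city {city['name']!r}: window exceeds grid "
                         "longitude bounds")
    return CityDomain(name=city["name"], country=city.get("country", ""),
                      center_lat=lat0, center_lon=lon0,
                      region_class=city["region_class"],
                      population=float(city.get("population", np.nan)),
                      lat_slice=slice(y0, y1 + 1), lon_slice=slice(x0, x1 + 1))


def land_filter(domain: CityDomain, land_mask: xr.DataArray,
                threshold: float = 0.70,
                cell_cutoff: float = 0.5) -> CityDomain:
    """Apply the land criterion: the window qualifies when its mean land
    fraction is >= threshold (inclusive); cells with fraction above
    cell_cutoff are selected for averaging.  Mutates and returns the
    domain."""
    lm = land_mask.values
    if lm.shape[-2] < domain.lat_slice.stop or lm.shape[-1] < domain.lon_slice.stop:
        raise ValueError("land mask grid does not cover the domain window")
    window = lm[domain.lat_slice, domain.lon_slice]
    n = REGION_WINDOW_CELLS[domain.region_class]
    if window.shape != (n, n):
        raise ValueError(f"window shape {window.shape} != class size {n}x{n}")

    domain.window_land_fraction = float(window.mean())
    domain.valid = domain.window_land_fraction >= threshold
    ys, xs = np.nonzero(window > cell_cutoff)
    domain.selected_cells = [(int(y + domain.lat_slice.start),
                              int(x + domain.lon_slice.start))
                             for y, x in zip(ys, xs)]
    return domain


def areal_average(met: xr.Dataset, domain: CityDomain) -> xr.Dataset:
    """Unweighted mean of every field over the domain's selected land
    cells, per hour.  Returns a dataset with a single time dimension.

    Must run on raw meteorology, before WBGT* computation.
    """
    if not domain.valid:
        raise ValueError(f"domain {domain.name!r} failed the land criterion "
                         f"(window land fraction "
                         f"{domain.window_land_fraction:.2f})")
    if not domain.selected_cells:
        raise ValueError(f"domain {domain.name!r} has no selected land cells")
    ys = xr.DataArray([c[0] for c in domain.selected_cells], dims="cell")
    xs = xr.DataArray([c[1] for c in domain.selected_cells], dims="cell")
    sub = met.isel(latitude=ys, longitude=xs)
    out = sub.mean(dim="cell", keep_attrs=True)
    out.attrs["domain"] = domain.name
    out.attrs["n_cells"] = len(domain.selected_cells)
    return out


def terrain_filter(domain: CityDomain,
                   orography_std: xr.DataArray | None = None,
                   max_std_m: float | None = None) -> CityDomain:
    """'Gentle terrain' stub: if a per-cell orography standard-deviation
    field and a threshold are both supplied, the domain is invalidated
    when the window-mean exceeds the threshold; with the defaults it is
    a pass-through (no published threshold exists)."""
    if orography_std is None or max_std_m is None:
        return domain
    window = orography_std.values[domain.lat_slice, domain.lon_slice]
    if float(window.mean()) > max_std_m:
        domain.valid = False
    return domain


def daily_extreme_dispersion(met: xr.Dataset, domain: CityDomain) -> dict:
    """Diagnostic for the 'evenly distributed daily extremes' criterion:
    spatial coefficient of variation of the window's daily Tmax and Tmin
    (reported, never used as a hard filter — no published threshold
    exists)."""
    sub = met.t2m.isel(latitude=domain.lat_slice, longitude=domain.lon_slice)
    daily_max = sub.resample(time="1D").max()
    daily_min = sub.resample(time="1D").min()

    def _cv(da):
        spatial = da.mean("time")
        return float(spatial.std() / np.abs(spatial.mean()))

    return {"cv_daily_tmax": _cv(daily_max), "cv_daily_tmin": _cv(daily_min)}
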