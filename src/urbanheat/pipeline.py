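"""End-to-end orchestration: meteorology -> city WBGT* -> flag ledgers
-> period differences -> summary conversions.

The pipeline runs one summer season at a time (memory stays bounded by
a single season's grid), averages raw meteorology over each valid city
domain before any WBGT* computation, solves the energy balances on the
per-city hourly series, accumulates the work-rest ledger over the local
working window, and finally differences the two year periods and
converts totals to the reporting units (minutes per day, work-week
equivalents).

All randomness derives from the config seed; identical config + seed
gives byte-identical CSV outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .domains import (CityDomain, areal_average, land_filter, load_cities,
                      make_domain)
from .flags import (DEFAULT_FLAG_TABLE, FlagLedger, FlagTable, WorkingWindow,
                    per_day_minutes, percentile_aggregate, period_difference,
                    workweek_equivalent)
from .io import read_met_netcdf, validate_met
from .liljegren import WBGTConstants, compute_wbgt, derive_inputs
from .solar import hour_midpoint, solar_zenith
from .synthetic import ClimateScenario, generate_fields, generate_land_mask

__all__ = ["PipelineConfig", "run_pipeline", "city_wbgt_series",
           "season_date_range"]

log = logging.getLogger(__name__)


def season_date_range(year: int, months=(6, 7, 8)) -> pd.DatetimeIndex:
    """Hourly UTC interval-start stamps covering the season of one year."""
    start = pd.Timestamp(year=year, month=months[0], day=1)
    end_month = months[-1]
    end = (pd.Timestamp(year=year, month=end_month, day=1)
           + pd.offsets.MonthEnd(0) + pd.Timedelta(hours=23))
    return pd.date_range(start, end, freq="h")


@dataclass
class PipelineConfig:
    """Everything one end-to-end run needs.

    Either ``met_paths`` (NetCDF files, one per season) or ``scenario``
    (synthetic generator config) must be provided.  Periods are
    'YYYY-YYYY' labels; the later period is listed first in
    ``periods`` = (later, earlier) for the customary later-minus-earlier
    difference.
    """

    scenario: ClimateScenario | None = None
    met_paths: list = field(default_factory=list)
    periods: tuple = ("2015-2019", "2010-2014")
    constants: WBGTConstants = field(default_factory=WBGTConstants)
    window: WorkingWindow = field(default_factory=WorkingWindow)
    flag_table: FlagTable = DEFAULT_FLAG_TABLE
    cities: list = field(default_factory=load_cities)
    land_fraction_target: float = 0.85
    land_threshold: float = 0.70
    cell_cutoff: float = 0.5
    output_dir: Path = Path("urbanheat_out")
    seed: int = 0
    zenith_at_center: bool = True

    def period_years(self, label: str) -> range:
        y0, y1 = (int(p) for p in label.split("-"))
        return range(y0, y1 + 1)

    def provenance(self) -> dict:
        prov = {
            "constants": self.constants.asdict(),
            "window": {"start_hour": self.window.start_hour,
                       "end_hour": self.window.end_hour,
                       "season_months": list(self.window.season_months),
                       "utc_offset": self.window.utc_offset},
            "flag_table": [{"name": b.name, "lower": float(b.lower),
                            "upper": float(b.upper),
                            "rest_minutes": b.rest_minutes}
                           for b in self.flag_table.bands],
            "periods": list(self.periods),
            "seed": self.seed,
            "n_cities": len(self.cities),
        }
        digest = hashlib.sha256(
            json.dumps(prov, sort_keys=True, default=str).encode()).hexdigest()[:12]
        prov["config_hash"] = digest
        return prov


def city_wbgt_series(met, domain: CityDomain,
                     constants: WBGTConstants) -> pd.Series:
    """Hourly WBGT* for one city: areal-average the raw meteorology over
    the domain's land cells, then run the solvers on the averaged series
    with the zenith evaluated at the city center (the series no longer
    has a spatial dimension)."""
    avg = areal_average(met, domain)
    times = pd.DatetimeIndex(avg.time.values)
    zen = solar_zenith(domain.center_lat, domain.center_lon,
                       hour_midpoint(times).values)
    inputs = derive_inputs(avg.t2m.values, avg.d2m.values, avg.uwd.values,
                           avg.vwd.values, avg.msdwswrt.values, zen, constants)
    res = compute_wbgt(inputs, constants)
    n_bad = int((~res.converged).sum())
    if n_bad:
        log.warning("%s: %d non-converged hours set to missing",
                    domain.name, n_bad)
    return pd.Series(res.wbgt, index=times, name=domain.name)


def _season_fields(config: PipelineConfig, year: int):
    """Meteorology for one season-year, synthetic or from file."""
    if config.scenario is not None:
        scn = config.scenario.replace(
            date_range=season_date_range(year, config.window.season_months),
            seed=int((config.seed + year) % (2 ** 31)))
        ds = generate_fields(scn)
        ds["lsm"] = generate_land_mask(scn.grid_extent,
                                       config.land_fraction_target,
                                       seed=config.seed,
                                       grid_step=scn.grid_step)
        return validate_met(ds)
    for p in config.met_paths:
        ds = read_met_netcdf(p)
        if pd.DatetimeIndex(ds.time.values).year[0] == year:
            return ds
    raise FileNotFoundError(f"no meteorology file covers year {year}")


def _write_csv(df: pd.DataFrame, path: Path, prov: dict):
    """CSV with a provenance comment header."""
    with open(path, "w") as fh:
        fh.write(f"# urbanheat config_hash={prov['config_hash']} "
                 f"seed={prov['seed']}\n")
        fh.write(f"# constants={json.dumps(prov['constants'])}\n")
        df.to_csv(fh, index=False, lineterminator="\n")


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full analysis; write CSVs; return the report bundle.

    Outputs under ``config.output_dir``:
      ledgers.csv      one row per city x season (category rest hours),
      differences.csv  per-city later-minus-earlier category differences,
      summary.csv      per-city totals with min/day and work-week
                       conversions and percentile summaries,
      domains.csv      domain geometry and land-fraction report.
    """
    if config.scenario is None and not config.met_paths:
        raise ValueError("pipeline stage 'input': neither a scenario nor "
                         "meteorology files were provided")
    if not config.cities:
        raise ValueError("pipeline stage 'domains': empty city list")
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    prov = config.provenance()

    later, earlier = config.periods
    years = sorted(set(config.period_years(later))
                   | set(config.period_years(earlier)))

    # domain geometry from the first season's grid (static across seasons)
    first = _season_fields(config, years[0])
    domains = []
    for city in config.cities:
        try:
            d = make_domain(city, first.latitude.values, first.longitude.values)
        except ValueError as err:
            raise ValueError(f"pipeline stage 'domains': {err}") from err
        land_filter(d, first.lsm, threshold=config.land_threshold,
                    cell_cutoff=config.cell_cutoff)
        domains.append(d)
    valid_domains = [d for d in domains if d.valid]
    if not valid_domains:
        raise ValueError("pipeline stage 'domains': no city passed the "
                         "land criterion")

    ledgers: dict[str, list[FlagLedger]] = {d.name: [] for d in valid_domains}
    series_store: dict[str, list[pd.Series]] = {d.name: [] for d in valid_domains}
    for year in years:
        met = first if year == years[0] else _season_fields(config, year)
        for d in valid_domains:
            wbgt = city_wbgt_series(met, d, config.constants)
            series_store[d.name].append(wbgt)
            ledgers[d.name].extend(
                _accumulate(wbgt, d, config))
        log.info("season %d done (%d cities)", year, len(valid_domains))

    ledger_rows, diff_rows, summary_rows = [], [], []
    later_years = set(config.period_years(later))
    for d in valid_domains:
        led = ledgers[d.name]
        ledger_rows.extend(l.to_row() for l in led)
        led_a = [l for l in led if int(l.season.split("-")[1]) in later_years]
        led_b = [l for l in led if int(l.season.split("-")[1]) not in later_years]
        diff = period_difference(led_a, led_b)
        diff_rows.append({"domain": d.name, **{f"diff_hours_{k}": round(v, 6)
                                               for k, v in diff.items()}})

        total_b = sum(l.total_rest_hours for l in led_b)
        all_wbgt = pd.concat(series_store[d.name])
        in_win = config.window.in_window(all_wbgt.index, d.center_lon)
        p50, p98 = percentile_aggregate(all_wbgt[in_win].values)
        summary_rows.append({
            "domain": d.name,
            "rest_hours_earlier_period": round(total_b, 6),
            "rest_hours_per_year": round(total_b / max(len(led_b), 1), 6),
            "rest_minutes_per_day": round(
                per_day_minutes(total_b, max(len(led_b), 1)), 6),
            "workweek_equivalent_diff": round(
                workweek_equivalent(diff["total"]), 6),
            "wbgt_p50": round(p50, 6), "wbgt_p98": round(p98, 6),
        })

    domain_rows = [{"domain": d.name, "region_class": d.region_class,
                    "valid": d.valid,
                    "window_land_fraction": round(d.window_land_fraction, 6),
                    "n_selected_cells": len(d.selected_cells)}
                   for d in domains]

    bundle = {
        "ledgers": pd.DataFrame(ledger_rows),
        "differences": pd.DataFrame(diff_rows),
        "summary": pd.DataFrame(summary_rows),
        "domains": pd.DataFrame(domain_rows),
        "provenance": prov,
    }
    for name in ("ledgers", "differences", "summary", "domains"):
        _write_csv(bundle[name], out_dir / f"{name}.csv", prov)
    return bundle


def _accumulate(wbgt: pd.Series, domain: CityDomain,
                config: PipelineConfig) -> list[FlagLedger]:
    from .flags import accumulate_rest
    return accumulate_rest(wbgt, domain.center_lon, window=config.window,
                           table=config.flag_table, domain=domain.name)
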