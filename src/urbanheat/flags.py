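"""Heat-flag categories and work-rest accumulation.

The military/ACGIH flag system maps WBGT to mandated rest minutes per
working hour at a given metabolic workload.  The packaged default is the
heavy-work (600 W) table:

    no flag   WBGT < 29.4 degC          0 min/h
    yellow    29.4 <= WBGT < 31.1      15 min/h
    red       31.1 <= WBGT <= 32.2     30 min/h
    black     WBGT > 32.2              45 min/h

Shared bounds are assigned as documented above (the printed table leaves
them ambiguous); the convention is centralised in :class:`FlagTable` and
other workload tables can be supplied from config.

Rest minutes are accumulated over every in-window hour of the summer
season (JJA, local 08:00-18:00 read as ten one-hour intervals starting
08:00..17:00), converted to hours, and differenced between year periods.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "FlagBand", "FlagTable", "DEFAULT_FLAG_TABLE", "WorkingWindow",
    "FlagLedger", "classify_flag", "accumulate_rest", "period_difference",
    "per_day_minutes", "workweek_equivalent", "percentile_aggregate",
]

JJA_DAYS = 92  # 1 June - 31 August inclusive


@dataclass(frozen=True)
class FlagBand:
    """One category: [lower, upper] WBGT bounds (degC, +-inf allowed) with
    explicit boundary inclusivity, and the rest minutes it mandates."""

    name: str
    lower: float
    upper: float
    lower_inclusive: bool
    upper_inclusive: bool
    rest_minutes: float

    def contains(self, wbgt) -> np.ndarray:
        w = np.asarray(wbgt, dtype=float)
        lo = w >= self.lower if self.lower_inclusive else w > self.lower
        hi = w <= self.upper if self.upper_inclusive else w < self.upper
        return lo & hi


@dataclass(frozen=True)
class FlagTable:
    """Ordered, exhaustive, mutually exclusive set of flag bands."""

    bands: tuple

    def __post_init__(self):
        if not self.bands:
            raise ValueError("flag table needs at least one band")
        prev = None
        for b in self.bands:
            if b.lower >= b.upper:
                raise ValueError(f"band {b.name!r}: lower >= upper")
            if b.rest_minutes < 0:
                raise ValueError(f"band {b.name!r}: negative rest minutes")
            if prev is not None:
                if b.lower != prev.upper:
                    raise ValueError(
                        f"bands {prev.name!r}/{b.name!r} do not share a bound")
                if b.lower_inclusive == prev.upper_inclusive:
                    raise ValueError(
                        f"bound {b.lower} owned by both or neither of "
                        f"{prev.name!r}/{b.name!r}")
                if b.rest_minutes < prev.rest_minutes:
                    raise ValueError("rest minutes must be non-decreasing")
            prev = b
        if not np.isneginf(self.bands[0].lower) or not np.isposinf(self.bands[-1].upper):
            raise ValueError("flag table must cover (-inf, +inf)")

    @property
    def names(self) -> tuple:
        return tuple(b.name for b in self.bands)

    def classify(self, wbgt) -> np.ndarray:
        """Category index for each finite WBGT; -1 marks missing (NaN)."""
        w = np.asarray(wbgt, dtype=float)
        out = np.full(w.shape, -1, dtype=np.int64)
        for i, b in enumerate(self.bands):
            out[b.contains(w)] = i
        return out

    def rest_minutes_for(self, wbgt) -> np.ndarray:
        """Rest minutes per hour for each WBGT; NaN for missing values."""
        idx = self.classify(wbgt)
        mins = np.array([b.rest_minutes for b in self.bands], dtype=float)
        out = np.where(idx >= 0, mins[np.clip(idx, 0, None)], np.nan)
        return out

    @classmethod
    def from_config(cls, path) -> "FlagTable":
        """Load a workload table from YAML: list of {name, upper,
        upper_inclusive, rest_minutes}, in increasing order; the last
        entry's upper is implied +inf."""
        with open(path) as fh:
            rows = yaml.safe_load(fh)
        bands = []
        lower, lower_inc = -np.inf, False
        for i, row in enumerate(rows):
            upper = float(row.get("upper", np.inf)) if i < len(rows) - 1 else np.inf
            upper_inc = bool(row.get("upper_inclusive", False))
            bands.append(FlagBand(row["name"], lower, upper, lower_inc,
                                  upper_inc if np.isfinite(upper) else True,
                                  float(row["rest_minutes"])))
            lower, lower_inc = upper, not upper_inc
        return cls(tuple(bands))


#: heavy-work (600 W) table; boundary ownership as documented above
DEFAULT_FLAG_TABLE = FlagTable((
    FlagBand("none", -np.inf, 29.4, False, False, 0.0),
    FlagBand("yellow", 29.4, 31.1, True, False, 15.0),
    FlagBand("red", 31.1, 32.2, True, True, 30.0),
    FlagBand("black", 32.2, np.inf, False, True, 45.0),
))


def classify_flag(wbgt, table: FlagTable = DEFAULT_FLAG_TABLE):
    """Category name(s) for WBGT value(s); None where WBGT is missing."""
    idx = table.classify(wbgt)
    names = np.array(table.names + (None,), dtype=object)
    out = names[np.where(idx >= 0, idx, len(table.names))]
    if np.ndim(out) == 0:
        return out if isinstance(out, (str, type(None))) else out.item()
    return out


@dataclass(frozen=True)
class WorkingWindow:
    """Daily working window in local time plus the season months.

    The window [start_hour, end_hour) is read as one-hour intervals
    starting at start_hour .. end_hour-1, each classified by the hourly
    WBGT stamped at the interval start.  Local time defaults to the
    solar convention UTC + longitude/15 h; a fixed utc_offset (hours)
    can be supplied instead.
    """

    start_hour: int = 8
    end_hour: int = 18
    season_months: tuple = (6, 7, 8)
    utc_offset: float | None = None

    def __post_init__(self):
        if not 0 <= self.start_hour < self.end_hour <= 24:
            raise ValueError("need 0 <= start_hour < end_hour <= 24")

    @property
    def hours_per_day(self) -> int:
        return self.end_hour - self.start_hour

    def local_times(self, utc_index: pd.DatetimeIndex,
                    longitude: float) -> pd.DatetimeIndex:
        offset = self.utc_offset if self.utc_offset is not None \
            else longitude / 15.0
        return utc_index + pd.Timedelta(hours=1) * offset

    def in_window(self, utc_index: pd.DatetimeIndex,
                  longitude: float) -> np.ndarray:
        """Boolean mask of in-season, in-window hourly stamps."""
        local = self.local_times(utc_index, longitude)
        hour = local.hour + local.minute / 60.0
        return (np.isin(local.month, self.season_months)
                & (hour >= self.start_hour) & (hour < self.end_hour))


@dataclass
class FlagLedger:
    """Accumulated rest time for one domain and one season.

    rest_minutes maps category name -> accumulated minutes over the
    season's working window; exposed_hours counts in-window hours with a
    finite WBGT, missing_hours those without (missing hours accrue no
    rest and are reported, not interpolated).
    """

    domain: str
    season: str
    rest_minutes: dict = field(default_factory=dict)
    exposed_hours: int = 0
    missing_hours: int = 0

    @property
    def rest_hours(self) -> dict:
        return {k: v / 60.0 for k, v in self.rest_minutes.items()}

    @property
    def total_rest_hours(self) -> float:
        return sum(self.rest_minutes.values()) / 60.0

    def check(self, max_rest_minutes: float = 45.0):
        """Invariants: non-negative buckets; total bounded by the
        worst-category cap over exposed hours."""
        if any(v < -1e-9 for v in self.rest_minutes.values()):
            raise AssertionError("negative rest bucket")
        cap = self.exposed_hours * max_rest_minutes / 60.0
        if self.total_rest_hours > cap + 1e-9:
            raise AssertionError(
                f"ledger {self.domain}/{self.season}: total rest "
                f"{self.total_rest_hours:.2f} h exceeds cap {cap:.2f} h")

    def to_row(self) -> dict:
        row = {"domain": self.domain, "season": self.season,
               "exposed_hours": self.exposed_hours,
               "missing_hours": self.missing_hours,
               "total_rest_hours": round(self.total_rest_hours, 6)}
        for k, v in self.rest_hours.items():
            row[f"rest_hours_{k}"] = round(v, 6)
        return row


def _check_hourly(index: pd.DatetimeIndex):
    if len(index) > 1:
        deltas = np.unique(np.diff(index.values))
        if not (deltas == np.timedelta64(1, "h")).all():
            raise ValueError("series must be hourly spaced "
                             f"(got steps {deltas.astype('timedelta64[m]')})")


def accumulate_rest(wbgt: pd.Series, longitude: float,
                    window: WorkingWindow = WorkingWindow(),
                    table: FlagTable = DEFAULT_FLAG_TABLE,
                    domain: str = "") -> list[FlagLedger]:
    """Accumulate per-category rest time from an hourly WBGT series.

    ``wbgt`` is indexed by UTC interval-start timestamps; missing hours
    may be NaN.  Returns one ledger per season (year) present in the
    series, labelled ``JJA-<year>`` (or ``S-<year>`` for non-default
    months).
    """
    if not isinstance(wbgt.index, pd.DatetimeIndex):
        raise TypeError("wbgt series must be indexed by timestamps")
    _check_hourly(wbgt.index)

    mask = window.in_window(wbgt.index, longitude)
    sel = wbgt[mask]
    tag = "JJA" if tuple(window.season_months) == (6, 7, 8) else "S"
    ledgers = []
    for year, grp in sel.groupby(sel.index.year):
        mins = table.rest_minutes_for(grp.values)
        idx = table.classify(grp.values)
        missing = int(np.sum(~np.isfinite(grp.values)))
        ledger = FlagLedger(domain=domain, season=f"{tag}-{year}")
        for i, name in enumerate(table.names):
            ledger.rest_minutes[name] = float(
                np.nansum(np.where(idx == i, mins, 0.0)))
        ledger.exposed_hours = int(len(grp) - missing)
        ledger.missing_hours = missing
        ledger.check(max_rest_minutes=table.bands[-1].rest_minutes)
        ledgers.append(ledger)
    return ledgers


def period_difference(ledgers_a: list[FlagLedger],
                      ledgers_b: list[FlagLedger]) -> dict:
    """Per-category rest-hour difference, sum(A) - sum(B).

    A is the later period, B the earlier; their season sets must be
    disjoint.  Returns {category: hours, ..., "total": hours}.
    """
    if not ledgers_a or not ledgers_b:
        raise ValueError("both period ledger sets must be non-empty")
    seasons_a = {(l.domain, l.season) for l in ledgers_a}
    seasons_b = {(l.domain, l.season) for l in ledgers_b}
    overlap = seasons_a & seasons_b
    if overlap:
        raise ValueError(f"periods overlap in seasons: {sorted(overlap)}")

    cats = list(ledgers_a[0].rest_minutes)
    diff = {}
    for c in cats:
        a = sum(l.rest_hours.get(c, 0.0) for l in ledgers_a)
        b = sum(l.rest_hours.get(c, 0.0) for l in ledgers_b)
        diff[c] = a - b
    diff["total"] = sum(diff[c] for c in cats)
    return diff


def per_day_minutes(total_rest_hours: float, n_seasons: int,
                    days_per_season: int = JJA_DAYS) -> float:
    """Average mandated rest in minutes per working day.

    total_rest_hours accumulated over n_seasons seasons of
    days_per_season days each.
    """
    if n_seasons < 1 or days_per_season < 1:
        raise ValueError("n_seasons and days_per_season must be >= 1")
    return total_rest_hours * 60.0 / (n_seasons * days_per_season)


def workweek_equivalent(rest_hours: float, hours_per_day: float = 8.0,
                        days_per_week: float = 5.0) -> float:
    """Rest time expressed as standard five-day, 8 h working weeks."""
    if hours_per_day <= 0 or days_per_week <= 0:
        raise ValueError("divisors must be positive")
    return rest_hours / (hours_per_day * days_per_week)


def percentile_aggregate(wbgt) -> tuple[float, float]:
    """Seasonal 'mean' and 'max' summary of an hourly WBGT distribution:
    its 50th and 98th percentiles (linear interpolation between order
    statistics)."""
    w = np.asarray(wbgt, dtype=float)
    w = w[np.isfinite(w)]
    if w.size == 0:
        raise ValueError("empty series")
    if w.size < 50:
        raise ValueError("need at least 50 samples for a stable 98th "
                         f"percentile (got {w.size})")
    p50, p98 = np.percentile(w, [50.0, 98.0])
    return float(p50), float(p98)
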