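# Methods

This note documents the models, conventions and design choices behind
`urbanheat`, in the order the pipeline applies them.

## From raw fields to solver inputs

The pipeline consumes five hourly fields on a regular 0.25°
latitude–longitude grid: 2 m temperature `t2m` (K), 2 m dewpoint `d2m`
(K), 10 m wind components `uwd`/`vwd` (m s⁻¹) and the mean surface
downward short-wave radiation flux `msdwswrt` (W m⁻²), plus a static
land mask. Derived inputs:

- Ta = t2m − 273.15, Td = d2m − 273.15 (°C);
- RH = 100·exp(17.27·(Td/(237.7+Td) − Ta/(237.3+Ta))) (%). The two
  Magnus denominators are deliberately asymmetric — this reproduces the
  expression exactly as printed in the source analysis, under which
  saturation (Td = Ta) yields ≈99.8 % rather than 100 %. A
  `magnus_consistent` switch uses 237.3 in both terms when exact
  saturation behaviour is preferred. The difference is below 0.25 % RH
  everywhere and does not visibly move WBGT.
- wind speed ws = √(uwd² + vwd²), floored at `min_wind_speed`
  (default 0.1 m s⁻¹ — the convective transfer correlations are
  singular at zero wind). The floor is applied once, in input
  derivation, so both solvers see identical wind.
- mrd = msdwswrt, floored at 0.

Non-finite inputs propagate to missing WBGT values; missing hours
accrue zero rest minutes and are counted in the ledgers, never
interpolated.

## Solar geometry

Solar zenith angles come from the standard NOAA solar-position
algorithm (Julian century → solar declination and equation of time →
hour angle), vectorised over arrays; accuracy is a few hundredths of a
degree for 1900–2100, verified in the test suite against an
independent transcription of the Michalsky Astronomical Almanac
algorithm (max deviation ~0.013° over 1000 random space–time points).
Atmospheric refraction is ignored (< 0.6° near the horizon, irrelevant
after capping, below).

Hourly fields are treated as interval means stamped at the interval
start, so the zenith attached to an hourly sample is evaluated at the
interval midpoint (stamp + 30 min). The same convention is used when
generating synthetic solar flux, when validating the "zero flux when
the sun is below the horizon" invariant, and when computing WBGT, so
the code path is identical for synthetic and real data.

For the radiative terms of the energy balances the zenith is capped at
87° (the direct-beam geometry factor contains 1/cos z); the raw zenith
is reported unchanged. For city series the zenith is evaluated once at
the city center — after areal averaging there is no spatial dimension
left; gridded (`wbgt_field`) computations evaluate it per cell.

## The Liljegren energy balances

WBGT* = 0.7·Tnwb + 0.2·Tg + 0.1·Ta, with the globe temperature Tg and
natural wet-bulb temperature Tnwb solved from the Liljegren
energy-balance model (the standard for outdoor WBGT from meteorological
inputs). Both solvers mirror the published public-domain reference
code: Buck's saturation vapour pressure with the 1.004 moist-air
enhancement, Chapman–Enskog viscosity/diffusivity, sphere and
cross-flow cylinder convection correlations, clear-sky atmospheric
emissivity 0.575·e^0.143, surface emissivity 0.999 and albedo 0.45,
globe (Ø 50.8 mm, emissivity 0.95, albedo 0.05) and wick (Ø 7 mm,
length 25.4 mm, emissivity 0.95, albedo 0.4).

Numerics: damped fixed-point iteration, state update
0.9·prev + 0.1·new, stopping when an undamped step moves less than
`convergence_tol` = 0.02 °C, at most `max_iterations` = 50 iterations —
the same scheme, tolerance and cap as the reference code, so the two
implementations agree to well under 0.1 °C (measured max ≈ 0.02 °C over
a 500-point Latin-hypercube sweep of Ta∈[10,45] °C, RH∈[5,100] %,
ws∈[0.1,10] m s⁻¹, mrd∈[0,1100] W m⁻², zenith∈[0,87]°). Non-converged
points (essentially nonexistent in the sweep) are flagged and reported
missing. The package implementation is fully vectorised; the scalar
loop transcription lives in the test suite as an independent oracle.

Fixed parameters: atmospheric pressure 101 kPa everywhere (no elevation
adjustment — a documented limitation, the source analysis applied the
same constant even for high-altitude cities), direct-beam fraction
`prop_direct` = 0.8 applied only when the sun is up; at night flux is
zero and the split is irrelevant.

A physical subtlety: at 100 % RH with no sun, the evaporative
depression vanishes but the wick still exchanges long-wave radiation
with the sub-unit-emissivity sky, so Tnwb sits up to ~0.25 °C below Ta
(less in warm, moist air where the sky emissivity approaches 1). This
is the reference model's behaviour, not solver error; the limit tests
assert equality with the air temperature to 0.5 °C and equality with
the reference transcription to 0.05 °C.

## Flag categories and rest accumulation

The heavy-work (600 W metabolic rate) flag table maps WBGT to mandated
rest minutes per working hour: none (<29.4 °C, 0 min), yellow
(29.4–31.1, 15), red (31.1–32.2, 30), black (>32.2, 45). The printed
table leaves shared bounds ambiguous; this package fixes yellow =
[29.4, 31.1), red = [31.1, 32.2], black = (32.2, ∞), centralised in
`FlagTable` so any convention or other ACGIH workload table can be
supplied from config.

Accumulation: the working window "local time 08:00–18:00" is read as
ten one-hour intervals starting 08:00 through 17:00, each classified by
the hourly WBGT stamped at the interval start; local time is the solar
convention UTC + longitude/15 (no civil time-zone database). Seasons
are JJA, 1 June–31 August inclusive (92 days). Rest minutes are
assigned per full hour in category — no sub-hour interpolation. A
season therefore caps at 92×10×45/60 = 690 rest hours. Period
differences are later-minus-earlier sums per category; overlapping
season sets are rejected.

Reporting conversions: minutes per day = hours × 60 / (seasons × 92);
work-week equivalents = hours / (8 × 5). Seasonal "mean" and "max"
summaries are the 50th and 98th percentiles of the hourly WBGT
distribution, linear interpolation between order statistics (numpy's
default; fixed here because no rule is otherwise prescribed).

## Urban domains

City windows are 8×8 grid cells (~200 km) for the asia_na class and
4×4 (~100 km) for europe, centred on the grid cell nearest the
configured city center. Cairo is assigned the asia_na class: only
Asia/North America (8×8) and Europe (4×4) classes are defined by the
source material, and Cairo's metropolitan extent is closer to the
former. The packaged 22-city list uses well-known center coordinates
chosen for this package.

A window qualifies when its mean land fraction is ≥ 0.70 (inclusive);
cells with land fraction > 0.5 enter the average. The two thresholds
are deliberately separate config. Averaging is an unweighted mean per
variable per hour — windows span ≤ 2°, so cos-latitude weighting would
change nothing at the third decimal, and plain areal averages keep the
definition transparent. Averaging happens on raw meteorology *before*
the WBGT computation; the solvers are nonlinear, so the order matters
and the test suite asserts the package takes the average-first path.
The "gentle terrain" criterion is a configurable stub (pass-through by
default) and the "evenly distributed daily extremes" criterion is an
optional diagnostic (spatial CV of daily Tmax/Tmin per window) — no
quantitative thresholds exist for either.

## Synthetic meteorology

The generator emulates the statistical structure the analysis needs,
not weather: per cell-hour, temperature = base + period offset +
diurnal sinusoid + Gaussian noise, with the sinusoid peaking at 14:00
local solar time (typical climatology; configurable). Dewpoint is
temperature minus a truncated-Gaussian depression (σ = 0.3 × mean,
clipped at zero), which guarantees d2m ≤ t2m by construction. Wind
components come from a truncated-Gaussian speed (σ = 0.3 × mean) with
uniform random direction. Short-wave flux is clear-sky:
peak × max(0, cos zenith) at the interval midpoint — hence exactly zero
at night. Land masks are thresholded smoothed noise, so land forms
contiguous blobs and window filters are meaningful; the threshold is
the (1 − target) quantile, pinning the spatial mean to the target.
Period offsets are additive °C per "YYYY-YYYY" year range.

What the generator does **not** emulate: synoptic variability (fronts,
monsoon breaks), cloud cover (all days are clear-sky), spatial
correlation of the noise, humidity–temperature covariance beyond the
fixed mean depression, and diurnal wind cycles. Tests passing on
synthetic data therefore demonstrate the correctness of the
*computation chain* — solvers, classification, accounting, aggregation
— not the climatological realism of any particular number.

The packaged demo study (`urbanheat.demo`) fixes one configuration:
6°×6° grid at 22–28 °N, base 20 °C, diurnal semi-amplitude 5 °C,
dewpoint depression 10 °C, wind 2 m s⁻¹, clear-sky peak 850 W m⁻²,
noise 0.5 °C, and a +1.0 °C offset for 2015–2019 relative to 2010–2014.
Under these conditions the working-window WBGT* distribution spans all
four flag categories (≈42/27/14/17 %), so the inter-period warming
moves hours across every threshold — the regime in which the flag
accounting is actually exercised. Two 4×4-window cities on an all-land
mask, ten JJA seasons: about 44 000 solver hours, a desk-scale stand-in
for the archive-scale analysis (which would require the full reanalysis
and is out of scope here).

## Determinism and problem sizes

Every stochastic step draws from `numpy.random.default_rng` seeded from
the scenario/config seed; per-season generator seeds are derived as
(seed + year) mod 2³¹. Identical config + seed reproduces CSV outputs
byte for byte. The solvers contain no randomness. The default test
suite runs in well under a minute; the end-to-end demo (2 cities × 10
seasons) takes a few seconds on one CPU.

## Known limitations

- Constant 101 kPa pressure (no elevation adjustment).
- Solar-convention local time ignores civil time zones and DST; for a
  city at the eastern edge of a wide zone this shifts the window by up
  to ~1 h against clock time.
- The clear-sky direct fraction 0.8 is held fixed; real skies vary it.
- The reader accepts NetCDF3-classic files (scipy engine); NetCDF4/HDF5
  inputs would need conversion upstream.
- Areal averaging before the nonlinear solvers systematically smooths
  extremes relative to a point measurement — the resulting WBGT* is a
  metropolitan-mean condition, not a worst-case street value.
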