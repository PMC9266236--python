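"""Liljegren outdoor WBGT model: input derivation and energy-balance solvers.

The wet-bulb globe temperature inferred from gridded meteorology is

    WBGT* = 0.7 Tnwb + 0.2 Tg + 0.1 Ta        (degC)

where Ta is the 2 m air temperature, Tg the black-globe temperature and
Tnwb the natural wet-bulb temperature.  Tg and Tnwb are fixed points of
the Liljegren globe and wetted-wick energy balances (absorbed short-wave
and long-wave radiation balanced against convective and, for the wick,
evaporative exchange) and are found here by the same damped fixed-point
iteration the published reference code uses (damping 0.1, tolerance
0.02 degC, at most 50 iterations).

Everything is vectorized: the solvers accept scalars or numpy arrays of
any common-broadcast shape and iterate all points simultaneously,
freezing each point once converged.  Non-converged or non-finite points
come back as NaN with ``converged=False``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import xarray as xr

from .solar import hour_midpoint, solar_zenith_grid

__all__ = [
    "WBGTConstants", "WBGTInputs", "WBGTResult",
    "relative_humidity", "derive_inputs",
    "globe_temperature", "natural_wet_bulb", "wbgt_star",
    "compute_wbgt", "wbgt_field",
]

log = logging.getLogger(__name__)

# physical constants (SI unless noted; pressures in mb inside the solvers)
_STEFANB = 5.6696e-8
_CP = 1003.5
_M_AIR = 28.97
_M_H2O = 18.015
_RATIO = _CP * _M_AIR / _M_H2O
_R_AIR = 8314.34 / _M_AIR
_PR = _CP / (_CP + 1.25 * _R_AIR)

# standard 6" black globe
_EMIS_GLOBE = 0.95
_ALB_GLOBE = 0.05
_D_GLOBE = 0.0508
# wetted wick
_EMIS_WICK = 0.95
_ALB_WICK = 0.4
_D_WICK = 0.007
_L_WICK = 0.0254
# ground surface
_EMIS_SFC = 0.999
_ALB_SFC = 0.45


@dataclass(frozen=True)
class WBGTConstants:
    """Fixed parameters of the WBGT* computation.

    atm_pressure : kPa; held constant everywhere (no elevation adjustment).
    min_wind_speed : m/s floor applied to the 10 m wind (the convective
        transfer correlations break down at exactly zero wind).
    prop_direct : direct fraction of the downward short-wave flux when the
        sun is up; the diffuse remainder is (1 - prop_direct).
    convergence_tol : degC; fixed-point stopping tolerance.
    max_iterations : iteration cap; points still moving are flagged.
    zenith_cap_deg : zenith passed to the radiative geometry terms is
        capped here to guard the 1/cos(zenith) direct-beam factor near the
        horizon; the raw zenith is still reported alongside.
    magnus_consistent : if True, use the same Magnus denominator (237.3)
        in both the dewpoint and temperature terms of the RH formula so
        that Td = Ta gives exactly 100 %.  Default False reproduces the
        asymmetric printed form (237.7 / 237.3), under which Td = Ta
        gives ~99.8 %.
    """

    atm_pressure: float = 101.0
    min_wind_speed: float = 0.1
    prop_direct: float = 0.8
    convergence_tol: float = 0.02
    max_iterations: int = 50
    zenith_cap_deg: float = 87.0
    magnus_consistent: bool = False

    def __post_init__(self):
        if not 0.0 < self.prop_direct <= 1.0:
            raise ValueError("prop_direct must be in (0, 1]")
        if self.min_wind_speed <= 0.0:
            raise ValueError("min_wind_speed must be > 0")
        if self.convergence_tol <= 0.0:
            raise ValueError("convergence_tol must be > 0")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")

    def asdict(self) -> dict:
        return {f: getattr(self, f) for f in self.__dataclass_fields__}


@dataclass
class WBGTInputs:
    """Per-point derived inputs: Ta/Td degC, RH percent, ws m/s, mrd W/m2,
    zenith degrees.  Arrays share one broadcast shape."""

    Ta: np.ndarray
    Td: np.ndarray
    RH: np.ndarray
    ws: np.ndarray
    mrd: np.ndarray
    zenith: np.ndarray


@dataclass
class WBGTResult:
    """Solver output: component temperatures (degC), the composite index,
    per-point convergence flags and iteration counts."""

    Tnwb: np.ndarray
    Tg: np.ndarray
    wbgt: np.ndarray
    converged: np.ndarray
    iterations: np.ndarray


def relative_humidity(Ta, Td, consistent: bool = False):
    """Relative humidity (%) from air and dewpoint temperature (degC).

    Magnus-type expression
        RH = 100 exp(17.27 (Td/(237.7+Td) - Ta/(237.3+Ta)))
    with the asymmetric denominators as printed; ``consistent=True``
    uses 237.3 in both terms so saturation maps to exactly 100 %.
    """
    Ta = np.asarray(Ta, dtype=float)
    Td = np.asarray(Td, dtype=float)
    d_dew = 237.3 if consistent else 237.7
    return 100.0 * np.exp(17.27 * (Td / (d_dew + Td) - Ta / (237.3 + Ta)))


def derive_inputs(t2m, d2m, uwd, vwd, msdwswrt, zenith,
                  constants: WBGTConstants = WBGTConstants()) -> WBGTInputs:
    """Convert raw fields (K, m/s, W/m2) to solver inputs.

    Ta = t2m - 273.15, Td = d2m - 273.15, RH from the Magnus expression,
    ws = hypot(uwd, vwd) floored at min_wind_speed, mrd floored at 0.
    Non-finite inputs propagate to NaN outputs (counted in the log, never
    silently zeroed).
    """
    t2m = np.asarray(t2m, dtype=float)
    if np.any((t2m < 150.0) | (t2m > 350.0)):
        bad = t2m[(t2m < 150.0) | (t2m > 350.0)]
        raise ValueError(
            f"t2m outside plausible range 150-350 K (e.g. {bad.flat[0]:.1f}); "
            "is the field already in degC?")
    Ta = t2m - 273.15
    Td = np.asarray(d2m, dtype=float) - 273.15
    RH = relative_humidity(Ta, Td, consistent=constants.magnus_consistent)
    ws = np.hypot(np.asarray(uwd, dtype=float), np.asarray(vwd, dtype=float))
    ws = np.maximum(ws, constants.min_wind_speed)
    mrd = np.maximum(np.asarray(msdwswrt, dtype=float), 0.0)
    n_missing = int(np.sum(~np.isfinite(Ta + Td + ws + mrd)))
    if n_missing:
        log.warning("derive_inputs: %d cell-hours with non-finite inputs "
                    "propagated as missing", n_missing)
    return WBGTInputs(Ta=Ta, Td=Td, RH=RH, ws=ws, mrd=mrd,
                      zenith=np.asarray(zenith, dtype=float))


def _esat_mb(tk):
    """Saturation vapour pressure over water (mb), Buck with 1.004
    moist-air enhancement — the solver-internal psychrometric closure."""
    return 1.004 * 6.1121 * np.exp(17.502 * (tk - 273.15) / (tk - 32.18))


def _viscosity(tk):
    omega = (tk / 97.0 - 2.9) / 0.4 * (-0.034) + 1.048
    return 2.6693e-6 * np.sqrt(_M_AIR * tk) / (3.617 ** 2 * omega)


def _thermal_cond(tk):
    return (_CP + 1.25 * _R_AIR) * _viscosity(tk)


def _emis_atm(tk, rh_frac):
    return 0.575 * (rh_frac * _esat_mb(tk)) ** 0.143


def _diffusivity(tk, pair_mb):
    pcrit13 = (36.4 * 218.0) ** (1.0 / 3.0)
    tcrit512 = (132.0 * 647.3) ** (5.0 / 12.0)
    tcrit12 = np.sqrt(132.0 * 647.3)
    mmix = np.sqrt(1.0 / _M_AIR + 1.0 / _M_H2O)
    return (0.000364 * (tk / tcrit12) ** 2.334 * pcrit13 * tcrit512 * mmix
            / (pair_mb / 1013.25) * 1e-4)


def _latent_heat(tk):
    return (313.15 - tk) / 30.0 * (-71100.0) + 2.4073e6


def _h_sphere(tk, pair_mb, speed):
    density = pair_mb * 100.0 / (_R_AIR * tk)
    re = speed * density * _D_GLOBE / _viscosity(tk)
    nu = 2.0 + 0.6 * np.sqrt(re) * _PR ** 0.3333
    return nu * _thermal_cond(tk) / _D_GLOBE


def _h_cylinder(tk, pair_mb, speed):
    density = pair_mb * 100.0 / (_R_AIR * tk)
    re = speed * density * _D_WICK / _viscosity(tk)
    nu = 0.56 * re ** 0.281 * _PR ** (1.0 / 3.0)
    return nu * _thermal_cond(tk) / _D_WICK


def _radiation_geometry(mrd, zenith, constants: WBGTConstants):
    """Effective solar flux, direct fraction and capped cos(zenith).

    The direct/diffuse split only applies with the sun above the horizon;
    at night the flux is zero and the split is irrelevant.
    """
    solar = np.maximum(np.asarray(mrd, dtype=float), 0.0)
    zenith = np.asarray(zenith, dtype=float)
    sun_up = (solar > 0.0) & (zenith < 90.0)
    solar = np.where(sun_up, solar, 0.0)
    fdir = np.where(sun_up, constants.prop_direct, 0.0)
    zen_eff = np.deg2rad(np.minimum(zenith, constants.zenith_cap_deg))
    return solar, fdir, np.cos(zen_eff), zen_eff


def _damped_fixed_point(step, t0, tol, max_iter):
    """Run the reference damped fixed-point scheme on arrays.

    ``step(t_prev)`` returns the undamped update.  Matches the reference
    loop exactly: convergence is |new - prev| < tol, the state advances as
    0.9 prev + 0.1 new, and the converged value is the *new* iterate at
    the step where the test first passes.
    """
    t_prev = np.array(t0, dtype=float, copy=True)
    result = np.full_like(t_prev, np.nan)
    converged = np.zeros(t_prev.shape, dtype=bool)
    iters = np.zeros(t_prev.shape, dtype=np.int64)
    for _ in range(max_iter):
        active = ~converged
        if not active.any():
            break
        with np.errstate(invalid="ignore", over="ignore", divide="ignore"):
            t_new = step(t_prev)
        hit = active & np.isfinite(t_new) & (np.abs(t_new - t_prev) < tol)
        result[hit] = t_new[hit]
        iters[active] += 1
        converged |= hit
        t_prev = np.where(converged, t_prev,
                          0.9 * t_prev + 0.1 * np.where(np.isfinite(t_new), t_new, t_prev))
    return result, converged, iters


def globe_temperature(inputs: WBGTInputs,
                      constants: WBGTConstants = WBGTConstants()):
    """Globe temperature Tg (degC) from the globe energy balance.

    Returns (Tg, converged, iterations); non-converged points are NaN.
    """
    Ta_k = np.asarray(inputs.Ta, dtype=float) + 273.15
    rh = np.asarray(inputs.RH, dtype=float) / 100.0
    pair = constants.atm_pressure * 10.0  # kPa -> mb
    speed = np.maximum(np.asarray(inputs.ws, dtype=float), constants.min_wind_speed)
    solar, fdir, cza, _ = _radiation_geometry(inputs.mrd, inputs.zenith, constants)
    Ta_k, rh, speed, solar, fdir, cza = np.broadcast_arrays(
        Ta_k, rh, speed, solar, fdir, cza)

    ea = _emis_atm(Ta_k, rh)
    lw_sky_sfc = 0.5 * (ea * Ta_k ** 4 + _EMIS_SFC * Ta_k ** 4)
    sw = (solar / (2.0 * _STEFANB * _EMIS_GLOBE) * (1.0 - _ALB_GLOBE)
          * (fdir * (1.0 / (2.0 * cza) - 1.0) + 1.0 + _ALB_SFC))

    def step(tg_prev):
        tref = 0.5 * (tg_prev + Ta_k)
        h = _h_sphere(tref, pair, speed)
        base = lw_sky_sfc - h / (_STEFANB * _EMIS_GLOBE) * (tg_prev - Ta_k) + sw
        return np.where(base > 0.0, base, np.nan) ** 0.25

    tg_k, converged, iters = _damped_fixed_point(
        step, Ta_k, constants.convergence_tol, constants.max_iterations)
    return tg_k - 273.15, converged, iters


def natural_wet_bulb(inputs: WBGTInputs,
                     constants: WBGTConstants = WBGTConstants()):
    """Natural wet-bulb temperature Tnwb (degC) from the wick balance.

    Returns (Tnwb, converged, iterations); non-converged points are NaN.
    """
    Ta_k = np.asarray(inputs.Ta, dtype=float) + 273.15
    Td_k = np.asarray(inputs.Td, dtype=float) + 273.15
    rh = np.asarray(inputs.RH, dtype=float) / 100.0
    pair = constants.atm_pressure * 10.0
    speed = np.maximum(np.asarray(inputs.ws, dtype=float), constants.min_wind_speed)
    solar, fdir, cza, sza = _radiation_geometry(inputs.mrd, inputs.zenith, constants)
    Ta_k, Td_k, rh, speed, solar, fdir, cza, sza = np.broadcast_arrays(
        Ta_k, Td_k, rh, speed, solar, fdir, cza, sza)

    eair = rh * _esat_mb(Ta_k)
    ea = _emis_atm(Ta_k, rh)
    lw_sky_sfc = 0.5 * (ea * Ta_k ** 4 + _EMIS_SFC * Ta_k ** 4)
    sw = ((1.0 - _ALB_WICK) * solar
          * ((1.0 - fdir) * (1.0 + 0.25 * _D_WICK / _L_WICK)
             + fdir * (np.tan(sza) / np.pi + 0.25 * _D_WICK / _L_WICK)
             + _ALB_SFC))

    def step(twb_prev):
        tref = 0.5 * (twb_prev + Ta_k)
        h = _h_cylinder(tref, pair, speed)
        fatm = _STEFANB * _EMIS_WICK * (lw_sky_sfc - twb_prev ** 4) + sw
        ewick = _esat_mb(twb_prev)
        density = pair * 100.0 / (_R_AIR * tref)
        sc = _viscosity(tref) / (density * _diffusivity(tref, pair))
        return (Ta_k - _latent_heat(tref) / _RATIO * (ewick - eair)
                / (pair - ewick) * (_PR / sc) ** 0.56 + fatm / h)

    tnwb_k, converged, iters = _damped_fixed_point(
        step, Td_k, constants.convergence_tol, constants.max_iterations)
    return tnwb_k - 273.15, converged, iters


def wbgt_star(Tnwb, Tg, Ta):
    """Composite index WBGT* = 0.7 Tnwb + 0.2 Tg + 0.1 Ta (degC).

    NaN in any component propagates to the output.
    """
    return 0.7 * np.asarray(Tnwb, dtype=float) \
        + 0.2 * np.asarray(Tg, dtype=float) \
        + 0.1 * np.asarray(Ta, dtype=float)


def compute_wbgt(inputs: WBGTInputs,
                 constants: WBGTConstants = WBGTConstants()) -> WBGTResult:
    """Run both solvers and compose WBGT* for one batch of inputs."""
    tg, conv_g, it_g = globe_temperature(inputs, constants)
    tnwb, conv_w, it_w = natural_wet_bulb(inputs, constants)
    converged = conv_g & conv_w
    tg = np.where(conv_g, tg, np.nan)
    tnwb = np.where(conv_w, tnwb, np.nan)
    return WBGTResult(Tnwb=tnwb, Tg=tg,
                      wbgt=wbgt_star(tnwb, tg, inputs.Ta),
                      converged=converged,
                      iterations=np.maximum(it_g, it_w))


def wbgt_field(met: xr.Dataset,
               constants: WBGTConstants = WBGTConstants()) -> xr.Dataset:
    """Hourly gridded WBGT* from a validated meteorology dataset.

    Expects variables t2m, d2m, uwd, vwd, msdwswrt on (time, latitude,
    longitude).  The solar zenith is evaluated per grid cell at each
    hourly interval's midpoint.  Returns a dataset with wbgt, tnwb, tg
    (degC) and the raw zenith (degrees), with the constants recorded as
    attributes.
    """
    required = ("t2m", "d2m", "uwd", "vwd", "msdwswrt")
    for name in required:
        if name not in met:
            raise KeyError(f"meteorology dataset is missing variable '{name}'")
        if met[name].dims != met["t2m"].dims or met[name].shape != met["t2m"].shape:
            raise ValueError(f"variable '{name}' does not share the grid/time "
                             "coordinates of 't2m'")

    zen = solar_zenith_grid(met.latitude.values, met.longitude.values,
                            hour_midpoint(met.time.values))
    inputs = derive_inputs(met.t2m.values, met.d2m.values,
                           met.uwd.values, met.vwd.values,
                           met.msdwswrt.values, zen, constants)
    res = compute_wbgt(inputs, constants)

    n = res.converged.size
    n_conv = int(res.converged.sum())
    log.info("wbgt_field: %d/%d cell-hours converged (max %d iterations)",
             n_conv, n, int(res.iterations.max(initial=0)))

    dims = ("time", "latitude", "longitude")
    coords = {d: met[d] for d in dims}
    out = xr.Dataset(
        {
            "wbgt": (dims, res.wbgt, {"units": "degC", "long_name": "wet-bulb globe temperature (inferred)"}),
            "tnwb": (dims, res.Tnwb, {"units": "degC", "long_name": "natural wet-bulb temperature"}),
            "tg": (dims, res.Tg, {"units": "degC", "long_name": "globe temperature"}),
            "zenith": (dims, np.broadcast_to(zen, res.wbgt.shape).copy(),
                       {"units": "degree", "long_name": "solar zenith angle (interval midpoint)"}),
        },
        coords=coords,
        attrs={f"wbgt_{k}": (int(v) if isinstance(v, bool) else v)
               for k, v in constants.asdict().items()},
    )
    out.attrs["wbgt_converged_fraction"] = n_conv / n if n else 1.0
    return out
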