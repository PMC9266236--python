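"""Scalar reference transcription of the published Liljegren WBGT code.

This is a deliberately literal, loop-based port of the public-domain C
reference implementation of the Liljegren outdoor WBGT model (globe and
natural wet-bulb energy balances).  It is kept independent of the package:
its own constants, its own helper functions, plain Python floats, no numpy
vectorization.  The test suite uses it as the oracle the vectorized
implementation must match to within 0.1 degC.

Conventions follow the reference code: temperatures in kelvin internally,
vapour pressures in millibar, barometric pressure in millibar, relative
humidity as a fraction (0-1).  Returns are in degC; -9999 flags
non-convergence.
"""

import math

# physical constants
STEFANB = 5.6696e-8
CP = 1003.5
M_AIR = 28.97
M_H2O = 18.015
RATIO = CP * M_AIR / M_H2O
R_GAS = 8314.34
R_AIR = R_GAS / M_AIR
PR = CP / (CP + 1.25 * R_AIR)

# wick constants
EMIS_WICK = 0.95
ALB_WICK = 0.4
D_WICK = 0.007
L_WICK = 0.0254

# globe constants
EMIS_GLOBE = 0.95
ALB_GLOBE = 0.05
D_GLOBE = 0.0508

# surface constants
EMIS_SFC = 0.999
ALB_SFC = 0.45

CONVERGENCE = 0.02
MAX_ITER = 50


def esat(tk):
    """Saturation vapour pressure (mb) over liquid water, Buck's formula
    with the 1.004 moist-air enhancement used by the reference code."""
    return 1.004 * 6.1121 * math.exp(17.502 * (tk - 273.15) / (tk - 32.18))


def dew_point(e):
    """Dew point (K) from vapour pressure (mb); inverse of esat."""
    z = math.log(e / (6.1121 * 1.004))
    return 273.15 + 240.97 * z / (17.502 - z)


def viscosity(tair):
    """Dynamic viscosity of air (kg/m/s), Chapman-Enskog with hard-coded
    collision integral fit."""
    sigma = 3.617
    eps_kappa = 97.0
    tr = tair / eps_kappa
    omega = (tr - 2.9) / 0.4 * (-0.034) + 1.048
    return 2.6693e-6 * math.sqrt(M_AIR * tair) / (sigma * sigma * omega)


def thermal_cond(tair):
    return (CP + 1.25 * R_AIR) * viscosity(tair)


def emis_atm(t, rh):
    """Clear-sky atmospheric emissivity from vapour pressure."""
    e = rh * esat(t)
    return 0.575 * e ** 0.143


def diffusivity(tair, pair):
    """Diffusivity of water vapour in air (m2/s), Chapman-Enskog critical
    property correlation."""
    pcrit13 = (36.4 * 218.0) ** (1.0 / 3.0)
    tcrit512 = (132.0 * 647.3) ** (5.0 / 12.0)
    tcrit12 = math.sqrt(132.0 * 647.3)
    mmix = math.sqrt(1.0 / M_AIR + 1.0 / M_H2O)
    return (0.000364 * (tair / tcrit12) ** 2.334 * pcrit13 * tcrit512 * mmix
            / (pair / 1013.25) * 1e-4)


def evap(tair):
    """Latent heat of vaporisation (J/kg), linear in temperature."""
    return (313.15 - tair) / 30.0 * (-71100.0) + 2.4073e6


def h_sphere_in_air(diameter, tair, pair, speed):
    """Convective heat-transfer coefficient for a sphere (W/m2/K)."""
    density = pair * 100.0 / (R_AIR * tair)
    re = speed * density * diameter / viscosity(tair)
    nu = 2.0 + 0.6 * math.sqrt(re) * PR ** 0.3333
    return nu * thermal_cond(tair) / diameter


def h_cylinder_in_air(diameter, tair, pair, speed):
    """Convective heat-transfer coefficient for a cylinder in cross flow
    (W/m2/K)."""
    a = 0.56
    b = 0.281
    density = pair * 100.0 / (R_AIR * tair)
    re = speed * density * diameter / viscosity(tair)
    nu = a * re ** b * PR ** (1.0 / 3.0)
    return nu * thermal_cond(tair) / diameter


def globe_temp(tair_k, rh, pair, speed, solar, fdir, cza):
    """Globe temperature (degC) by damped fixed-point iteration on the
    globe energy balance.  tair_k in K, rh fraction, pair mb."""
    tsfc = tair_k
    tglobe_prev = tair_k
    converged = False
    it = 0
    tglobe_new = tglobe_prev
    while not converged and it < MAX_ITER:
        it += 1
        tref = 0.5 * (tglobe_prev + tair_k)
        h = h_sphere_in_air(D_GLOBE, tref, pair, speed)
        tglobe_new = (0.5 * (emis_atm(tair_k, rh) * tair_k ** 4 + EMIS_SFC * tsfc ** 4)
                      - h / (STEFANB * EMIS_GLOBE) * (tglobe_prev - tair_k)
                      + solar / (2.0 * STEFANB * EMIS_GLOBE) * (1.0 - ALB_GLOBE)
                      * (fdir * (1.0 / (2.0 * cza) - 1.0) + 1.0 + ALB_SFC)) ** 0.25
        if abs(tglobe_new - tglobe_prev) < CONVERGENCE:
            converged = True
        tglobe_prev = 0.9 * tglobe_prev + 0.1 * tglobe_new
    if converged:
        return tglobe_new - 273.15
    return -9999.0


def natural_wet_bulb(tair_k, rh, pair, speed, solar, fdir, cza, irad=1.0):
    """Natural wet-bulb temperature (degC) by damped fixed-point iteration
    on the wetted-wick energy balance.  irad=1 includes radiation (natural
    wet bulb); irad=0 gives the psychrometric wet bulb."""
    a = 0.56
    tsfc = tair_k
    sza = math.acos(cza)
    eair = rh * esat(tair_k)
    tdew = dew_point(eair)
    twb_prev = tdew
    converged = False
    it = 0
    twb_new = twb_prev
    while not converged and it < MAX_ITER:
        it += 1
        tref = 0.5 * (twb_prev + tair_k)
        h = h_cylinder_in_air(D_WICK, tref, pair, speed)
        fatm = (STEFANB * EMIS_WICK
                * (0.5 * (emis_atm(tair_k, rh) * tair_k ** 4 + EMIS_SFC * tsfc ** 4)
                   - twb_prev ** 4)
                + (1.0 - ALB_WICK) * solar
                * ((1.0 - fdir) * (1.0 + 0.25 * D_WICK / L_WICK)
                   + fdir * ((math.tan(sza) / math.pi) + 0.25 * D_WICK / L_WICK)
                   + ALB_SFC))
        ewick = esat(twb_prev)
        density = pair * 100.0 / (R_AIR * tref)
        sc = viscosity(tref) / (density * diffusivity(tref, pair))
        twb_new = (tair_k - evap(tref) / RATIO * (ewick - eair) / (pair - ewick)
                   * (PR / sc) ** a + fatm / h * irad)
        if abs(twb_new - twb_prev) < CONVERGENCE:
            converged = True
        twb_prev = 0.9 * twb_prev + 0.1 * twb_new
    if converged:
        return twb_new - 273.15
    return -9999.0


def wbgt_oracle(ta_c, rh_pct, ws, mrd, zenith_deg,
                pressure_kpa=101.0, prop_direct=0.8, min_wind=0.1,
                zenith_cap=87.0):
    """Full oracle path: Tnwb, Tg, WBGT (degC) from degC/percent inputs.

    Mirrors the study's driver conventions: pressure in kPa converted to mb,
    wind floored at min_wind, direct fraction applied only with sun up,
    zenith capped for the radiative geometry terms.
    """
    tair_k = ta_c + 273.15
    rh = rh_pct / 100.0
    pair = pressure_kpa * 10.0
    speed = max(ws, min_wind)
    solar = max(mrd, 0.0)
    if solar > 0.0 and zenith_deg < 90.0:
        fdir = prop_direct
        zen = min(zenith_deg, zenith_cap)
    else:
        solar = 0.0
        fdir = 0.0
        zen = min(zenith_deg, zenith_cap)
    cza = math.cos(math.radians(zen))
    tg = globe_temp(tair_k, rh, pair, speed, solar, fdir, cza)
    tnwb = natural_wet_bulb(tair_k, rh, pair, speed, solar, fdir, cza)
    if tg == -9999.0 or tnwb == -9999.0:
        return float("nan"), float("nan"), float("nan")
    wbgt = 0.7 * tnwb + 0.2 * tg + 0.1 * ta_c
    return tnwb, tg, wbgt
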