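"""Hourly thermal indices from basic meteorology.

This module converts raw hourly surface meteorology (2-m air temperature,
2-m specific humidity, surface pressure, wind speed, downward shortwave
irradiance) into the three heat-exposure measures used throughout the
pipeline:

* relative humidity, from the vapor-pressure identity and a Magnus-form
  saturation curve;
* the US National Weather Service heat index (Rothfusz regression with the
  low/high-humidity adjustments and the Steadman simple-formula fallback
  below the 80 °F switchover);
* outdoor wet-bulb globe temperature (WBGT) via the Liljegren energy-balance
  solvers for the 0.0508-m black globe and the natural (unaspirated,
  sun-exposed) wet-bulb wick, combined as
  ``0.7 * t_nwb + 0.2 * t_globe + 0.1 * t_air``.

All physics is done in SI / °C internally; the heat index and WBGT are
reported in °F at the aggregation boundary. Functions are vectorized: any
argument may be a scalar or a numpy array, and the iterative solvers run
fixed-point sweeps over whole arrays with a per-element convergence mask, so
outputs are reproducible bit-for-bit for identical inputs and tolerances.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import ConvergenceError, DataIntegrityError, InvalidInputError

__all__ = [
    "SolverConfig",
    "SiteCoords",
    "relative_humidity",
    "saturation_vapor_pressure",
    "vapor_pressure_from_q",
    "dew_point",
    "heat_index",
    "globe_temperature",
    "natural_wet_bulb",
    "wbgt_outdoor",
    "derive_hourly",
    "solar_zenith",
    "direct_fraction",
    "globe_energy_residual",
    "wick_energy_residual",
    "c_to_f",
    "f_to_c",
]

# --- physical constants (SI) -------------------------------------------------
STEFANB = 5.6696e-8          # Stefan-Boltzmann, W m-2 K-4
M_AIR = 28.97                # g/mol dry air
M_H2O = 18.015               # g/mol water
R_GAS = 8314.34              # J kmol-1 K-1
R_AIR = R_GAS / M_AIR        # specific gas constant of dry air
CP = 1003.5                  # J kg-1 K-1
PRANDTL = 0.709
EPSILON = M_H2O / M_AIR      # 0.622, mixing-ratio constant
RATIO = CP * M_AIR / M_H2O
SOLAR_CONST = 1367.0         # W m-2

# Liljegren instrument geometry / radiative properties
D_GLOBE = 0.0508             # globe diameter, m
EMIS_GLOBE = 0.95
ALB_GLOBE = 0.05
D_WICK = 0.007               # wick diameter, m
L_WICK = 0.0254              # wick length, m
EMIS_WICK = 0.95
ALB_WICK = 0.4
EMIS_SFC = 0.999
ALB_SFC = 0.45

MIN_COS_ZENITH = np.cos(np.deg2rad(89.5))


@dataclass(frozen=True)
class SolverConfig:
    """Tolerances for the Liljegren fixed-point solvers.

    tolerance: convergence threshold on the bisection bracket width, °C.
        The default 1e-4 keeps the worst-case energy-balance residual well
        below 1e-3 of the governing flux scale even where the evaporation
        term is steep (hot, humid air).
    max_iter: iteration cap before a ConvergenceError is raised.
    min_wind: floor on wind speed, m/s, keeping the convective correlations
        defined in calm air.
    """

    tolerance: float = 1e-4
    max_iter: int = 100
    min_wind: float = 0.1


@dataclass(frozen=True)
class SiteCoords:
    """Geographic metadata needed for solar geometry at one location."""

    latitude: float
    longitude: float
    utc_offset: float  # hours, local standard time (e.g. -6 for US Central)


def c_to_f(t_c):
    return np.asarray(t_c, dtype=float) * 9.0 / 5.0 + 32.0


def f_to_c(t_f):
    return (np.asarray(t_f, dtype=float) - 32.0) * 5.0 / 9.0


def _check_finite(name, x):
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise InvalidInputError(f"non-finite value in '{name}'", field=name)
    return x


# --- humidity ----------------------------------------------------------------

def saturation_vapor_pressure(t_c):
    """Saturation vapor pressure over liquid water, Pa.

    Magnus form with the Alduchov & Eskridge coefficients
    (es = 610.94 exp(17.625 T / (243.04 + T)), T in °C), accurate to ~0.4 %
    over -40..50 °C.
    """
    t = np.asarray(t_c, dtype=float)
    return 610.94 * np.exp(17.625 * t / (243.04 + t))


def dew_point(e_pa):
    """Dew point (°C) from vapor pressure (Pa); inverse of the Magnus curve."""
    e = np.maximum(np.asarray(e_pa, dtype=float), 1e-6)
    ln = np.log(e / 610.94)
    return 243.04 * ln / (17.625 - ln)


def vapor_pressure_from_q(q, pressure):
    """Partial water-vapor pressure (Pa) from specific humidity and pressure.

    Uses the exact identity e = q p / (eps + (1 - eps) q) with eps = 0.622.
    """
    q = np.asarray(q, dtype=float)
    p = np.asarray(pressure, dtype=float)
    return q * p / (EPSILON + (1.0 - EPSILON) * q)


def relative_humidity(q, t_air, pressure):
    """Relative humidity (%) from specific humidity, temperature and pressure.

    Parameters
    ----------
    q : specific humidity, kg/kg (>= 0)
    t_air : air temperature, °C (plausible range -60..60)
    pressure : surface pressure, Pa (> 0)

    Returns the ratio of the vapor pressure implied by ``q`` to the
    saturation vapor pressure at ``t_air``, as a percentage clipped to
    [0, 100]. Supersaturated inputs therefore report 100 %.
    """
    q = _check_finite("q", q)
    t = _check_finite("t_air", t_air)
    p = _check_finite("pressure", pressure)
    if np.any(q < 0):
        raise InvalidInputError("specific humidity must be >= 0", field="q")
    if np.any(p <= 0):
        raise InvalidInputError("pressure must be > 0", field="pressure")
    if np.any((t < -60) | (t > 60)):
        raise InvalidInputError(
            "t_air outside plausible range [-60, 60] °C", field="t_air"
        )
    e = vapor_pressure_from_q(q, p)
    rh = 100.0 * e / saturation_vapor_pressure(t)
    return np.clip(rh, 0.0, 100.0)


# --- NWS heat index ----------------------------------------------------------

def heat_index(t_air_f, rh):
    """NWS heat index, °F, from air temperature (°F) and RH (%).

    Follows the NWS operational procedure: the Steadman simple formula
    ``0.5 (T + 61 + 1.2 (T - 68) + 0.094 RH)`` (already an average of T with
    the simple apparent temperature) is evaluated first; at or above the
    80 °F switchover the Rothfusz multiple regression replaces it, with the
    published low-RH (RH < 13 %, 80..112 °F) and high-RH (RH > 85 %,
    80..87 °F) adjustment terms. The hand-off is continuous at the
    switchover by construction of the NWS procedure.
    """
    t = _check_finite("t_air_f", t_air_f)
    r = _check_finite("rh", rh)
    if np.any((r < 0) | (r > 100)):
        raise InvalidInputError("rh must be within [0, 100]", field="rh")
    t, r = np.broadcast_arrays(t, r)
    simple = 0.5 * (t + 61.0 + (t - 68.0) * 1.2 + r * 0.094)

    hi = np.array(simple, dtype=float, copy=True)
    hot = simple >= 80.0
    if np.any(hot):
        th, rh_h = t[hot], r[hot]
        roth = (
            -42.379
            + 2.04901523 * th
            + 10.14333127 * rh_h
            - 0.22475541 * th * rh_h
            - 6.83783e-3 * th * th
            - 5.481717e-2 * rh_h * rh_h
            + 1.22874e-3 * th * th * rh_h
            + 8.5282e-4 * th * rh_h * rh_h
            - 1.99e-6 * th * th * rh_h * rh_h
        )
        low = (rh_h < 13.0) & (th >= 80.0) & (th <= 112.0)
        adj_low = ((13.0 - rh_h) / 4.0) * np.sqrt(
            np.maximum(17.0 - np.abs(th - 95.0), 0.0) / 17.0
        )
        roth = np.where(low, roth - adj_low, roth)
        high = (rh_h > 85.0) & (th >= 80.0) & (th <= 87.0)
        adj_high = ((rh_h - 85.0) / 10.0) * ((87.0 - th) / 5.0)
        roth = np.where(high, roth + adj_high, roth)
        hi[hot] = roth
    return hi if hi.ndim else float(hi)


# --- solar geometry ----------------------------------------------------------

def solar_zenith(timestamps, latitude, longitude, utc_offset):
    """Solar zenith angle (radians) for naive local-standard-time stamps.

    Uses the NOAA low-accuracy algorithm (Fourier declination and equation
    of time), adequate for partitioning irradiance into direct and diffuse
    components. ``longitude`` is degrees east (negative in the US);
    ``utc_offset`` in hours matches the local standard time of the stamps.
    """
    ts = pd.DatetimeIndex(timestamps)
    doy = ts.dayofyear.to_numpy(dtype=float)
    hour = ts.hour.to_numpy(dtype=float) + ts.minute.to_numpy(dtype=float) / 60.0
    g = 2.0 * np.pi / 365.0 * (doy - 1.0 + (hour - 12.0) / 24.0)
    decl = (
        0.006918
        - 0.399912 * np.cos(g)
        + 0.070257 * np.sin(g)
        - 0.006758 * np.cos(2 * g)
        + 0.000907 * np.sin(2 * g)
        - 0.002697 * np.cos(3 * g)
        + 0.00148 * np.sin(3 * g)
    )
    eqtime = 229.18 * (
        0.000075
        + 0.001868 * np.cos(g)
        - 0.032077 * np.sin(g)
        - 0.014615 * np.cos(2 * g)
        - 0.040849 * np.sin(2 * g)
    )
    tst = hour * 60.0 + eqtime + 4.0 * longitude - 60.0 * utc_offset
    ha = np.deg2rad(tst / 4.0 - 180.0)
    lat = np.deg2rad(latitude)
    cosz = np.sin(lat) * np.sin(decl) + np.cos(lat) * np.cos(decl) * np.cos(ha)
    return np.arccos(np.clip(cosz, -1.0, 1.0))


def direct_fraction(solar, cos_zenith):
    """Direct-beam fraction of global horizontal irradiance (Liljegren).

    The clearness index star = solar / (top-of-atmosphere irradiance on the
    horizontal) drives ``fdir = exp(3 - 1.34 star - 1.65 / star)``, clipped
    to [0, 0.9]; star itself is capped at 0.85. Near or below the horizon
    (cos z < cos 89.5°) everything is treated as diffuse. Also returns the
    irradiance capped at its clear-sky maximum, which the solvers use.
    """
    solar = np.asarray(solar, dtype=float)
    cza = np.asarray(cos_zenith, dtype=float)
    solar, cza = np.broadcast_arrays(solar, cza)
    toa = SOLAR_CONST * np.maximum(cza, 0.0)
    up = (solar > 10.0) & (cza > MIN_COS_ZENITH)
    with np.errstate(divide="ignore", invalid="ignore"):
        star = np.where(up, np.minimum(solar / np.where(toa > 0, toa, 1.0), 0.85), 0.0)
        fdir = np.where(
            star > 0, np.exp(3.0 - 1.34 * star - 1.65 / np.maximum(star, 1e-9)), 0.0
        )
    fdir = np.clip(fdir, 0.0, 0.9)
    solar_adj = np.where(up, np.minimum(solar, 0.85 * toa), np.where(cza > 0, solar, 0.0))
    return fdir, solar_adj


# --- air transport properties ------------------------------------------------

def _viscosity(tk):
    """Dynamic viscosity of air, kg m-1 s-1 (Sutherland)."""
    return 1.458e-6 * tk ** 1.5 / (tk + 110.4)


def _thermal_conductivity(tk):
    """Thermal conductivity of air, W m-1 K-1 (Eucken-type, from viscosity)."""
    return (CP + 1.25 * R_AIR) * _viscosity(tk)


def _h_sphere(tk, p_pa, speed):
    """Convective heat-transfer coefficient for the globe, W m-2 K-1."""
    density = p_pa / (R_AIR * tk)
    re = speed * density * D_GLOBE / _viscosity(tk)
    nu = 2.0 + 0.6 * np.sqrt(re) * PRANDTL ** (1.0 / 3.0)
    return nu * _thermal_conductivity(tk) / D_GLOBE


def _h_cylinder(tk, p_pa, speed):
    """Convective heat-transfer coefficient for the wick, W m-2 K-1."""
    a, b, c = 0.56, 0.281, 0.4
    density = p_pa / (R_AIR * tk)
    re = speed * density * D_WICK / _viscosity(tk)
    nu = b * re ** (1.0 - c) * PRANDTL ** (1.0 - a)
    return nu * _thermal_conductivity(tk) / D_WICK


def _diffusivity(tk, p_pa):
    """Binary diffusivity of water vapor in air, m2 s-1."""
    pcrit13 = (36.4 * 218.0) ** (1.0 / 3.0)
    tcrit512 = (132.0 * 647.3) ** (5.0 / 12.0)
    tcrit12 = np.sqrt(132.0 * 647.3)
    mmix = np.sqrt(1.0 / M_AIR + 1.0 / M_H2O)
    patm = p_pa / 101325.0
    return 3.640e-4 * (tk / tcrit12) ** 2.334 * pcrit13 * tcrit512 * mmix / patm * 1e-4


def _evap_heat(tk):
    """Latent heat of vaporization of water, J kg-1, linear in temperature."""
    return (313.15 - tk) / 30.0 * (-71100.0) + 2.4073e6


def _emis_atm(t_air_k, e_pa):
    """Clear-sky atmospheric emissivity, 0.575 e^{1/7} with e in hPa.

    Capped at 1: the empirical fit exceeds unity above ~49 hPa vapor
    pressure (hot, near-saturated air), which would make the sky radiate
    more than a blackbody and push the wet bulb above the air temperature.
    """
    return np.minimum(0.575 * np.maximum(e_pa / 100.0, 1e-3) ** (1.0 / 7.0), 1.0)


# --- energy-balance residuals (used by the solvers and the tests) ------------

def globe_energy_residual(t_globe_c, t_air_c, rh, pressure_pa, wind_ms,
                          solar_wm2, fdir=0.0, cos_zenith=1.0,
                          min_wind=0.1):
    """Net flux on the globe, W m-2, at a candidate globe temperature.

    Positive residual means the globe would still warm. Zero at the
    converged solution (to within solver tolerance).
    """
    tg = np.asarray(t_globe_c, dtype=float) + 273.15
    ta = np.asarray(t_air_c, dtype=float) + 273.15
    e = np.asarray(rh, dtype=float) / 100.0 * saturation_vapor_pressure(t_air_c)
    speed = np.maximum(np.asarray(wind_ms, dtype=float), min_wind)
    tref = 0.5 * (tg + ta)
    h = _h_sphere(tref, pressure_pa, speed)
    ea = _emis_atm(ta, e)
    lw = EMIS_GLOBE * STEFANB * (
        0.5 * (ea * ta ** 4 + EMIS_SFC * ta ** 4) - tg ** 4
    )
    cza = np.maximum(np.asarray(cos_zenith, dtype=float), MIN_COS_ZENITH)
    sw = (
        np.asarray(solar_wm2, dtype=float)
        / 2.0
        * (1.0 - ALB_GLOBE)
        * (np.asarray(fdir, dtype=float) * (1.0 / (2.0 * cza) - 1.0) + 1.0 + ALB_SFC)
    )
    return lw + sw + h * (ta - tg)


def wick_energy_residual(t_nwb_c, t_air_c, rh, pressure_pa, wind_ms,
                         solar_wm2, fdir=0.0, zenith_rad=0.0,
                         min_wind=0.1):
    """Net flux on the natural wet-bulb wick, W m-2, at a candidate Twb."""
    tw = np.asarray(t_nwb_c, dtype=float) + 273.15
    ta = np.asarray(t_air_c, dtype=float) + 273.15
    p = np.asarray(pressure_pa, dtype=float)
    e_air = np.asarray(rh, dtype=float) / 100.0 * saturation_vapor_pressure(t_air_c)
    speed = np.maximum(np.asarray(wind_ms, dtype=float), min_wind)
    tref = 0.5 * (tw + ta)
    h = _h_cylinder(tref, p, speed)
    ea = _emis_atm(ta, e_air)
    fatm = STEFANB * EMIS_WICK * (
        0.5 * (ea * ta ** 4 + EMIS_SFC * ta ** 4) - tw ** 4
    ) + (1.0 - ALB_WICK) * np.asarray(solar_wm2, dtype=float) * (
        (1.0 - np.asarray(fdir, dtype=float)) * (1.0 + 0.25 * D_WICK / L_WICK)
        + np.asarray(fdir, dtype=float)
        * (np.tan(np.minimum(np.asarray(zenith_rad, dtype=float), 1.562)) / np.pi
           + 0.25 * D_WICK / L_WICK)
        + ALB_SFC
    )
    e_wick = saturation_vapor_pressure(tw - 273.15)
    sc = _viscosity(tref) / ((p / (R_AIR * tref)) * _diffusivity(tref, p))
    evap_flux = (
        h
        * _evap_heat(tref)
        / RATIO
        * (e_wick - e_air)
        / (p - e_wick)
        * (PRANDTL / sc) ** 0.56
    )
    return h * (ta - tw) + fatm - evap_flux


# --- Liljegren solvers -------------------------------------------------------

def _bisect(residual, lo, hi, config: SolverConfig, label: str, policy: str):
    """Vectorized bisection on a monotone-decreasing flux residual.

    The bracket must satisfy residual(lo) >= 0 >= residual(hi); elements
    violating it (physically impossible inputs) are treated as
    non-convergent. Bisection halves the bracket until its width falls
    below the configured tolerance, so the result is deterministic.
    """
    lo = np.array(lo, dtype=float, copy=True)
    hi = np.array(hi, dtype=float, copy=True)
    ok = (residual(lo) >= 0) & (residual(hi) <= 0)
    for _ in range(config.max_iter):
        mid = 0.5 * (lo + hi)
        take_lo = residual(mid) > 0
        lo = np.where(take_lo, mid, lo)
        hi = np.where(take_lo, hi, mid)
        if float(np.max(hi - lo)) < config.tolerance:
            break
    out = 0.5 * (lo + hi)
    wide = (hi - lo) >= config.tolerance
    bad = ~ok | wide
    if bad.any():
        worst = float(np.nanmax(np.abs(residual(out))))
        if policy == "raise":
            raise ConvergenceError(
                f"{label} solver failed to converge for {int(bad.sum())} "
                f"point(s) within {config.max_iter} iterations "
                f"(worst |residual| {worst:.3g} W/m^2)",
                residual=worst,
            )
        out[bad] = np.nan
    return out


def globe_temperature(t_air_c, rh, pressure_pa, wind_ms, solar_wm2,
                      fdir=0.0, cos_zenith=1.0,
                      config: SolverConfig | None = None, policy="raise"):
    """Black-globe temperature (°C) from the Liljegren energy balance.

    Absorbed solar (direct + diffuse + ground-reflected) and thermal
    radiation from sky and ground balance convective exchange and emission
    from a standard 0.0508-m globe. Solved by damped fixed-point iteration
    on the quartic balance; the converged value zeroes
    :func:`globe_energy_residual` to within solver tolerance.
    """
    cfg = config or SolverConfig()
    ta = np.asarray(t_air_c, dtype=float) + 273.15
    scalar = ta.ndim == 0
    ta = np.atleast_1d(ta)
    e = np.atleast_1d(
        np.asarray(rh, dtype=float) / 100.0 * saturation_vapor_pressure(t_air_c)
    )
    p = np.atleast_1d(np.asarray(pressure_pa, dtype=float))
    speed = np.maximum(np.atleast_1d(np.asarray(wind_ms, dtype=float)), cfg.min_wind)
    solar = np.atleast_1d(np.asarray(solar_wm2, dtype=float))
    fd = np.atleast_1d(np.asarray(fdir, dtype=float))
    cza = np.maximum(np.atleast_1d(np.asarray(cos_zenith, dtype=float)), MIN_COS_ZENITH)
    ta, e, p, speed, solar, fd, cza = np.broadcast_arrays(
        ta, e, p, speed, solar, fd, cza
    )
    ea = _emis_atm(ta, e)
    lw_in = 0.5 * (ea * ta ** 4 + EMIS_SFC * ta ** 4)
    sw_flux = solar / 2.0 * (1.0 - ALB_GLOBE) * (
        fd * (1.0 / (2.0 * cza) - 1.0) + 1.0 + ALB_SFC
    )

    def residual(tg):
        tref = 0.5 * (tg + ta)
        h = _h_sphere(tref, p, speed)
        return (
            EMIS_GLOBE * STEFANB * (lw_in - tg ** 4)
            + sw_flux
            + h * (ta - tg)
        )

    tg = _bisect(residual, ta - 40.0, ta + 150.0, cfg, "globe temperature", policy)
    out = tg - 273.15
    return float(out[0]) if scalar else out


def natural_wet_bulb(t_air_c, rh, pressure_pa, wind_ms, solar_wm2,
                     fdir=0.0, zenith_rad=0.0,
                     config: SolverConfig | None = None, policy="raise"):
    """Natural wet-bulb temperature (°C) from the Liljegren wick balance.

    Balances convective exchange, absorbed solar and thermal radiation
    against evaporative cooling for a freely exposed wetted wick. The
    converged value zeroes :func:`wick_energy_residual` to within solver
    tolerance. Unlike the aspirated psychrometric wet bulb it can exceed it
    under radiative load and approaches it in the no-sun, ventilated limit.
    """
    cfg = config or SolverConfig()
    ta = np.asarray(t_air_c, dtype=float) + 273.15
    scalar = ta.ndim == 0
    ta = np.atleast_1d(ta)
    e_air = np.atleast_1d(
        np.asarray(rh, dtype=float) / 100.0 * saturation_vapor_pressure(t_air_c)
    )
    p = np.atleast_1d(np.asarray(pressure_pa, dtype=float))
    speed = np.maximum(np.atleast_1d(np.asarray(wind_ms, dtype=float)), cfg.min_wind)
    solar = np.atleast_1d(np.asarray(solar_wm2, dtype=float))
    fd = np.atleast_1d(np.asarray(fdir, dtype=float))
    sza = np.atleast_1d(np.asarray(zenith_rad, dtype=float))
    ta, e_air, p, speed, solar, fd, sza = np.broadcast_arrays(
        ta, e_air, p, speed, solar, fd, sza
    )
    ea = _emis_atm(ta, e_air)
    lw_in = 0.5 * (ea * ta ** 4 + EMIS_SFC * ta ** 4)
    sw = (1.0 - ALB_WICK) * solar * (
        (1.0 - fd) * (1.0 + 0.25 * D_WICK / L_WICK)
        + fd * (np.tan(np.minimum(sza, 1.562)) / np.pi + 0.25 * D_WICK / L_WICK)
        + ALB_SFC
    )

    def residual(tw):
        tref = 0.5 * (tw + ta)
        h = _h_cylinder(tref, p, speed)
        fatm = STEFANB * EMIS_WICK * (lw_in - tw ** 4) + sw
        e_wick = saturation_vapor_pressure(tw - 273.15)
        sc = _viscosity(tref) / ((p / (R_AIR * tref)) * _diffusivity(tref, p))
        evap_flux = (
            h
            * _evap_heat(tref)
            / RATIO
            * (e_wick - e_air)
            / np.maximum(p - e_wick, 1.0)
            * (PRANDTL / sc) ** 0.56
        )
        return h * (ta - tw) + fatm - evap_flux

    tw = _bisect(residual, ta - 60.0, ta + 30.0, cfg, "natural wet bulb", policy)
    out = tw - 273.15
    return float(out[0]) if scalar else out


def wbgt_outdoor(t_nwb, t_globe, t_air):
    """Outdoor WBGT: 0.7 Tnwb + 0.2 Tg + 0.1 Ta (any consistent unit)."""
    parts = [np.asarray(x, dtype=float) for x in (t_nwb, t_globe, t_air)]
    if any(not np.all(np.isfinite(x)) for x in parts):
        raise InvalidInputError("WBGT components must be finite")
    return 0.7 * parts[0] + 0.2 * parts[1] + 0.1 * parts[2]


# --- batch driver ------------------------------------------------------------

HOURLY_COLUMNS = ["location_id", "timestamp", "t_air_c", "q_kgkg",
                  "pressure_pa", "wind_ms", "solar_wm2"]


def _validate_hourly(df: pd.DataFrame):
    missing = [c for c in HOURLY_COLUMNS if c not in df.columns]
    if missing:
        raise InvalidInputError(
            f"hourly table missing column(s): {missing}", field=missing[0]
        )
    dup = df.duplicated(subset=["location_id", "timestamp"])
    if dup.any():
        first = df.loc[dup.idxmax()]
        raise DataIntegrityError(
            "duplicate (location_id, timestamp): "
            f"{first['location_id']} @ {first['timestamp']}"
        )


def derive_hourly(df: pd.DataFrame, sites: dict[str, SiteCoords] | None = None,
                  config: SolverConfig | None = None,
                  policy: str = "raise") -> pd.DataFrame:
    """Derive RH, heat index and WBGT for a batch of hourly records.

    Parameters
    ----------
    df : hourly meteorology with columns
        location_id, timestamp, t_air_c, q_kgkg, pressure_pa, wind_ms,
        solar_wm2 (timestamps in local standard time, unique per location).
    sites : optional mapping location_id -> SiteCoords. When present, solar
        zenith angles drive the Liljegren direct/diffuse partitioning; when
        absent all irradiance is treated as diffuse and a warning is issued.
    policy : 'raise' fails fast on invalid rows or non-convergence, naming
        the offending row; 'flag' leaves NaN in the derived columns instead.

    Returns a copy of ``df`` with columns rh_pct, hi_f, t_air_f, t_globe_c,
    t_nwb_c, wbgt_f appended, aligned 1:1 with the input rows.
    """
    cfg = config or SolverConfig()
    _validate_hourly(df)
    out = df.copy()
    if len(out) == 0:
        for c in ["rh_pct", "hi_f", "t_air_f", "t_globe_c", "t_nwb_c", "wbgt_f"]:
            out[c] = pd.Series(dtype=float)
        return out

    raw = out[["t_air_c", "q_kgkg", "pressure_pa", "wind_ms", "solar_wm2"]].to_numpy(
        dtype=float
    )
    bad = ~np.isfinite(raw).all(axis=1)
    bad |= (raw[:, 1] < 0) | (raw[:, 2] <= 0) | (raw[:, 3] < 0) | (raw[:, 4] < 0)
    if bad.any() and policy == "raise":
        i = int(np.argmax(bad))
        raise InvalidInputError(
            f"invalid meteorology in row {out.index[i]} "
            f"(location {out['location_id'].iloc[i]} @ {out['timestamp'].iloc[i]})"
        )
    ok = ~bad

    t_air = raw[ok, 0]
    q = raw[ok, 1]
    p = raw[ok, 2]
    wind = raw[ok, 3]
    solar = raw[ok, 4]

    rh = relative_humidity(q, t_air, p)

    # solar geometry per location
    fdir = np.zeros_like(solar)
    zen = np.zeros_like(solar)
    if sites is not None:
        ts = pd.DatetimeIndex(out.loc[ok, "timestamp"])
        locs = out.loc[ok, "location_id"].to_numpy()
        for loc in np.unique(locs):
            if loc not in sites:
                raise InvalidInputError(f"no coordinates for location '{loc}'")
            m = locs == loc
            sc = sites[loc]
            zen[m] = solar_zenith(ts[m], sc.latitude, sc.longitude, sc.utc_offset)
        fdir, solar = direct_fraction(solar, np.cos(zen))
    elif np.any(solar > 0):
        warnings.warn(
            "no site coordinates supplied; treating all solar irradiance as "
            "diffuse",
            stacklevel=2,
        )

    tg = globe_temperature(t_air, rh, p, wind, solar, fdir=fdir,
                           cos_zenith=np.cos(zen), config=cfg, policy=policy)
    tnwb = natural_wet_bulb(t_air, rh, p, wind, solar, fdir=fdir,
                            zenith_rad=zen, config=cfg, policy=policy)
    wbgt_c = wbgt_outdoor(tnwb, tg, t_air)

    n = len(out)
    cols = {
        "rh_pct": np.full(n, np.nan),
        "hi_f": np.full(n, np.nan),
        "t_air_f": c_to_f(raw[:, 0]),
        "t_globe_c": np.full(n, np.nan),
        "t_nwb_c": np.full(n, np.nan),
        "wbgt_f": np.full(n, np.nan),
    }
    cols["rh_pct"][ok] = rh
    cols["hi_f"][ok] = heat_index(c_to_f(t_air), rh)
    cols["t_globe_c"][ok] = tg
    cols["t_nwb_c"][ok] = tnwb
    cols["wbgt_f"][ok] = c_to_f(wbgt_c)
    for k, v in cols.items():
        out[k] = v
    return out
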