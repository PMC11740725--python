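"""Wet bulb globe temperature (WBGT) from hourly meteorology.

Outdoor WBGT is assembled from three temperatures:

* the natural wet-bulb temperature ``Tw``, approximated from air temperature
  and relative humidity with Stull's (2011) arctangent fit;
* the black-globe temperature ``Tg``, the equilibrium temperature of a
  standard 15 cm globe, solved from a radiative-convective energy balance in
  the Liljegren et al. (2008) formulation;
* the 2-m air temperature ``Ta``.

For sun-exposed hours ``WBGT = 0.7*Tw + 0.2*Tg + 0.1*Ta``.  For hours with
no sunlight (shade or night) the globe term drops out and the wind speed
selects between a windy form ``0.7*Tw + 0.3*Ta`` (u > 3 m/s) and a calm form
``0.67*Tw + 0.33*Ta - 0.048*log10(u)*(Ta - Tw)``.

All temperatures are degrees Celsius at every public interface; Kelvin is
used only inside the radiative algebra.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional

import numpy as np
import pandas as pd
from scipy.optimize import brentq

__all__ = [
    "STEFAN_BOLTZMANN",
    "MetSample",
    "GlobeParams",
    "SunRule",
    "WBGTRecord",
    "wet_bulb_stull",
    "globe_temperature",
    "wbgt_no_sun",
    "wbgt_sun",
    "compute_wbgt_series",
    "read_met_csv",
    "write_wbgt_csv",
    "read_wbgt_csv",
]

#: Stefan-Boltzmann constant, W m^-2 K^-4 (CODATA).
STEFAN_BOLTZMANN = 5.670374419e-8

_KELVIN = 273.15

# Columns of the hourly met CSV schema shared with synthetic_met.
MET_CSV_COLUMNS = [
    "location_id",
    "timestamp_local",
    "Ta_C",
    "RH_pct",
    "u_ms",
    "Kdown_Wm2",
    "Kup_Wm2",
    "Ldown_Wm2",
    "Lup_Wm2",
    "F_frac",
    "zenith_deg",
    "scenario",
]

WBGT_CSV_COLUMNS = [
    "location_id",
    "timestamp_local",
    "scenario",
    "Tw_C",
    "Tg_C",
    "WBGT_C",
    "branch",
    "iterations",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MetSample:
    """One hour of micrometeorology at one location under one scenario.

    Fluxes are W/m^2 on a horizontal surface: ``Kdown``/``Kup`` shortwave,
    ``Ldown``/``Lup`` longwave.  ``F`` is the direct-beam fraction of total
    horizontal shortwave and ``Z`` the solar zenith angle in degrees.
    """

    Ta: float
    RH: float
    u: float
    Kdown: float
    Kup: float
    Ldown: float
    Lup: float
    F: float
    Z: float
    timestamp_local: Optional[pd.Timestamp] = None
    location_id: str = ""
    scenario: str = ""

    def __post_init__(self) -> None:
        if not (0.0 <= self.RH <= 100.0):
            raise ValueError(f"RH must be in [0, 100] %, got {self.RH}")
        if self.u < 0:
            raise ValueError(f"wind speed must be >= 0, got {self.u}")
        for name in ("Kdown", "Kup", "Ldown", "Lup"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not (0.0 <= self.F <= 1.0):
            raise ValueError(f"direct-beam fraction must be in [0, 1], got {self.F}")


@dataclass(frozen=True)
class GlobeParams:
    """Physical constants and solver settings for the globe-temperature balance.

    Defaults describe the standard 15 cm black globe: emissivity 0.95,
    shortwave albedo 0.05.  The convective coefficient ``h_c`` comes from a
    forced-convection smooth-sphere Nusselt correlation
    ``Nu = nu_const + nu_coeff * Re**nu_exp * Pr**(1/3)`` (Ranz-Marshall
    coefficients by default) with air properties evaluated at the film
    temperature.  The fixed-point iteration stops when successive globe
    temperatures agree to ``tolerance`` (0.02 degC).
    """

    epsilon_g: float = 0.95
    alpha_g: float = 0.05
    diameter: float = 0.15
    sigma: float = STEFAN_BOLTZMANN
    tolerance: float = 0.02
    max_iterations: int = 50
    damping: float = 0.5
    cos_zenith_floor: float = 0.02
    nu_const: float = 2.0
    nu_coeff: float = 0.6
    nu_exp: float = 0.5
    pressure_pa: float = 101325.0

    def __post_init__(self) -> None:
        if not (0.0 < self.epsilon_g <= 1.0):
            raise ValueError("globe emissivity must be in (0, 1]")
        if not (0.0 <= self.alpha_g < 1.0):
            raise ValueError("globe albedo must be in [0, 1)")
        if self.tolerance <= 0:
            raise ValueError("tolerance must be > 0")


@dataclass(frozen=True)
class SunRule:
    """Decides whether an hour is treated as sun-exposed.

    An hour uses the sun form (globe temperature solved) iff the downwelling
    shortwave exceeds ``kdown_threshold`` and the sun is above the horizon.
    """

    kdown_threshold: float = 25.0
    zenith_max: float = 90.0

    def is_sun(self, Kdown: float, Z: float) -> bool:
        return Kdown > self.kdown_threshold and Z < self.zenith_max


@dataclass(frozen=True)
class WBGTRecord:
    Tw: float
    Tg: Optional[float]
    WBGT: float
    branch: str  # sun | no_sun_windy | no_sun_calm
    iterations_used: int = 0
    timestamp_local: Optional[pd.Timestamp] = None
    location_id: str = ""
    scenario: str = ""


# ---------------------------------------------------------------------------
# wet bulb (Stull approximation)
# ---------------------------------------------------------------------------

#: Validity window of the Stull fit.
STULL_RH_RANGE = (5.0, 99.0)
STULL_TA_RANGE = (-20.0, 50.0)


def wet_bulb_stull(Ta, RH):
    """Natural wet-bulb temperature (degC) from Stull's arctangent fit.

    ``Tw = Ta*atan(0.151977*sqrt(RH + 8.313659)) + atan(Ta + RH)
    - atan(RH - 1.676331) + 0.00391838*RH**1.5*atan(0.023101*RH)
    - 4.686035`` with arctangents in radians, Ta in degC and RH in percent.

    Accepts scalars or numpy arrays.  Inputs outside the fit's stated
    validity window (RH 5-99 %, Ta -20..50 degC) raise a warning but are
    still evaluated; NaN inputs raise ``ValueError``.
    """
    Ta_arr = np.asarray(Ta, dtype=float)
    RH_arr = np.asarray(RH, dtype=float)
    if np.any(np.isnan(Ta_arr)) or np.any(np.isnan(RH_arr)):
        raise ValueError("NaN inputs to wet_bulb_stull")
    out_of_window = (
        (RH_arr < STULL_RH_RANGE[0])
        | (RH_arr > STULL_RH_RANGE[1])
        | (Ta_arr < STULL_TA_RANGE[0])
        | (Ta_arr > STULL_TA_RANGE[1])
    )
    if np.any(out_of_window):
        warnings.warn(
            "wet_bulb_stull evaluated outside its validity window "
            "(RH 5-99 %, Ta -20..50 degC)",
            RuntimeWarning,
            stacklevel=2,
        )
    Tw = (
        Ta_arr * np.arctan(0.151977 * np.sqrt(RH_arr + 8.313659))
        + np.arctan(Ta_arr + RH_arr)
        - np.arctan(RH_arr - 1.676331)
        + 0.00391838 * RH_arr**1.5 * np.arctan(0.023101 * RH_arr)
        - 4.686035
    )
    if np.isscalar(Ta) and np.isscalar(RH):
        return float(Tw)
    return Tw


# ---------------------------------------------------------------------------
# globe temperature (radiative-convective energy balance)
# ---------------------------------------------------------------------------


def _air_conductivity(T_k: float) -> float:
    # W m^-1 K^-1; power-law fit around 300 K
    return 0.02624 * (T_k / 300.0) ** 0.8646


def _air_dynamic_viscosity(T_k: float) -> float:
    # Sutherland's law, kg m^-1 s^-1
    return 1.458e-6 * T_k**1.5 / (T_k + 110.4)


def convective_coefficient(u: float, T_film_k: float, params: GlobeParams) -> float:
    """Sphere convective heat-transfer coefficient h_c (W m^-2 K^-1).

    Nu = nu_const + nu_coeff * Re**nu_exp * Pr**(1/3), evaluated with air
    properties at the film temperature; the additive constant keeps a
    conductive floor as u -> 0.
    """
    k = _air_conductivity(T_film_k)
    mu = _air_dynamic_viscosity(T_film_k)
    rho = params.pressure_pa / (287.05 * T_film_k)
    cp = 1006.0
    pr = cp * mu / k
    re = max(u, 0.0) * rho * params.diameter / mu
    nu = params.nu_const + params.nu_coeff * re**params.nu_exp * pr ** (1.0 / 3.0)
    return nu * k / params.diameter


def _radiative_load(met: MetSample, params: GlobeParams) -> float:
    """Sum of the Tg-independent radiative terms of the balance, in K^4."""
    sigma = params.sigma
    eps = params.epsilon_g
    a_g = params.alpha_g
    cos_z = max(math.cos(math.radians(met.Z)), params.cos_zenith_floor)
    longwave = (met.Ldown + met.Lup) / (2.0 * sigma)
    direct_diffuse = (
        met.Kdown
        * (1.0 - a_g)
        / (2.0 * eps * sigma)
        * (1.0 - met.F + met.F / (2.0 * cos_z))
    )
    reflected = (1.0 - a_g) / (2.0 * eps * sigma) * met.Kup
    return longwave + direct_diffuse + reflected


def _globe_residual(Tg_c: float, met: MetSample, params: GlobeParams, load: float) -> float:
    """Energy-balance residual Tg^4 - rhs(Tg) in K^4 units."""
    tg_k = Tg_c + _KELVIN
    ta_k = met.Ta + _KELVIN
    t_film = 0.5 * (tg_k + ta_k)
    hc = convective_coefficient(met.u, t_film, params)
    rhs = load - hc * (Tg_c - met.Ta) / (params.epsilon_g * params.sigma)
    return tg_k**4 - rhs


def globe_temperature(met: MetSample, params: GlobeParams = GlobeParams()) -> tuple[float, int]:
    """Solve the globe-temperature energy balance; returns (Tg degC, iterations).

    The balance equates the globe's blackbody emission ``Tg_K**4`` with the
    mean long- and shortwave radiative load minus the convective exchange
    ``h_c*(Tg - Ta)/(eps_g*sigma)``.  Solved by damped successive
    substitution on Tg (Kelvin) until successive iterates agree within
    ``params.tolerance`` (default 0.02 degC); falls back to bracketed root
    finding on [Ta - 5, Ta + 80] degC if the iteration does not converge.
    """
    load = _radiative_load(met, params)
    tg_c = met.Ta  # start at air temperature
    for iteration in range(1, params.max_iterations + 1):
        tg_k = tg_c + _KELVIN
        ta_k = met.Ta + _KELVIN
        t_film = 0.5 * (tg_k + ta_k)
        hc = convective_coefficient(met.u, t_film, params)
        radicand = load - hc * (tg_c - met.Ta) / (params.epsilon_g * params.sigma)
        if radicand <= 0.0:
            break  # nonphysical intermediate; hand over to bisection
        tg_new = radicand**0.25 - _KELVIN
        step = tg_new - tg_c
        tg_c = tg_c + (1.0 - params.damping) * step
        if abs(step) < params.tolerance:
            return tg_c, iteration
    # bisection fallback on the residual
    lo, hi = met.Ta - 5.0, met.Ta + 80.0
    f_lo = _globe_residual(lo, met, params, load)
    f_hi = _globe_residual(hi, met, params, load)
    if f_lo * f_hi > 0:
        raise ArithmeticError(
            "globe temperature bisection failed: residual does not change sign "
            f"on [{lo:.2f}, {hi:.2f}] degC (f_lo={f_lo:.3g}, f_hi={f_hi:.3g}; "
            f"Ta={met.Ta}, u={met.u}, Kdown={met.Kdown})"
        )
    tg_c = brentq(_globe_residual, lo, hi, args=(met, params, load), xtol=1e-6)
    return float(tg_c), params.max_iterations


# ---------------------------------------------------------------------------
# WBGT branches
# ---------------------------------------------------------------------------

#: Lower wind clamp before log10 in the calm no-sun form (m/s).
WIND_CLAMP = 0.13

NO_SUN_WIND_THRESHOLD = 3.0  # m/s


def wbgt_no_sun(Tw: float, Ta: float, u: float, wind_clamp: float = WIND_CLAMP) -> tuple[float, str]:
    """WBGT for hours with no sunlight (shade or night).

    Windy (u > 3 m/s): ``0.7*Tw + 0.3*Ta``.  Calm (u <= 3 m/s):
    ``0.67*Tw + 0.33*Ta - 0.048*log10(u)*(Ta - Tw)``; u is clamped below at
    ``wind_clamp`` because the calm form diverges as u -> 0.
    """
    u_eff = max(u, wind_clamp)
    if u_eff > NO_SUN_WIND_THRESHOLD:
        return 0.7 * Tw + 0.3 * Ta, "no_sun_windy"
    wbgt = 0.67 * Tw + 0.33 * Ta - 0.048 * math.log10(u_eff) * (Ta - Tw)
    return wbgt, "no_sun_calm"


def wbgt_sun(Tw: float, Tg: float, Ta: float) -> float:
    """Sun-exposed WBGT: ``0.7*Tw + 0.2*Tg + 0.1*Ta``."""
    for name, value in (("Tw", Tw), ("Tg", Tg), ("Ta", Ta)):
        if not math.isfinite(value):
            raise ValueError(f"{name} must be finite, got {value}")
    return 0.7 * Tw + 0.2 * Tg + 0.1 * Ta


# ---------------------------------------------------------------------------
# series driver
# ---------------------------------------------------------------------------


def compute_wbgt_record(
    met: MetSample,
    params: GlobeParams = GlobeParams(),
    sun_rule: SunRule = SunRule(),
    wind_clamp: float = WIND_CLAMP,
) -> WBGTRecord:
    """WBGT for a single hourly sample, choosing the sun / no-sun branch."""
    tw = wet_bulb_stull(met.Ta, met.RH)
    if sun_rule.is_sun(met.Kdown, met.Z):
        tg, iters = globe_temperature(met, params)
        wbgt = wbgt_sun(tw, tg, met.Ta)
        return WBGTRecord(
            Tw=tw, Tg=tg, WBGT=wbgt, branch="sun", iterations_used=iters,
            timestamp_local=met.timestamp_local, location_id=met.location_id,
            scenario=met.scenario,
        )
    wbgt, branch = wbgt_no_sun(tw, met.Ta, met.u, wind_clamp=wind_clamp)
    return WBGTRecord(
        Tw=tw, Tg=None, WBGT=wbgt, branch=branch, iterations_used=0,
        timestamp_local=met.timestamp_local, location_id=met.location_id,
        scenario=met.scenario,
    )


def compute_wbgt_series(
    met: pd.DataFrame,
    params: GlobeParams = GlobeParams(),
    sun_rule: SunRule = SunRule(),
    wind_clamp: float = WIND_CLAMP,
) -> pd.DataFrame:
    """Per-hour WBGT for an hourly met table (schema of ``MET_CSV_COLUMNS``).

    Returns one row per input row, order preserved, with columns
    ``WBGT_CSV_COLUMNS``.  Per-hour solver failures are recorded as NaN rows
    and counted in the returned frame's ``attrs['n_failures']`` rather than
    aborting the run.
    """
    missing = [c for c in MET_CSV_COLUMNS if c not in met.columns]
    if missing:
        raise ValueError(f"met table missing columns: {missing}")
    records = []
    n_failures = 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        for row in met.itertuples(index=False):
            sample = MetSample(
                Ta=row.Ta_C, RH=row.RH_pct, u=row.u_ms,
                Kdown=row.Kdown_Wm2, Kup=row.Kup_Wm2,
                Ldown=row.Ldown_Wm2, Lup=row.Lup_Wm2,
                F=row.F_frac, Z=row.zenith_deg,
                timestamp_local=row.timestamp_local,
                location_id=row.location_id, scenario=row.scenario,
            )
            try:
                rec = compute_wbgt_record(sample, params, sun_rule, wind_clamp)
            except ArithmeticError:
                n_failures += 1
                rec = WBGTRecord(
                    Tw=math.nan, Tg=None, WBGT=math.nan, branch="failed",
                    timestamp_local=sample.timestamp_local,
                    location_id=sample.location_id, scenario=sample.scenario,
                )
            records.append(rec)
    out = pd.DataFrame(
        {
            "location_id": [r.location_id for r in records],
            "timestamp_local": [r.timestamp_local for r in records],
            "scenario": [r.scenario for r in records],
            "Tw_C": [r.Tw for r in records],
            "Tg_C": [r.Tg if r.Tg is not None else np.nan for r in records],
            "WBGT_C": [r.WBGT for r in records],
            "branch": [r.branch for r in records],
            "iterations": [r.iterations_used for r in records],
        }
    )
    out.attrs["n_failures"] = n_failures
    return out


# ---------------------------------------------------------------------------
# CSV interfaces (schemas shared across the pipeline)
# ---------------------------------------------------------------------------


def read_met_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, parse_dates=["timestamp_local"])
    missing = [c for c in MET_CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"met CSV {path} missing columns: {missing}")
    return df


def write_wbgt_csv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, columns=WBGT_CSV_COLUMNS, float_format="%.6f")


def read_wbgt_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, parse_dates=["timestamp_local"])
    missing = [c for c in ("location_id", "timestamp_local", "scenario", "WBGT_C")]
    missing = [c for c in missing if c not in df.columns]
    if missing:
        raise ValueError(f"WBGT CSV {path} missing columns: {missing}")
    return df
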