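"""Shared fixtures and independent oracles for the test suite.

Oracles here deliberately avoid the package's own code paths: high-precision
closed-form evaluation goes through sympy at 50 digits, solar position
through a second published algorithm (Michalsky 1988), and the globe
temperature through direct bracketing bisection on the energy balance.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest
import sympy as sp

import heatshift as hs


# ---------------------------------------------------------------------------
# high-precision closed-form oracles (sympy, 50 digits)
# ---------------------------------------------------------------------------


def stull_oracle(ta: float, rh: float) -> float:
    """Stull wet-bulb arctangent fit evaluated at 50 decimal digits."""
    Ta, RH = sp.Float(ta, 50), sp.Float(rh, 50)
    tw = (
        Ta * sp.atan(sp.Float("0.151977", 50) * sp.sqrt(RH + sp.Float("8.313659", 50)))
        + sp.atan(Ta + RH)
        - sp.atan(RH - sp.Float("1.676331", 50))
        + sp.Float("0.00391838", 50) * RH ** sp.Rational(3, 2) * sp.atan(sp.Float("0.023101", 50) * RH)
        - sp.Float("4.686035", 50)
    )
    return float(tw.evalf(50))


def work_loss_oracle(wbgt: float) -> float:
    """Logistic work-loss curve evaluated at 50 decimal digits."""
    w = sp.Float(wbgt, 50)
    expr = 60 - (1 / (1 + (sp.Float("33.63", 50) / w) ** sp.Float("-6.33", 50))) * 60
    return float(expr.evalf(50))


# ---------------------------------------------------------------------------
# independent solar-position oracle (Michalsky 1988, Astronomical Almanac)
# ---------------------------------------------------------------------------


def michalsky_zenith(lat_deg: float, lon_deg: float, when_utc) -> float:
    """Solar zenith angle via Michalsky's Astronomical Almanac algorithm.

    East longitude positive; stated accuracy 0.01 deg through 2050 —
    independent of the NOAA/Meeus formulation used by the package.
    """
    ts = pd.Timestamp(when_utc)
    if ts.tzinfo is not None:
        ts = ts.tz_convert("UTC").tz_localize(None)
    hour_ut = ts.hour + ts.minute / 60.0 + ts.second / 3600.0
    # days from J2000.0
    delta = (ts.normalize() - pd.Timestamp("2000-01-01 12:00")) / pd.Timedelta(days=1)
    n = delta + hour_ut / 24.0
    mnlong = (280.460 + 0.9856474 * n) % 360.0
    mnanom = math.radians((357.528 + 0.9856003 * n) % 360.0)
    eclong = math.radians(
        (mnlong + 1.915 * math.sin(mnanom) + 0.020 * math.sin(2 * mnanom)) % 360.0
    )
    oblqec = math.radians(23.439 - 0.0000004 * n)
    dec = math.asin(math.sin(oblqec) * math.sin(eclong))
    ra = math.atan2(math.cos(oblqec) * math.sin(eclong), math.cos(eclong))
    if ra < 0:
        ra += 2 * math.pi
    gmst = (6.697375 + 0.0657098242 * n + hour_ut) % 24.0
    lmst = (gmst + lon_deg / 15.0) % 24.0
    ha = math.radians(lmst * 15.0) - ra
    while ha < -math.pi:
        ha += 2 * math.pi
    while ha > math.pi:
        ha -= 2 * math.pi
    lat = math.radians(lat_deg)
    el = math.asin(
        math.sin(dec) * math.sin(lat) + math.cos(dec) * math.cos(lat) * math.cos(ha)
    )
    return 90.0 - math.degrees(el)


# ---------------------------------------------------------------------------
# randomized-but-physical met samples for the globe solver
# ---------------------------------------------------------------------------


def random_met_sample(rng: np.random.Generator) -> hs.MetSample:
    """A random daytime sample inside the physically valid envelope."""
    ta = rng.uniform(5.0, 40.0)
    zen = rng.uniform(10.0, 80.0)
    cosz = math.cos(math.radians(zen))
    kdown = rng.uniform(0.05, 1.0) * 1100.0 * cosz
    sigma = hs.GlobeParams().sigma
    ta_k4 = (ta + 273.15) ** 4
    return hs.MetSample(
        Ta=ta,
        RH=rng.uniform(20.0, 95.0),
        u=float(3.5 * np.exp(rng.normal(0.0, 0.45))),
        Kdown=kdown,
        Kup=rng.uniform(0.05, 0.4) * kdown,
        Ldown=rng.uniform(0.6, 1.0) * sigma * ta_k4,
        Lup=rng.uniform(0.9, 1.15) * sigma * ta_k4,
        F=rng.uniform(0.0, 0.85),
        Z=zen,
    )


def bisect_globe_oracle(met: hs.MetSample, params: hs.GlobeParams, tol: float = 1e-4) -> float:
    """Plain interval-halving bisection on the globe energy-balance residual."""
    sigma, eps, a_g = params.sigma, params.epsilon_g, params.alpha_g
    cosz = max(math.cos(math.radians(met.Z)), params.cos_zenith_floor)
    load = (
        (met.Ldown + met.Lup) / (2 * sigma)
        + met.Kdown * (1 - a_g) / (2 * eps * sigma) * (1 - met.F + met.F / (2 * cosz))
        + (1 - a_g) / (2 * eps * sigma) * met.Kup
    )

    def residual(tg_c: float) -> float:
        t_film = 0.5 * (tg_c + met.Ta) + 273.15
        hc = hs.wbgt_core.convective_coefficient(met.u, t_film, params)
        return (tg_c + 273.15) ** 4 - (load - hc * (tg_c - met.Ta) / (eps * sigma))

    lo, hi = met.Ta - 5.0, met.Ta + 80.0
    f_lo = residual(lo)
    assert f_lo * residual(hi) < 0, "oracle bracket does not straddle the root"
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if f_lo * residual(mid) <= 0:
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------


@pytest.fixture(scope="session")
def small_campaign() -> pd.DataFrame:
    """A 2-location, 4-scenario synthetic August used across tests."""
    return hs.generate_campaign(hs.CampaignConfig(n_locations=2, seed=11))


@pytest.fixture(scope="session")
def small_wbgt(small_campaign) -> pd.DataFrame:
    return hs.compute_wbgt_series(small_campaign)


def make_wbgt_frame(wbgt_by_location: dict[str, np.ndarray], scenario: str = "baseline") -> pd.DataFrame:
    """Assemble a full-month WBGT table from per-location hourly arrays."""
    hours = pd.date_range("2020-08-01", "2020-09-01", freq="h", inclusive="left")
    frames = []
    for loc, values in wbgt_by_location.items():
        assert len(values) == len(hours)
        frames.append(
            pd.DataFrame(
                {
                    "location_id": loc,
                    "timestamp_local": hours,
                    "scenario": scenario,
                    "WBGT_C": values,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)
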