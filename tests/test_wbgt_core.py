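"""Unit tests for the WBGT core: wet bulb, globe temperature, branching."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import heatshift as hs
from heatshift.wbgt_core import (
    MET_CSV_COLUMNS,
    NO_SUN_WIND_THRESHOLD,
    WIND_CLAMP,
    compute_wbgt_record,
)

from conftest import bisect_globe_oracle, random_met_sample, stull_oracle

SIGMA = hs.GlobeParams().sigma


def night_sample(ta: float, rh: float = 60.0, u: float = 2.0, lw_scale: float = 1.0) -> hs.MetSample:
    lw = lw_scale * SIGMA * (ta + 273.15) ** 4
    return hs.MetSample(Ta=ta, RH=rh, u=u, Kdown=0, Kup=0, Ldown=lw, Lup=lw, F=0, Z=120.0)


# ---------------------------------------------------------------------------
# wet bulb (Stull)
# ---------------------------------------------------------------------------


class TestWetBulbStull:
    @pytest.mark.parametrize(
        "ta, rh, expected, tol",
        [
            (20.0, 50.0, 13.7, 0.05),  # canonical check value of the fit
            (30.0, 60.0, stull_oracle(30.0, 60.0), 1e-9),
            (10.0, 80.0, stull_oracle(10.0, 80.0), 1e-9),
        ],
    )
    def test_known_values(self, ta, rh, expected, tol):
        assert hs.wet_bulb_stull(ta, rh) == pytest.approx(expected, abs=tol)

    def test_saturation_limit(self):
        # near saturation the wet bulb approaches the dry bulb
        assert hs.wet_bulb_stull(30.0, 99.0) == pytest.approx(30.0, abs=1.0)

    def test_wet_bulb_depression_positive(self):
        ta = np.linspace(0, 45, 20)
        rh = np.linspace(10, 95, 20)
        tw = hs.wet_bulb_stull(ta, rh)
        assert np.all(tw <= ta + 0.5)

    def test_vectorized_matches_scalar(self):
        ta = np.array([15.0, 25.0, 35.0])
        rh = np.array([40.0, 60.0, 80.0])
        vec = hs.wet_bulb_stull(ta, rh)
        assert vec == pytest.approx([hs.wet_bulb_stull(t, r) for t, r in zip(ta, rh)])

    def test_nan_raises(self):
        with pytest.raises(ValueError):
            hs.wet_bulb_stull(float("nan"), 50.0)

    def test_outside_validity_warns_but_evaluates(self):
        with pytest.warns(RuntimeWarning):
            tw = hs.wet_bulb_stull(25.0, 2.0)
        assert math.isfinite(tw)


# ---------------------------------------------------------------------------
# globe temperature
# ---------------------------------------------------------------------------


class TestGlobeTemperature:
    def test_radiative_equilibrium_fixed_point(self):
        # with no shortwave and L-down = L-up = sigma*Ta_K^4 the balance is
        # satisfied exactly at Tg = Ta (convective term vanishes)
        for ta in (0.0, 15.0, 30.0):
            tg, iters = hs.globe_temperature(night_sample(ta))
            assert tg == pytest.approx(ta, abs=1e-9)
            assert iters == 1

    def test_monotone_in_shortwave(self):
        base = random_met_sample(np.random.default_rng(5))
        doubled = hs.MetSample(
            Ta=base.Ta, RH=base.RH, u=base.u, Kdown=2 * base.Kdown, Kup=base.Kup,
            Ldown=base.Ldown, Lup=base.Lup, F=base.F, Z=base.Z,
        )
        tg_base, _ = hs.globe_temperature(base)
        tg_doubled, _ = hs.globe_temperature(doubled)
        assert tg_doubled > tg_base

    def test_strong_sun_globe_exceeds_air(self):
        # under strong shortwave and near-blackbody longwave the solar load
        # dominates the sky deficit, so the globe runs hotter than the air
        # (with a cold clear sky and weak sun it can legitimately run cooler)
        rng = np.random.default_rng(17)
        checked = 0
        while checked < 20:
            met = random_met_sample(rng)
            ta_k4 = SIGMA * (met.Ta + 273.15) ** 4
            if met.Kdown < 400.0 or met.Ldown < 0.85 * ta_k4 or met.Lup < ta_k4:
                continue
            tg, _ = hs.globe_temperature(met)
            assert tg > met.Ta
            checked += 1

    def test_agrees_with_bisection_oracle(self):
        params = hs.GlobeParams()
        rng = np.random.default_rng(23)
        for _ in range(100):
            met = random_met_sample(rng)
            tg, _ = hs.globe_temperature(met, params)
            assert tg == pytest.approx(bisect_globe_oracle(met, params), abs=2 * params.tolerance)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            hs.GlobeParams(epsilon_g=0.0)
        with pytest.raises(ValueError):
            hs.GlobeParams(tolerance=-1.0)


# ---------------------------------------------------------------------------
# WBGT branches
# ---------------------------------------------------------------------------


class TestBranches:
    @pytest.mark.parametrize(
        "tw, ta, u, expected, branch",
        [
            (20.0, 30.0, 5.0, 23.0, "no_sun_windy"),
            (20.0, 30.0, 1.0, 23.3, "no_sun_calm"),  # log10(1) = 0
            (20.0, 30.0, 0.1, 23.78, "no_sun_calm"),  # log10(0.1) adds +0.48
        ],
    )
    def test_no_sun_values(self, tw, ta, u, expected, branch):
        wbgt, got_branch = hs.wbgt_no_sun(tw, ta, u, wind_clamp=0.05)
        assert wbgt == pytest.approx(expected, abs=1e-9)
        assert got_branch == branch

    def test_wind_clamp_no_exception(self):
        wbgt, branch = hs.wbgt_no_sun(20.0, 30.0, 0.0)
        assert branch == "no_sun_calm"
        ref, _ = hs.wbgt_no_sun(20.0, 30.0, WIND_CLAMP)
        assert wbgt == ref

    @pytest.mark.parametrize(
        "tw, tg, ta, expected",
        [
            (25.0, 25.0, 25.0, 25.0),  # weights sum to 1
            (20.0, 40.0, 30.0, 25.0),
            (18.5, 45.0, 28.0, 24.75),
        ],
    )
    def test_sun_weighted_sum(self, tw, tg, ta, expected):
        assert hs.wbgt_sun(tw, tg, ta) == pytest.approx(expected, abs=1e-12)

    def test_sun_rejects_nonfinite(self):
        with pytest.raises(ValueError):
            hs.wbgt_sun(20.0, float("inf"), 25.0)

    def test_branch_discontinuity_bounded_at_threshold(self):
        # the two no-sun forms disagree at u = 3 m/s; the gap is small and
        # bounded by the documented envelope, not patched over
        for tw, ta in [(15.0, 25.0), (20.0, 22.0), (10.0, 30.0)]:
            windy = 0.7 * tw + 0.3 * ta
            calm, _ = hs.wbgt_no_sun(tw, ta, NO_SUN_WIND_THRESHOLD)
            bound = 0.048 * math.log10(3.0) * (ta - tw) + 0.03 * abs(ta - tw) + 0.03 * abs(tw)
            assert abs(windy - calm) <= bound

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(
        tw=st.floats(5.0, 30.0),
        ta_excess=st.floats(0.0, 15.0),
        delta=st.floats(0.1, 5.0),
        u=st.floats(0.2, 10.0),
    )
    def test_monotone_in_components(self, tw, ta_excess, delta, u):
        """WBGT is non-decreasing in Tw and Ta (Ta >= Tw, the physical regime)."""
        ta = tw + ta_excess
        lo, _ = hs.wbgt_no_sun(tw, ta, u)
        hi_tw, _ = hs.wbgt_no_sun(tw + delta, ta + delta, u)  # raise both
        assert hi_tw >= lo
        assert hs.wbgt_sun(tw + delta, 40.0, ta) >= hs.wbgt_sun(tw, 40.0, ta)
        assert hs.wbgt_sun(tw, 40.0 + delta, ta) >= hs.wbgt_sun(tw, 40.0, ta)
        assert hs.wbgt_sun(tw, 40.0, ta + delta) >= hs.wbgt_sun(tw, 40.0, ta)


# ---------------------------------------------------------------------------
# series driver
# ---------------------------------------------------------------------------


def _met_frame(samples: list[hs.MetSample]) -> pd.DataFrame:
    hours = pd.date_range("2020-08-01", periods=len(samples), freq="h")
    return pd.DataFrame(
        {
            "location_id": "L01",
            "timestamp_local": hours,
            "Ta_C": [m.Ta for m in samples],
            "RH_pct": [m.RH for m in samples],
            "u_ms": [m.u for m in samples],
            "Kdown_Wm2": [m.Kdown for m in samples],
            "Kup_Wm2": [m.Kup for m in samples],
            "Ldown_Wm2": [m.Ldown for m in samples],
            "Lup_Wm2": [m.Lup for m in samples],
            "F_frac": [m.F for m in samples],
            "zenith_deg": [m.Z for m in samples],
            "scenario": "baseline",
        }
    )[MET_CSV_COLUMNS]


class TestSeries:
    def test_all_night_series_uses_no_sun_branches(self):
        df = _met_frame([night_sample(15.0 + i, u=1.0 + i) for i in range(6)])
        out = hs.compute_wbgt_series(df)
        assert set(out["branch"]) <= {"no_sun_windy", "no_sun_calm"}
        assert out["Tg_C"].isna().all()

    def test_windy_night_is_fixed_weighted_sum(self):
        df = _met_frame([night_sample(10.0 + i, rh=70.0, u=5.0) for i in range(8)])
        out = hs.compute_wbgt_series(df)
        tw = hs.wet_bulb_stull(df["Ta_C"].to_numpy(), df["RH_pct"].to_numpy())
        assert out["WBGT_C"].to_numpy() == pytest.approx(0.7 * tw + 0.3 * df["Ta_C"].to_numpy())
        assert (out["branch"] == "no_sun_windy").all()

    def test_mixed_series_matches_composed_operations(self):
        rng = np.random.default_rng(31)
        samples = []
        for i in range(24):
            if 8 <= i <= 18:
                samples.append(random_met_sample(rng))
            else:
                samples.append(night_sample(12.0 + rng.uniform(0, 8), u=rng.uniform(0.5, 6)))
        df = _met_frame(samples)
        out = hs.compute_wbgt_series(df)
        for sample, row in zip(samples, out.itertuples(index=False)):
            rec = compute_wbgt_record(sample)
            assert row.WBGT_C == rec.WBGT
            assert row.branch == rec.branch

    def test_missing_column_rejected(self):
        df = _met_frame([night_sample(15.0)]).drop(columns=["u_ms"])
        with pytest.raises(ValueError, match="u_ms"):
            hs.compute_wbgt_series(df)

    def test_csv_round_trip(self, tmp_path, small_wbgt):
        path = tmp_path / "wbgt.csv"
        hs.wbgt_core.write_wbgt_csv(small_wbgt, path)
        back = hs.wbgt_core.read_wbgt_csv(path)
        assert len(back) == len(small_wbgt)
        assert back["WBGT_C"].to_numpy() == pytest.approx(
            small_wbgt["WBGT_C"].to_numpy(), abs=1e-5
        )


class TestMetSampleValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"RH": 120.0},
            {"u": -1.0},
            {"Kdown": -5.0},
            {"F": 1.5},
        ],
    )
    def test_invalid_fields_rejected(self, kwargs):
        base = dict(Ta=20.0, RH=50.0, u=1.0, Kdown=0, Kup=0, Ldown=300, Lup=300, F=0, Z=100)
        base.update(kwargs)
        with pytest.raises(ValueError):
            hs.MetSample(**base)
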