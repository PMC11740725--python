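"""Physical-work-capacity loss and shift-level productivity reports.

Hourly WBGT is converted to minutes of work lost per hour with the Foster
et al. (2021) logistic exposure-response for unacclimatized workers doing
moderate-to-heavy labor:

    work_loss(WBGT) = 60 * r**6.33 / (1 + r**6.33),   r = WBGT / 33.63

i.e. physical work capacity PWC = 1 / (1 + (WBGT/33.63)**6.33), with the
half-capacity point at 33.63 degC.  The loss is applied to each hourly,
per-location WBGT *before* any averaging (the curve is nonlinear, so
aggregating means first would understate losses), then summed over the
hours of each 8-hour shift across the month and averaged (unweighted)
across locations.  "Hours gained" for a scenario is the baseline's lost
hours minus the scenario's, per shift.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PWC_HALF_POINT_C",
    "PWC_EXPONENT",
    "Shift",
    "ShiftSchedule",
    "work_loss",
    "pwc_percent",
    "attach_work_loss",
    "shift_aggregate",
    "hours_gained",
    "productivity_auc",
    "diurnal_mean_wbgt",
]

#: WBGT at which physical work capacity is 50 % (degC).
PWC_HALF_POINT_C = 33.63
#: Logistic steepness exponent.
PWC_EXPONENT = 6.33


# ---------------------------------------------------------------------------
# shift schedule
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Shift:
    name: str
    start_hour: int  # inclusive, local hour
    end_hour: int  # exclusive; may be < start_hour for shifts crossing midnight

    def hours(self) -> list[int]:
        if self.start_hour < self.end_hour:
            return list(range(self.start_hour, self.end_hour))
        return list(range(self.start_hour, 24)) + list(range(0, self.end_hour))

    def contains_hour(self, hour: int) -> bool:
        return hour in self.hours()


def _default_shifts() -> tuple[Shift, ...]:
    return (
        Shift("first", 7, 15),
        Shift("second", 15, 23),
        Shift("third", 23, 7),  # crosses midnight
    )


@dataclass(frozen=True)
class ShiftSchedule:
    """Named 8-hour shifts partitioning the 24-hour day.

    Default: first 07-15, second 15-23, third 23-07 local time; the third
    shift is assembled across the midnight boundary by hour-of-day
    membership (23:00 of day d together with 00:00-06:00 of day d+1).
    """

    shifts: tuple[Shift, ...] = field(default_factory=_default_shifts)

    def __post_init__(self) -> None:
        covered: list[int] = []
        for shift in self.shifts:
            hrs = shift.hours()
            if len(hrs) != 8:
                raise ValueError(f"shift {shift.name!r} covers {len(hrs)} hours, expected 8")
            covered.extend(hrs)
        if sorted(covered) != list(range(24)):
            raise ValueError("shifts must partition the 24-hour day")

    @property
    def names(self) -> list[str]:
        return [s.name for s in self.shifts]

    def shift_of_hour(self, hour: int) -> str:
        for shift in self.shifts:
            if shift.contains_hour(hour):
                return shift.name
        raise ValueError(f"hour {hour} not covered")  # pragma: no cover

    def hour_map(self) -> dict[int, str]:
        return {h: s.name for s in self.shifts for h in s.hours()}


# ---------------------------------------------------------------------------
# exposure-response
# ---------------------------------------------------------------------------


def work_loss(wbgt):
    """Minutes of work lost per hour at a given WBGT (degC).

    Vectorized; clamped to [0, 60] and strictly increasing in WBGT.
    Non-positive WBGT (where the power law is undefined) returns 0: there is
    no heat-attributable loss in freezing conditions under this model.
    """
    w = np.asarray(wbgt, dtype=float)
    positive = w > 0.0
    r = np.where(positive, w / PWC_HALF_POINT_C, 1.0)
    rp = r**PWC_EXPONENT
    loss = np.where(positive, 60.0 * rp / (1.0 + rp), 0.0)
    loss = np.clip(loss, 0.0, 60.0)
    if np.isscalar(wbgt):
        return float(loss)
    return loss


def pwc_percent(wbgt):
    """Physical work capacity in percent, 100 * (1 - work_loss/60)."""
    loss = work_loss(wbgt)
    return 100.0 * (1.0 - loss / 60.0)


def attach_work_loss(wbgt_df: pd.DataFrame) -> pd.DataFrame:
    """Add ``work_loss_min`` and ``pwc_pct`` columns to a WBGT table."""
    out = wbgt_df.copy()
    out["work_loss_min"] = work_loss(out["WBGT_C"].to_numpy())
    out["pwc_pct"] = 100.0 * (1.0 - out["work_loss_min"] / 60.0)
    return out


# ---------------------------------------------------------------------------
# aggregation
# ---------------------------------------------------------------------------


def _check_complete_coverage(df: pd.DataFrame) -> None:
    """Every (location, scenario) must cover the same complete hourly grid."""
    gaps = []
    for (loc, scn), group in df.groupby(["location_id", "scenario"], sort=False):
        ts = pd.DatetimeIndex(group["timestamp_local"]).sort_values()
        if ts.has_duplicates:
            gaps.append(f"{loc}/{scn}: duplicate timestamps")
            continue
        expected = pd.date_range(ts[0], ts[-1], freq="h")
        missing = expected.difference(ts)
        if len(missing) > 0:
            preview = ", ".join(str(t) for t in missing[:5])
            gaps.append(f"{loc}/{scn}: {len(missing)} missing hours (first: {preview})")
    if gaps:
        raise ValueError("incomplete hourly coverage; no imputation performed:\n" + "\n".join(gaps))


def shift_aggregate(
    wbgt_df: pd.DataFrame,
    schedule: ShiftSchedule = ShiftSchedule(),
) -> pd.DataFrame:
    """Per-(shift, scenario) lost hours per worker per month and mean WBGT.

    ``lost_hours`` sums, over every hour-cell of the month belonging to the
    shift, the across-location mean of the hourly work loss, divided by 60.
    ``mean_WBGT_C`` is the unweighted mean WBGT over the same cells.
    Missing hours raise (no silent imputation).
    """
    required = {"location_id", "timestamp_local", "scenario", "WBGT_C"}
    missing = required - set(wbgt_df.columns)
    if missing:
        raise ValueError(f"WBGT table missing columns: {sorted(missing)}")
    _check_complete_coverage(wbgt_df)

    df = attach_work_loss(wbgt_df)
    hours = pd.DatetimeIndex(df["timestamp_local"]).hour
    df = df.assign(shift=hours.map(schedule.hour_map()))

    rows = []
    for scenario, scn_df in df.groupby("scenario", sort=False):
        for shift_name in schedule.names:
            cells = scn_df[scn_df["shift"] == shift_name]
            # mean over locations within each hour, then sum over hours
            per_hour = cells.groupby("timestamp_local")["work_loss_min"].mean()
            lost_hours = float(per_hour.sum()) / 60.0
            rows.append(
                {
                    "scenario": scenario,
                    "shift": shift_name,
                    "mean_WBGT_C": float(cells["WBGT_C"].mean()),
                    "lost_hours": lost_hours,
                    "n_hour_cells": int(per_hour.size),
                }
            )
    return pd.DataFrame(rows)


def hours_gained(baseline_report: pd.DataFrame, scenario_report: pd.DataFrame) -> pd.DataFrame:
    """Per-shift and total hours gained of a scenario versus baseline.

    ``gained = lost_hours_baseline - lost_hours_scenario``; negative if the
    scenario is hotter.  Both reports must cover the same shifts with the
    same hour-cell counts.
    """
    base = baseline_report.set_index("shift")
    scn = scenario_report.set_index("shift")
    if sorted(base.index) != sorted(scn.index):
        raise ValueError("reports cover different shifts")
    scn = scn.reindex(base.index)
    if not (base["n_hour_cells"] == scn["n_hour_cells"]).all():
        raise ValueError("reports cover different numbers of hour cells per shift")
    gained = base["lost_hours"] - scn["lost_hours"]
    out = pd.DataFrame(
        {
            "shift": base.index,
            "scenario": scn["scenario"].to_numpy(),
            "hours_gained": gained.to_numpy(),
        }
    )
    total = pd.DataFrame(
        {
            "shift": ["total"],
            "scenario": [scn["scenario"].iloc[0]],
            "hours_gained": [float(gained.sum())],
        }
    )
    return pd.concat([out, total], ignore_index=True)


def productivity_auc(pwc_pct: Sequence[float], dt_hours: float = 1.0) -> float:
    """Area under the productivity curve, in percent-hours.

    Trapezoidal rule over chronological hourly productivity percentages:
    sum over consecutive pairs of (pwc_i + pwc_{i+1})/2 * dt.
    """
    values = np.asarray(pwc_pct, dtype=float)
    if values.ndim != 1 or values.size < 2:
        raise ValueError("productivity AUC needs at least two chronological points")
    if dt_hours <= 0:
        raise ValueError("dt_hours must be > 0")
    return float(np.trapezoid(values, dx=dt_hours))


def diurnal_mean_wbgt(wbgt_df: pd.DataFrame) -> pd.DataFrame:
    """Mean WBGT by (scenario, hour of day), averaged over days and locations.

    The monthly average daily WBGT curve per scenario — one row per
    (scenario, hour 0-23).
    """
    hours = pd.DatetimeIndex(wbgt_df["timestamp_local"]).hour
    out = (
        wbgt_df.assign(hour=hours)
        .groupby(["scenario", "hour"], sort=True)["WBGT_C"]
        .mean()
        .reset_index()
        .rename(columns={"WBGT_C": "mean_WBGT_C"})
    )
    return out
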