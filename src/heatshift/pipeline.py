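"""End-to-end orchestration: met -> WBGT -> productivity -> reports.

A run is described by a :class:`RunConfig` (usually loaded from YAML):
where the hourly meteorology comes from (the synthetic generator or a CSV),
the globe-solver settings, the shift schedule, which scenarios to compare,
and an output directory.  ``run_pipeline`` executes the stages in order and
writes:

* ``met.csv`` — the hourly meteorology (only when simulated);
* ``wbgt.csv`` — per-hour wet-bulb, globe and WBGT temperatures;
* ``shift_report.csv`` — per (scenario, shift) mean WBGT and lost hours,
  plus a 24-h total row per scenario;
* ``hours_gained.csv`` — per-shift and total hours gained versus baseline;
* ``diurnal_wbgt.csv`` — monthly-mean WBGT by hour of day per scenario;
* ``manifest.json`` — config hash, seed, package version, stage counts.

Runs are deterministic given (config, seed): rerunning writes byte-identical
artifacts.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from . import __version__
from .productivity import (
    Shift,
    ShiftSchedule,
    diurnal_mean_wbgt,
    hours_gained,
    shift_aggregate,
)
from .synthetic_met import CampaignConfig, generate_campaign, write_met_csv
from .wbgt_core import GlobeParams, SunRule, compute_wbgt_series, read_met_csv, write_wbgt_csv

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]

logger = logging.getLogger("heatshift")


class PipelineError(RuntimeError):
    """A stage failed; carries the failing stage's name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Configuration of one end-to-end run."""

    out_dir: Path = Path("heatshift_run")
    seed: int = 0
    met_csv: Optional[Path] = None  # ingest this CSV instead of simulating
    campaign: CampaignConfig = field(default_factory=CampaignConfig)
    globe: GlobeParams = field(default_factory=GlobeParams)
    sun_rule: SunRule = field(default_factory=SunRule)
    schedule: ShiftSchedule = field(default_factory=ShiftSchedule)
    scenarios: Optional[list[str]] = None  # None -> all scenarios present
    baseline_name: str = "baseline"
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs: dict = {}
        for key in ("out_dir", "seed", "met_csv", "scenarios", "baseline_name", "log_level"):
            if key in raw:
                kwargs[key] = raw[key]
        if "campaign" in raw:
            kwargs["campaign"] = CampaignConfig(**raw["campaign"])
        if "globe" in raw:
            kwargs["globe"] = GlobeParams(**raw["globe"])
        if "sun_rule" in raw:
            kwargs["sun_rule"] = SunRule(**raw["sun_rule"])
        if "shifts" in raw:
            kwargs["schedule"] = ShiftSchedule(
                shifts=tuple(Shift(s["name"], s["start_hour"], s["end_hour"]) for s in raw["shifts"])
            )
        cfg = cls(**kwargs)
        cfg.out_dir = Path(cfg.out_dir)
        if cfg.met_csv is not None:
            cfg.met_csv = Path(cfg.met_csv)
        return cfg

    def config_hash(self) -> str:
        def encode(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {f.name: encode(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
            if isinstance(obj, (Path,)):
                return str(obj)
            if isinstance(obj, dict):
                return {k: encode(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [encode(v) for v in obj]
            return obj

        payload = json.dumps(encode(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _shift_report_with_total(wbgt_df: pd.DataFrame, schedule: ShiftSchedule) -> pd.DataFrame:
    """Per-shift report plus a 24-h 'total' row per scenario."""
    report = shift_aggregate(wbgt_df, schedule)
    totals = []
    for scenario, grp in report.groupby("scenario", sort=False):
        scn_rows = wbgt_df[wbgt_df["scenario"] == scenario]
        totals.append(
            {
                "scenario": scenario,
                "shift": "total",
                "mean_WBGT_C": float(scn_rows["WBGT_C"].mean()),
                "lost_hours": float(grp["lost_hours"].sum()),
                "n_hour_cells": int(grp["n_hour_cells"].sum()),
            }
        )
    return pd.concat([report, pd.DataFrame(totals)], ignore_index=True)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis; returns the in-memory tables and paths.

    Returns a dict with keys ``met``, ``wbgt``, ``shift_report``,
    ``hours_gained``, ``diurnal``, ``manifest`` and ``out_dir``.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package_version": __version__,
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stages": {},
        "artifacts": [],
    }

    def finish_stage(name: str, **counts) -> None:
        manifest["stages"][name] = counts
        logger.info("stage %s: %s", name, counts)

    def write_manifest() -> None:
        with open(out_dir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)

    # --- stage 1: meteorology ------------------------------------------------
    try:
        if config.met_csv is not None:
            met = read_met_csv(config.met_csv)
            simulated = False
        else:
            campaign = dataclasses.replace(config.campaign, seed=config.seed)
            met = generate_campaign(campaign)
            simulated = True
        if config.scenarios is not None:
            present = set(met["scenario"].unique())
            missing = [s for s in config.scenarios if s not in present]
            if missing:
                raise ValueError(f"requested scenarios absent from met data: {missing}")
            met = met[met["scenario"].isin(config.scenarios)].reset_index(drop=True)
        if config.baseline_name not in set(met["scenario"].unique()):
            raise ValueError(f"baseline scenario {config.baseline_name!r} not present")
    except Exception as exc:
        write_manifest()
        raise PipelineError("met", str(exc)) from exc
    if simulated:
        write_met_csv(met, out_dir / "met.csv")
        manifest["artifacts"].append("met.csv")
    finish_stage("met", hours=len(met), simulated=simulated,
                 scenarios=sorted(met["scenario"].unique().tolist()))

    # --- stage 2: WBGT --------------------------------------------------------
    try:
        wbgt = compute_wbgt_series(met, config.globe, config.sun_rule)
    except Exception as exc:
        write_manifest()
        raise PipelineError("wbgt", str(exc)) from exc
    write_wbgt_csv(wbgt, out_dir / "wbgt.csv")
    manifest["artifacts"].append("wbgt.csv")
    finish_stage(
        "wbgt",
        hours=len(wbgt),
        sun_hours=int((wbgt["branch"] == "sun").sum()),
        solver_failures=wbgt.attrs.get("n_failures", 0),
    )

    # --- stage 3: productivity ------------------------------------------------
    try:
        shift_report = _shift_report_with_total(wbgt, config.schedule)
        base_report = shift_report[
            (shift_report["scenario"] == config.baseline_name) & (shift_report["shift"] != "total")
        ]
        gained_frames = []
        for scenario in shift_report["scenario"].unique():
            scn_report = shift_report[
                (shift_report["scenario"] == scenario) & (shift_report["shift"] != "total")
            ]
            gained_frames.append(hours_gained(base_report, scn_report))
        gained = pd.concat(gained_frames, ignore_index=True)
        diurnal = diurnal_mean_wbgt(wbgt)
    except Exception as exc:
        write_manifest()
        raise PipelineError("productivity", str(exc)) from exc
    shift_report.to_csv(out_dir / "shift_report.csv", index=False, float_format="%.6f")
    gained.to_csv(out_dir / "hours_gained.csv", index=False, float_format="%.6f")
    diurnal.to_csv(out_dir / "diurnal_wbgt.csv", index=False, float_format="%.6f")
    manifest["artifacts"] += ["shift_report.csv", "hours_gained.csv", "diurnal_wbgt.csv"]
    finish_stage("productivity", shifts=len(config.schedule.names),
                 scenarios=int(shift_report["scenario"].nunique()))

    write_manifest()
    manifest["artifacts"].append("manifest.json")
    return {
        "met": met,
        "wbgt": wbgt,
        "shift_report": shift_report,
        "hours_gained": gained,
        "diurnal": diurnal,
        "manifest": manifest,
        "out_dir": out_dir,
    }
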