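"""Broadband surface albedo from multiband reflectance, and albedo scenarios.

Broadband shortwave albedo is a weighted sum of narrowband surface
reflectances (blue, green, red, near-infrared and two shortwave-infrared
bands for a Sentinel-2-like sensor), ``albedo = offset + sum_b w_b * rho_b``.
Weighted sums can exceed 1 over very bright targets (sensor noise, specular
roofs); values above 1 are clipped to 1, and negative values to 0.

Scenario modelling replaces each surface type's albedo with a prescribed
value per scenario (baseline / low / moderate / high), monotonically
brightening per type.

Raster IO is deliberately minimal: single-band TIFFs (via ``tifffile``) and
whitespace-delimited text matrices; cloud/nodata masking is accepted as a
precomputed mask or score grid.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Optional

import numpy as np

__all__ = [
    "REQUIRED_BANDS",
    "BandCoefficients",
    "BandStack",
    "AlbedoRaster",
    "ScenarioTable",
    "load_default_coefficients",
    "narrowband_to_broadband",
    "campus_summary",
    "apply_scenario",
    "mask_from_cloud_score",
    "read_band_grid",
    "write_albedo_grid",
]

REQUIRED_BANDS = ("B2", "B3", "B4", "B8", "B11", "B12")

SURFACE_TYPES = (
    "roofs",
    "aprons",
    "parking",
    "roadways/shoulders/taxiways",
    "unclassified pavements",
    "runways",
)

SCENARIOS = ("baseline", "low", "moderate", "high")

# Prescribed per-surface-type albedos: baseline and the three modification
# scenarios (low / moderate / high).
DEFAULT_SCENARIO_ALBEDOS: dict[str, dict[str, float]] = {
    "roofs": {"baseline": 0.28, "low": 0.63, "moderate": 0.75, "high": 0.85},
    "aprons": {"baseline": 0.21, "low": 0.30, "moderate": 0.35, "high": 0.40},
    "parking": {"baseline": 0.18, "low": 0.30, "moderate": 0.35, "high": 0.40},
    "roadways/shoulders/taxiways": {"baseline": 0.18, "low": 0.30, "moderate": 0.35, "high": 0.40},
    "unclassified pavements": {"baseline": 0.19, "low": 0.35, "moderate": 0.40, "high": 0.45},
    "runways": {"baseline": 0.15, "low": 0.20, "moderate": 0.25, "high": 0.30},
}


# ---------------------------------------------------------------------------
# types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BandCoefficients:
    """Per-band weights and offset of a narrow-to-broadband conversion."""

    weights: Mapping[str, float]
    offset: float = 0.0
    name: str = "custom"

    @classmethod
    def from_json(cls, path) -> "BandCoefficients":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            weights=dict(payload["weights"]),
            offset=float(payload.get("offset", 0.0)),
            name=payload.get("name", Path(path).stem),
        )


def load_default_coefficients() -> BandCoefficients:
    """The packaged Sentinel-2 coefficient set (Bonafoni & Sekertekin 2020)."""
    ref = resources.files("heatshift.data") / "s2_broadband_coeffs.json"
    with resources.as_file(ref) as path:
        return BandCoefficients.from_json(path)


@dataclass
class BandStack:
    """Co-registered per-band reflectance grids plus a shared validity mask.

    ``mask`` is True where pixels are valid (cloud-free, in-swath).
    """

    bands: dict[str, np.ndarray]
    resolution: float = 10.0
    mask: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        shapes = {name: grid.shape for name, grid in self.bands.items()}
        if len(set(shapes.values())) != 1:
            raise ValueError(f"bands differ in shape: {shapes}")
        shape = next(iter(shapes.values()))
        if self.mask is None:
            self.mask = np.ones(shape, dtype=bool)
        elif self.mask.shape != shape:
            raise ValueError("mask shape does not match band shape")
        for name, grid in self.bands.items():
            if np.any(grid[self.mask] < 0):
                raise ValueError(f"band {name} has negative reflectance in valid pixels")


@dataclass
class AlbedoRaster:
    """Per-pixel broadband albedo with its resolution and validity mask."""

    values: np.ndarray
    resolution: float = 10.0
    mask: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if self.mask is None:
            self.mask = np.ones(self.values.shape, dtype=bool)
        elif self.mask.shape != self.values.shape:
            raise ValueError("mask shape does not match raster shape")


@dataclass(frozen=True)
class ScenarioTable:
    """Surface-type -> albedo mapping per scenario, monotone per type."""

    albedos: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: DEFAULT_SCENARIO_ALBEDOS
    )

    def __post_init__(self) -> None:
        for surface, row in self.albedos.items():
            for scenario, value in row.items():
                if not (0.0 <= value <= 1.0):
                    raise ValueError(f"albedo out of [0, 1]: {surface}/{scenario}={value}")
            ordered = [row[s] for s in SCENARIOS if s in row]
            if any(b < a for a, b in zip(ordered, ordered[1:])):
                raise ValueError(
                    f"albedos for {surface!r} must be non-decreasing baseline -> high"
                )

    @classmethod
    def from_json(cls, path) -> "ScenarioTable":
        with open(path) as fh:
            return cls(albedos=json.load(fh))

    def value(self, surface_type: str, scenario: str) -> float:
        try:
            return self.albedos[surface_type][scenario]
        except KeyError as exc:
            raise KeyError(f"no albedo for surface {surface_type!r} scenario {scenario!r}") from exc


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def narrowband_to_broadband(
    stack: BandStack,
    coefficients: Optional[BandCoefficients] = None,
) -> AlbedoRaster:
    """Broadband albedo from a band stack via a linear narrowband combination.

    ``albedo = offset + sum_b w_b * reflectance_b``, then clipped to [0, 1]
    (values above 1 arise from sensor noise or highly reflective materials
    and are set to 1; negatives to 0).  The validity mask is propagated.
    """
    if coefficients is None:
        coefficients = load_default_coefficients()
    missing = [b for b in coefficients.weights if b not in stack.bands]
    if missing:
        raise KeyError(f"band stack missing bands required by coefficients: {missing}")
    albedo = np.full(next(iter(stack.bands.values())).shape, coefficients.offset, dtype=float)
    for band, weight in coefficients.weights.items():
        albedo = albedo + weight * stack.bands[band]
    albedo = np.clip(albedo, 0.0, 1.0)
    return AlbedoRaster(values=albedo, resolution=stack.resolution, mask=stack.mask.copy())


def campus_summary(
    raster: AlbedoRaster,
    boundary_mask: Optional[np.ndarray] = None,
    bins: int = 20,
) -> dict:
    """Unweighted albedo statistics over unmasked pixels inside a boundary.

    Returns mean, min, max, pixel count and a histogram over [0, 1].
    """
    select = raster.mask.copy()
    if boundary_mask is not None:
        if boundary_mask.shape != raster.values.shape:
            raise ValueError("boundary mask shape does not match raster")
        select &= boundary_mask.astype(bool)
    values = raster.values[select]
    if values.size == 0:
        raise ValueError("no valid pixels selected for campus summary")
    counts, edges = np.histogram(values, bins=bins, range=(0.0, 1.0))
    return {
        "mean": float(values.mean()),
        "min": float(values.min()),
        "max": float(values.max()),
        "count": int(values.size),
        "histogram": {"counts": counts.tolist(), "bin_edges": edges.tolist()},
    }


def apply_scenario(
    surface_type_map: np.ndarray,
    legend: Mapping[int, str],
    table: ScenarioTable,
    scenario: str,
    baseline_raster: Optional[AlbedoRaster] = None,
    passthrough_codes: tuple[int, ...] = (),
    resolution: float = 10.0,
) -> AlbedoRaster:
    """Albedo raster obtained by assigning each surface type its scenario albedo.

    ``surface_type_map`` is integer-coded; ``legend`` maps codes to surface
    type names known to the table.  Codes listed in ``passthrough_codes``
    keep the ``baseline_raster`` value (required if any passthrough code is
    present); any other unknown code is an error.
    """
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}; expected one of {SCENARIOS}")
    codes = np.unique(surface_type_map)
    unknown = [int(c) for c in codes if int(c) not in legend and int(c) not in passthrough_codes]
    if unknown:
        raise ValueError(f"surface codes without legend entry or passthrough flag: {unknown}")
    out = np.empty(surface_type_map.shape, dtype=float)
    mask = np.ones(surface_type_map.shape, dtype=bool)
    for code in codes:
        sel = surface_type_map == code
        if int(code) in passthrough_codes:
            if baseline_raster is None:
                raise ValueError("passthrough codes present but no baseline raster supplied")
            out[sel] = baseline_raster.values[sel]
            mask[sel] = baseline_raster.mask[sel]
        else:
            out[sel] = table.value(legend[int(code)], scenario)
    return AlbedoRaster(values=out, resolution=resolution, mask=mask)


def mask_from_cloud_score(score: np.ndarray, threshold: float = 0.60) -> np.ndarray:
    """Validity mask from a per-pixel clear-sky score: valid iff score >= threshold."""
    return np.asarray(score, dtype=float) >= threshold


# ---------------------------------------------------------------------------
# raster IO
# ---------------------------------------------------------------------------


def read_band_grid(path) -> np.ndarray:
    """Read a single-band grid: TIFF (.tif/.tiff) or delimited text matrix."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        grid = np.asarray(tifffile.imread(path), dtype=float)
    else:
        grid = np.loadtxt(path, dtype=float)
    if grid.ndim == 1:
        grid = grid[np.newaxis, :]
    if grid.ndim != 2:
        raise ValueError(f"{path}: expected a single-band 2-D grid, got shape {grid.shape}")
    return grid


def read_band_stack(directory, resolution: float = 10.0, mask_path=None) -> BandStack:
    """Read ``<band>.tif`` / ``<band>.txt`` grids for all required bands."""
    directory = Path(directory)
    bands = {}
    for band in REQUIRED_BANDS:
        candidates = [directory / f"{band}{ext}" for ext in (".tif", ".tiff", ".txt")]
        found = next((p for p in candidates if p.exists()), None)
        if found is None:
            raise FileNotFoundError(f"missing band grid for {band} in {directory}")
        bands[band] = read_band_grid(found)
    mask = None
    if mask_path is not None:
        mask = read_band_grid(mask_path).astype(bool)
    return BandStack(bands=bands, resolution=resolution, mask=mask)


def write_albedo_grid(raster: AlbedoRaster, path) -> None:
    """Write an albedo raster: TIFF, or text matrix for any other suffix."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        tifffile.imwrite(path, raster.values.astype(np.float32))
    else:
        np.savetxt(path, raster.values, fmt="%.6f")
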