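"""Projection over climate grids, thresholding, areas, ensembles, range table.

For each selected algorithm, the model refitted on all data is projected over
the current grid and over every GCM x RCP x year grid; probabilities are
binarised at the algorithm's *current-conditions* max-kappa threshold, the
suitable area is summed with a cosine-latitude cell-area correction, and per
scenario the mean/min/max across (algorithm x GCM) members plus the percent
of the current simulated range left are reported.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, SchemaError, UndefinedMetricError
from .grids import KM_PER_DEGREE, ClimateGrid, GridGeometry, ScenarioSpec
from .evaluation import ThresholdResult
from .models import SdmModel, predict


@dataclass
class SuitabilitySurface:
    """Per-cell probability of occurrence with provenance (algorithm, scenario)."""

    geometry: GridGeometry
    values: np.ndarray  # probabilities; NaN marks no-data cells
    algorithm: str
    scenario: ScenarioSpec

    def __post_init__(self) -> None:
        if self.values.shape != self.geometry.shape:
            raise SchemaError("surface values do not match the geometry")


@dataclass
class BinaryMask:
    """Binarised suitability: 1 suitable, 0 unsuitable, NaN no-data."""

    geometry: GridGeometry
    values: np.ndarray


def project_surface(model: SdmModel, grid: ClimateGrid) -> SuitabilitySurface:
    """Predict probability of occurrence for every grid cell.

    Cells with a non-finite value in any band become no-data (NaN) and are
    excluded from areas downstream.
    """
    missing = [c for c in model.covariates if c not in grid.bands]
    if missing:
        raise SchemaError(f"grid is missing model covariate band(s): {missing}")
    table = grid.as_table()
    valid = np.isfinite(table[model.covariates].to_numpy(dtype=float)).all(axis=1)
    out = np.full(len(table), np.nan)
    if valid.any():
        safe = table.loc[valid, model.covariates]
        out[valid] = predict(model, safe)
    return SuitabilitySurface(
        grid.geometry,
        out.reshape(grid.geometry.shape),
        algorithm=model.spec.id,
        scenario=grid.scenario,
    )


def binarize(surface: SuitabilitySurface, threshold: float) -> BinaryMask:
    """Cell = 1 iff probability >= threshold; no-data stays no-data."""
    if not (0.0 <= threshold <= 1.0):
        raise ConfigurationError("threshold must lie in [0, 1]")
    v = surface.values
    out = np.where(np.isnan(v), np.nan, (v >= threshold).astype(float))
    return BinaryMask(surface.geometry, out)


def mask_area_km2(mask: BinaryMask) -> float:
    """Total area of the suitable cells.

    Cell area uses the cosine-latitude rectangle approximation
    (resolution * 111.32 km)^2 * cos(latitude of the cell centre).
    """
    row_area = mask.geometry.cell_area_km2()  # per row (south to north)
    ones = np.nan_to_num(mask.values, nan=0.0)
    return float((ones.sum(axis=1) * row_area).sum())


def ensemble_mean_surface(
    surfaces: Sequence[SuitabilitySurface],
) -> SuitabilitySurface:
    """Cell-wise arithmetic mean; no-data propagates from any member."""
    if not surfaces:
        raise ConfigurationError("cannot ensemble zero surfaces")
    geom = surfaces[0].geometry
    for s in surfaces[1:]:
        if s.geometry != geom:
            raise SchemaError("ensemble members have mismatched geometries")
    stack = np.stack([s.values for s in surfaces])
    mean = stack.mean(axis=0)  # plain mean: any NaN member poisons the cell
    algs = sorted({s.algorithm for s in surfaces})
    return SuitabilitySurface(geom, mean, algorithm="+".join(algs),
                              scenario=surfaces[0].scenario)


def percent_left(future_area_km2: float, current_area_km2: float) -> int:
    """Integer percent of the current simulated range remaining (half-up rounding)."""
    if current_area_km2 <= 0:
        raise UndefinedMetricError("current area must be positive")
    return int(math.floor(100.0 * future_area_km2 / current_area_km2 + 0.5))


@dataclass
class RangeEstimate:
    """Suitable-area summary for one scenario (the range-table row)."""

    scenario: str
    rcp: float | None
    year: int | None
    member_areas_km2: dict[tuple[str, str], float]  # (algorithm, gcm) -> km^2
    mean_area_km2: float
    min_area_km2: float
    max_area_km2: float
    percent_left: int | None
    percent_left_min: int | None
    percent_left_max: int | None


def _mean_minmax(values: Sequence[float]) -> tuple[float, float, float]:
    arr = np.asarray(list(values), dtype=float)
    return float(arr.mean()), float(arr.min()), float(arr.max())


def scenario_range_table(
    models: Mapping[str, SdmModel],
    thresholds: Mapping[str, ThresholdResult],
    scenario_grids: Sequence[ClimateGrid],
    current_grid: ClimateGrid,
) -> list[RangeEstimate]:
    """Build the scenario summary table.

    The current simulated range is the mean over algorithms of the current
    binarised areas; each future (RCP, year) row averages suitable area over
    every (algorithm x GCM) member, binarised at the algorithm's
    current-conditions threshold, with min-max across members and percent of
    the current mean range left.
    """
    missing = [a for a in models if a not in thresholds]
    if missing:
        raise ConfigurationError(f"no max-kappa threshold for algorithm(s): {missing}")
    if not current_grid.scenario.is_current:
        raise ConfigurationError("current_grid must carry the current scenario")

    current_areas: dict[tuple[str, str], float] = {}
    for alg, model in models.items():
        surf = project_surface(model, current_grid)
        area = mask_area_km2(binarize(surf, thresholds[alg].threshold))
        current_areas[(alg, "current")] = area
    cur_mean, cur_min, cur_max = _mean_minmax(current_areas.values())
    out = [
        RangeEstimate(
            scenario="current", rcp=None, year=None,
            member_areas_km2=current_areas,
            mean_area_km2=cur_mean, min_area_km2=cur_min, max_area_km2=cur_max,
            percent_left=None, percent_left_min=None, percent_left_max=None,
        )
    ]

    by_scenario: dict[tuple[float, int], list[ClimateGrid]] = {}
    for g in scenario_grids:
        if g.scenario.is_current:
            raise ConfigurationError("scenario_grids must all be future scenarios")
        by_scenario.setdefault((g.scenario.rcp, g.scenario.year), []).append(g)

    for (rcp, year), grids in sorted(by_scenario.items(), key=lambda kv: (kv[0][1], kv[0][0])):
        member_areas: dict[tuple[str, str], float] = {}
        for alg, model in models.items():
            # threshold transfer: future binarisation always uses the
            # algorithm's current-conditions max-kappa threshold
            thr = thresholds[alg].threshold
            for g in grids:
                surf = project_surface(model, g)
                member_areas[(alg, g.scenario.gcm)] = mask_area_km2(
                    binarize(surf, thr)
                )
        mean_a, min_a, max_a = _mean_minmax(member_areas.values())
        out.append(
            RangeEstimate(
                scenario=f"rcp{rcp}_{year}", rcp=rcp, year=year,
                member_areas_km2=member_areas,
                mean_area_km2=mean_a, min_area_km2=min_a, max_area_km2=max_a,
                percent_left=percent_left(mean_a, cur_mean) if cur_mean > 0 else None,
                percent_left_min=percent_left(min_a, cur_mean) if cur_mean > 0 else None,
                percent_left_max=percent_left(max_a, cur_mean) if cur_mean > 0 else None,
            )
        )
    return out


def range_table_to_frame(estimates: Sequence[RangeEstimate]) -> pd.DataFrame:
    """Flatten RangeEstimates into the CSV layout of the scenario summary."""
    rows = []
    for e in estimates:
        rows.append(
            {
                "scenario": e.scenario,
                "rcp": e.rcp,
                "year": e.year,
                "mean_area_km2": e.mean_area_km2,
                "area_min": e.min_area_km2,
                "area_max": e.max_area_km2,
                "percent_left": e.percent_left,
                "percent_min": e.percent_left_min,
                "percent_max": e.percent_left_max,
            }
        )
    return pd.DataFrame(rows)
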