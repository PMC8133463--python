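"""Projection surfaces, binarisation, areas, ensembles, the scenario table."""

import math

import numpy as np
import pandas as pd
import pytest

from climenv.errors import ConfigurationError, SchemaError, UndefinedMetricError
from climenv.evaluation import max_kappa_threshold
from climenv.grids import ClimateGrid, GridGeometry, ScenarioSpec
from climenv.models import AlgorithmSpec, fit, predict
from climenv.projection import (
    BinaryMask,
    SuitabilitySurface,
    binarize,
    ensemble_mean_surface,
    mask_area_km2,
    percent_left,
    project_surface,
    scenario_range_table,
)
from climenv.synthetic import generate_future_grid, true_occupancy


def surface_of(values, geom=None, scenario=None):
    values = np.asarray(values, dtype=float)
    geom = geom or GridGeometry(0.0, 0.0, 0.5, values.shape[1], values.shape[0])
    return SuitabilitySurface(geom, values, "GLM", scenario or ScenarioSpec.current())


class TestProjectSurface:
    def test_surface_matches_pointwise_prediction(self, small_world, small_table):
        model = fit(AlgorithmSpec("GLM"), small_table)
        surf = project_surface(model, small_world["grid"])
        geom = small_world["grid"].geometry
        rows, cols, inside = geom.cell_index(small_table["lon"], small_table["lat"])
        assert inside.all()
        direct = predict(model, small_table)
        np.testing.assert_allclose(surf.values[rows, cols], direct, atol=1e-12)

    def test_recovers_true_occupancy_pattern(self, small_world, small_table, small_config):
        model = fit(AlgorithmSpec("GLM"), small_table)
        surf = project_surface(model, small_world["grid"])
        truth = true_occupancy(small_world["grid"], small_config).values
        r = np.corrcoef(surf.values.ravel(), truth.ravel())[0, 1]
        assert r > 0.7

    def test_missing_band_raises_and_nodata_propagates(self, small_table):
        model = fit(AlgorithmSpec("GLM"), small_table)
        geom = GridGeometry(0, 0, 0.5, 2, 2)
        with pytest.raises(SchemaError):
            project_surface(model, ClimateGrid(geom, {"bio_maxtemp": np.zeros((2, 2))}))

        bands = {c: np.full((2, 2), small_table[c].mean()) for c in model.covariates}
        bands["bio_maxtemp"][0, 0] = np.nan
        surf = project_surface(model, ClimateGrid(geom, bands))
        assert np.isnan(surf.values[0, 0]) and np.isfinite(surf.values[1, 1])


class TestBinarize:
    def test_threshold_bounds(self):
        s = surface_of([[0.2, 0.8]])
        assert binarize(s, 0.0).values.tolist() == [[1.0, 1.0]]
        assert binarize(s, 1.0).values.tolist() == [[0.0, 0.0]]
        with pytest.raises(ConfigurationError):
            binarize(s, 1.0001)

    def test_comparator_is_greater_equal_and_nodata_kept(self):
        s = surface_of([[0.5, np.nan]])
        out = binarize(s, 0.5)
        assert out.values[0, 0] == 1.0 and np.isnan(out.values[0, 1])

    def test_raising_threshold_never_adds_cells(self):
        rng = np.random.default_rng(0)
        s = surface_of(rng.random((10, 10)))
        prev = binarize(s, 0.0).values
        for t in np.linspace(0.1, 1.0, 10):
            cur = binarize(s, t).values
            assert (cur <= prev).all()
            prev = cur


class TestArea:
    def test_empty_mask_is_zero(self):
        geom = GridGeometry(0, 0, 0.5, 4, 4)
        assert mask_area_km2(BinaryMask(geom, np.zeros((4, 4)))) == 0.0

    def test_single_equator_cell_against_spherical_oracle(self):
        res = 1.0 / 120.0
        geom = GridGeometry(0.0, -res / 2, res, 1, 1)
        area = mask_area_km2(BinaryMask(geom, np.ones((1, 1))))
        # independent spherical-zone computation
        R, dlam = 6371.0, math.radians(res)
        exact = R * R * dlam * (math.sin(math.radians(res / 2)) * 2)
        assert area == pytest.approx(0.8606, abs=0.002)
        assert abs(area - exact) / exact < 0.005

    def test_reflection_about_equator_preserves_area(self):
        north = GridGeometry(10.0, 5.0, 0.25, 8, 6)
        south = GridGeometry(10.0, -5.0 - 6 * 0.25, 0.25, 8, 6)
        rng = np.random.default_rng(1)
        cells = (rng.random((6, 8)) > 0.5).astype(float)
        a_n = mask_area_km2(BinaryMask(north, cells))
        a_s = mask_area_km2(BinaryMask(south, cells[::-1]))
        assert a_n == pytest.approx(a_s, rel=1e-12)

    def test_area_additive_over_disjoint_masks(self):
        geom = GridGeometry(0, 0, 0.5, 6, 6)
        rng = np.random.default_rng(2)
        all_cells = rng.random((6, 6)) > 0.4
        a = all_cells.copy()
        a[3:] = False
        b = all_cells & ~a
        total = mask_area_km2(BinaryMask(geom, all_cells.astype(float)))
        assert total == pytest.approx(
            mask_area_km2(BinaryMask(geom, a.astype(float)))
            + mask_area_km2(BinaryMask(geom, b.astype(float)))
        )


class TestEnsemble:
    def test_identity_complement_and_mean(self):
        rng = np.random.default_rng(3)
        p = rng.random((5, 5))
        s = surface_of(p)
        np.testing.assert_array_equal(ensemble_mean_surface([s]).values, p)
        comp = surface_of(1 - p)
        np.testing.assert_allclose(
            ensemble_mean_surface([s, comp]).values, 0.5, atol=1e-12
        )
        np.testing.assert_allclose(
            ensemble_mean_surface([s, s, s]).values, p, rtol=0, atol=1e-15
        )

    def test_nodata_poisons_cell_and_geometry_must_match(self):
        p = np.array([[0.5, 0.5]])
        q = np.array([[np.nan, 0.7]])
        out = ensemble_mean_surface([surface_of(p), surface_of(q)])
        assert np.isnan(out.values[0, 0]) and out.values[0, 1] == pytest.approx(0.6)
        other = surface_of(np.zeros((2, 2)))
        with pytest.raises(SchemaError):
            ensemble_mean_surface([surface_of(p), other])


class TestPercentLeft:
    @pytest.mark.parametrize(
        "future,current,expected",
        [
            (8311.0, 8311.0, 100),
            (3642.0, 8311.0, 44),
            (1583.0, 8311.0, 19),
            (136.0, 3495.0, 4),
            (5.0, 3495.0, 0),
        ],
    )
    def test_rounding_matches_reported_scenario_table(self, future, current, expected):
        assert percent_left(future, current) == expected

    def test_zero_current_area_rejected(self):
        with pytest.raises(UndefinedMetricError):
            percent_left(100.0, 0.0)


class TestScenarioRangeTable:
    @pytest.fixture()
    def setup(self, small_world, small_table):
        models = {a: fit(AlgorithmSpec(a), small_table) for a in ("GLM", "MAXENT")}
        thresholds = {
            a: max_kappa_threshold(
                small_table["response"].to_numpy(), predict(m, small_table)
            )
            for a, m in models.items()
        }
        return models, thresholds, small_world["grid"]

    def test_identical_future_grids_leave_100_percent(self, setup):
        models, thresholds, grid = setup
        zero = {b: 0.0 for b in grid.band_names}
        futures = [
            generate_future_grid(grid, zero, ScenarioSpec(g, 4.5, 2050))
            for g in ("GCM-A", "GCM-B")
        ]
        table = scenario_range_table(models, thresholds, futures, grid)
        current, future = table
        assert current.scenario == "current"
        assert future.percent_left == 100
        assert future.mean_area_km2 == pytest.approx(current.mean_area_km2)

    def test_ensemble_bounds_and_member_bookkeeping(self, setup):
        models, thresholds, grid = setup
        deltas = {b: 0.0 for b in grid.band_names}
        futures = [
            generate_future_grid(
                grid, {**deltas, "bio_maxtemp": off}, ScenarioSpec(g, 8.5, 2070)
            )
            for g, off in (("GCM-A", 1.0), ("GCM-B", 3.0))
        ]
        [current, fut] = scenario_range_table(models, thresholds, futures, grid)
        assert len(fut.member_areas_km2) == len(models) * 2
        assert fut.min_area_km2 <= fut.mean_area_km2 <= fut.max_area_km2
        assert fut.mean_area_km2 <= current.mean_area_km2  # warming shrinks range
        if all(a == 0 for a in fut.member_areas_km2.values()):
            assert fut.percent_left == 0

    def test_missing_threshold_rejected(self, setup):
        models, thresholds, grid = setup
        with pytest.raises(ConfigurationError):
            scenario_range_table(models, {"GLM": thresholds["GLM"]}, [], grid)
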