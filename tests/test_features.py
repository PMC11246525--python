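import datetime as dt

import numpy as np
import pandas as pd
import pytest

from wheatcast.features import (
    CLIMATE_VARS,
    ClimateStack,
    CountyMap,
    YieldRecord,
    build_feature_matrix,
    feature_columns,
    pixel_feature_table,
    resample_climate,
    truncate_to_month,
    zonal_mean,
)
from wheatcast.raster import GridSpec, RasterCube, RasterGrid
from wheatcast.reconstruct import SLOT_NAMES, SeasonSpec

from conftest import grid_from

SPEC = GridSpec(0, 6, 1, 1, 6, 6, "t")


def county_map_2() -> CountyMap:
    labels = np.ones(SPEC.shape)
    labels[:, 3:] = 2
    return CountyMap(grid_from(SPEC, labels), {1: "West", 2: "East"})


def constant_climate(years, spec=SPEC, value=10.0) -> ClimateStack:
    grids = {}
    for year in years:
        for yy, mm in SeasonSpec(year).slots:
            grids[(yy, mm)] = {v: RasterGrid.full(spec, value) for v in CLIMATE_VARS}
    return ClimateStack(spec=spec, grids=grids)


def vi_cube_for(year, fill=0.5):
    vals = np.full((8,) + SPEC.shape, fill)
    return RasterCube.from_arrays(SPEC, SeasonSpec(year).slot_dates, vals)


class TestZonalMean:
    def test_constant_county(self):
        out = zonal_mean(RasterGrid.full(SPEC, 7.0), county_map_2(), RasterGrid.full(SPEC, 1.0))
        assert out == {1: pytest.approx(7.0), 2: pytest.approx(7.0)}

    def test_two_pixel_mean(self):
        counties = county_map_2()
        mask = np.zeros(SPEC.shape)
        mask[0, 0] = mask[1, 0] = 1
        vals = np.zeros(SPEC.shape)
        vals[0, 0], vals[1, 0] = 2.0, 4.0
        out = zonal_mean(grid_from(SPEC, vals), counties, grid_from(SPEC, mask))
        assert out == {1: pytest.approx(3.0)}  # county 2 outside mask: omitted

    def test_conservation_against_direct_summation(self, rng):
        # sum over counties of mean*count must equal the masked pixel sum.
        labels = rng.integers(1, 6, SPEC.shape).astype(float)
        counties = CountyMap(grid_from(SPEC, labels), {i: str(i) for i in range(1, 6)})
        mask = grid_from(SPEC, (rng.random(SPEC.shape) > 0.3).astype(float))
        grid = grid_from(SPEC, rng.random(SPEC.shape))
        out = zonal_mean(grid, counties, mask)
        keep = (mask.values != 0)
        total = 0.0
        for cid, mean in out.items():
            count = ((labels == cid) & keep).sum()
            total += mean * count
        assert total == pytest.approx(grid.values[keep].sum(), rel=1e-12)


class TestResampleClimate:
    def test_identity_and_constant(self):
        stack = constant_climate([2020])
        assert resample_climate(stack, SPEC) is stack
        coarse_spec = GridSpec(-2, 8, 2, 2, 5, 5, "t")
        coarse = constant_climate([2020], spec=coarse_spec, value=3.0)
        fine = resample_climate(coarse, SPEC)
        g = fine.grids[(2019, 10)]["Pr"]
        assert g.spec == SPEC
        np.testing.assert_allclose(g.values[g.valid], 3.0)

    def test_affine_field_reproduced(self):
        coarse_spec = GridSpec(-2, 8, 2, 2, 5, 5, "t")
        xs, ys = coarse_spec.pixel_centers()
        field = 1.0 + 0.5 * xs[None, :] - 0.25 * ys[:, None]
        grids = {
            (yy, mm): {v: grid_from(coarse_spec, field) for v in CLIMATE_VARS}
            for (yy, mm) in SeasonSpec(2020).slots
        }
        fine = resample_climate(ClimateStack(spec=coarse_spec, grids=grids), SPEC)
        txs, tys = SPEC.pixel_centers()
        expected = 1.0 + 0.5 * txs[None, :] - 0.25 * tys[:, None]
        g = fine.grids[(2020, 3)]["SM"]
        np.testing.assert_allclose(g.values[g.valid], expected[g.valid], atol=1e-12)


class TestBuildFeatureMatrix:
    def make_inputs(self, years=(2019, 2020, 2021)):
        cubes = {y: vi_cube_for(y) for y in years}
        climate = constant_climate(years)
        counties = county_map_2()
        mask = RasterGrid.full(SPEC, 1.0)
        yields = [
            YieldRecord(cid, y, 5000.0 + cid * 100 + (y - 2019) * 10)
            for cid in (1, 2)
            for y in years
        ]
        return cubes, climate, counties, mask, yields

    def test_complete_join_counts_and_layout(self):
        fm = build_feature_matrix(*self.make_inputs())
        assert len(fm) == 6  # 2 counties x 3 years
        assert list(fm.columns) == ["unit_id", "year", *feature_columns(), "yield_kg_ha"]
        assert len(feature_columns()) == 48

    def test_missing_yield_drops_row(self):
        cubes, climate, counties, mask, yields = self.make_inputs()
        yields = [r for r in yields if not (r.unit_id == 1 and r.year == 2020)]
        fm = build_feature_matrix(cubes, climate, counties, mask, yields)
        assert len(fm) == 5
        assert not ((fm.unit_id == 1) & (fm.year == 2020)).any()

    def test_all_invalid_vi_drops_row(self):
        cubes, climate, counties, mask, yields = self.make_inputs()
        # Invalidate county 1's pixels in one slot of 2020.
        cube = cubes[2020]
        cube.layers[3].valid[:, :3] = False
        fm = build_feature_matrix(cubes, climate, counties, mask, yields)
        assert len(fm) == 5
        assert not ((fm.unit_id == 1) & (fm.year == 2020)).any()


class TestPixelFeatureTable:
    def test_rows_layout_and_mask(self):
        years = (2020,)
        cube = vi_cube_for(2020)
        climate = constant_climate(years)
        mask_vals = np.zeros(SPEC.shape)
        mask_vals[0, :5] = 1
        mask_vals[3, 2] = 1
        table = pixel_feature_table(cube, climate, grid_from(SPEC, mask_vals), 2020)
        assert len(table) == 6
        assert list(table.columns) == ["unit_id", "year", "row", "col", *feature_columns()]
        assert set(zip(table.row, table.col)) == {(0, 0), (0, 1), (0, 2), (0, 3), (0, 4), (3, 2)}

    def test_schema_matches_county_matrix(self):
        cube = vi_cube_for(2020)
        climate = constant_climate((2020,))
        table = pixel_feature_table(cube, climate, RasterGrid.full(SPEC, 1.0), 2020)
        county_fm = build_feature_matrix(
            {2020: cube}, climate, county_map_2(), RasterGrid.full(SPEC, 1.0),
            [YieldRecord(1, 2020, 5000.0), YieldRecord(2, 2020, 6000.0)],
        )
        pixel_features = [c for c in table.columns if c not in ("unit_id", "year", "row", "col")]
        county_features = [c for c in county_fm.columns
                           if c not in ("unit_id", "year", "yield_kg_ha")]
        assert pixel_features == county_features

    def test_gappy_pixel_excluded(self):
        cube = vi_cube_for(2020)
        cube.layers[4].valid[2, 2] = False
        climate = constant_climate((2020,))
        table = pixel_feature_table(cube, climate, RasterGrid.full(SPEC, 1.0), 2020)
        assert (2, 2) not in set(zip(table.row, table.col))
        assert len(table) == 35


class TestTruncateToMonth:
    @pytest.mark.parametrize("month,n_cols", [("May", 48), ("Oct", 6), ("Apr", 42)])
    def test_column_counts(self, month, n_cols):
        fm = build_feature_matrix(
            {2020: vi_cube_for(2020)}, constant_climate((2020,)), county_map_2(),
            RasterGrid.full(SPEC, 1.0),
            [YieldRecord(1, 2020, 5000.0), YieldRecord(2, 2020, 6000.0)],
        )
        out = truncate_to_month(fm, month)
        features = [c for c in out.columns if c not in ("unit_id", "year", "yield_kg_ha")]
        assert len(features) == n_cols
        assert "yield_kg_ha" in out.columns

    def test_may_is_identity_and_unknown_month_rejected(self):
        fm = build_feature_matrix(
            {2020: vi_cube_for(2020)}, constant_climate((2020,)), county_map_2(),
            RasterGrid.full(SPEC, 1.0),
            [YieldRecord(1, 2020, 5000.0), YieldRecord(2, 2020, 6000.0)],
        )
        pd.testing.assert_frame_equal(truncate_to_month(fm, "May"), fm)
        with pytest.raises(ValueError):
            truncate_to_month(fm, "July")


class TestYieldRecord:
    def test_validation(self):
        with pytest.raises(ValueError):
            YieldRecord(1, 2020, -5.0)
        with pytest.raises(ValueError):
            YieldRecord(1, 2020, 100.0, "site")  # site without coordinates
        YieldRecord(1, 2020, 100.0, "site", x=1.0, y=2.0)
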