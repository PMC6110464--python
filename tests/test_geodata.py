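"""Raster/occurrence I/O, season labels, dedup and point extraction."""

import numpy as np
import pandas as pd
import pytest

from seasonniche import (
    ClimateStack,
    GridSpec,
    Layer,
    OccurrenceRecord,
    OccurrenceSet,
    assign_season,
    dedup_occurrences,
    extract_env,
    read_occurrences,
    read_raster,
    write_occurrences,
    write_raster,
)
from seasonniche.geodata import DEFAULT_SEASON_OF_MONTH


def _layer(grid, values, variable="tmax", month=5):
    return Layer(grid, variable, month, np.asarray(values, dtype=float))


class TestRasterIO:
    def test_ascii_roundtrip_with_nodata(self, tmp_path):
        """A handwritten 3x3 ASCII grid with one nodata cell survives a
        read/write/read cycle exactly."""
        src = tmp_path / "tmax_05.asc"
        src.write_text(
            "ncols 3\nnrows 3\nxllcorner -100.0\nyllcorner 40.0\n"
            "cellsize 0.5\nNODATA_value -9999\n"
            "1.5 2.5 3.5\n4.5 -9999 6.5\n7.5 8.5 9.5\n"
        )
        layer = read_raster(src)
        assert layer.variable == "tmax" and layer.month == 5
        assert layer.grid.shape == (3, 3)
        assert layer.nodata_mask.sum() == 1
        assert layer.grid.y_origin == pytest.approx(40.0 + 3 * 0.5)
        dst = tmp_path / "copy.asc"
        write_raster(layer, dst)
        again = read_raster(dst)
        np.testing.assert_array_equal(again.values, layer.values)
        assert again.grid.approx_equal(layer.grid)

    def test_geotiff_roundtrip_preserves_grid(self, tmp_path):
        grid = GridSpec(4, 5, -110.0, 50.0, 0.0416)
        values = np.arange(20, dtype=float).reshape(4, 5)
        values[1, 2] = grid.nodata
        path = tmp_path / "prec_01.tif"
        write_raster(Layer(grid, "prec", 1, values), path)
        layer = read_raster(path)
        assert layer.grid.cell_size == pytest.approx(0.0416)
        assert layer.grid.x_origin == pytest.approx(-110.0)
        assert layer.grid.y_origin == pytest.approx(50.0)
        np.testing.assert_array_equal(layer.values, values)
        assert layer.nodata_mask.sum() == 1

    def test_geotiff_without_georeferencing_errors(self, tmp_path):
        import tifffile

        path = tmp_path / "plain.tif"
        tifffile.imwrite(str(path), np.zeros((3, 3)))
        with pytest.raises(ValueError, match="ModelPixelScale"):
            read_raster(path)

    def test_unsupported_format_errors(self, tmp_path):
        path = tmp_path / "x.png"
        path.write_text("")
        with pytest.raises(ValueError, match="unsupported"):
            read_raster(path)


class TestGridSpec:
    def test_half_open_cell_assignment_is_unique(self):
        """A point on a shared edge belongs to exactly one cell, the one to
        its south-east."""
        grid = GridSpec(4, 4, 0.0, 4.0, 1.0)
        # vertical edge between col 1 and col 2, inside row 0
        assert grid.cell_of(2.0, 3.5) == (0, 2)
        # horizontal edge between row 0 and row 1
        assert grid.cell_of(0.5, 3.0) == (1, 0)
        # corner shared by four cells -> south-east cell
        assert grid.cell_of(2.0, 2.0) == (2, 2)
        # outside
        assert grid.cell_of(-0.1, 3.0) is None
        assert grid.cell_of(0.5, 4.0 + 1e-9) is None

    def test_cell_center_inverts_cell_of(self):
        grid = GridSpec(7, 9, -110.0, 50.0, 0.0416)
        for row, col in [(0, 0), (3, 4), (6, 8)]:
            lon, lat = grid.cell_center(row, col)
            assert grid.cell_of(lon, lat) == (row, col)

    def test_invalid_grid_rejected(self):
        with pytest.raises(ValueError):
            GridSpec(0, 4, 0, 0, 1.0)
        with pytest.raises(ValueError):
            GridSpec(4, 4, 0, 0, -1.0)


class TestStack:
    def test_stack_requires_all_variables_per_month(self, small_grid):
        layers = [_layer(small_grid, np.zeros(small_grid.shape), v, 5)
                  for v in ("tmax", "tmin")]
        with pytest.raises(ValueError, match="missing variable"):
            ClimateStack(layers)

    def test_stack_rejects_mismatched_grids(self, small_grid):
        other = GridSpec(10, 10, 0.0, 10.0, 1.0)
        layers = [_layer(small_grid, np.zeros(small_grid.shape), "tmax", 5),
                  _layer(other, np.zeros(other.shape), "tmin", 5),
                  _layer(small_grid, np.zeros(small_grid.shape), "prec", 5)]
        with pytest.raises(ValueError, match="share one grid"):
            ClimateStack(layers)

    def test_negative_precipitation_rejected(self, small_grid):
        with pytest.raises(ValueError, match="non-negative"):
            _layer(small_grid, np.full(small_grid.shape, -1.0), "prec", 5)


class TestSeasons:
    @pytest.mark.parametrize(
        "month,season",
        [(5, "breeding"), (6, "breeding"), (3, "excluded"), (8, "excluded"),
         (10, "migratory"), (4, "migratory"), (12, "winter"), (1, "winter")],
    )
    def test_default_season_map(self, month, season):
        occ = OccurrenceSet([OccurrenceRecord("a", 0.0, 0.0, month)])
        assert assign_season(occ).records[0].season == season

    def test_season_map_override(self):
        occ = OccurrenceSet([OccurrenceRecord("a", 0.0, 0.0, 5)])
        out = assign_season(occ, {5: "winter"})
        assert out.records[0].season == "winter"

    def test_month_outside_map_errors(self):
        occ = OccurrenceSet([OccurrenceRecord("a", 0.0, 0.0, 7)])
        with pytest.raises(ValueError, match="month"):
            assign_season(occ, {5: "breeding"})

    def test_invalid_month_rejected_at_construction(self):
        with pytest.raises(ValueError):
            OccurrenceRecord("a", 0.0, 0.0, 13)

    def test_default_map_covers_all_months(self):
        assert sorted(DEFAULT_SEASON_OF_MONTH) == list(range(1, 13))


class TestDedup:
    grid = GridSpec(10, 10, 0.0, 10.0, 1.0)

    def _occ(self, *recs):
        return OccurrenceSet([OccurrenceRecord(*r) for r in recs])

    def test_same_cell_same_season_collapses(self):
        occ = self._occ(("a", 0.5, 9.5, 1, "winter"), ("b", 0.6, 9.6, 1, "winter"))
        out = dedup_occurrences(occ, self.grid)
        assert [r.id for r in out.records] == ["a"]  # earliest kept

    def test_same_cell_different_season_kept(self):
        occ = self._occ(("a", 0.5, 9.5, 1, "winter"), ("b", 0.6, 9.6, 5, "breeding"))
        assert len(dedup_occurrences(occ, self.grid)) == 2

    def test_distinct_cells_all_kept(self, rng):
        recs = [("r%d" % i, i + 0.5, 9.5, 1, "winter") for i in range(10)]
        assert len(dedup_occurrences(self._occ(*recs), self.grid)) == 10

    def test_idempotent(self):
        occ = self._occ(("a", 0.5, 9.5, 1, "winter"), ("b", 0.6, 9.6, 1, "winter"),
                        ("c", 3.5, 2.5, 5, "breeding"))
        once = dedup_occurrences(occ, self.grid)
        twice = dedup_occurrences(once, self.grid)
        assert [r.id for r in twice.records] == [r.id for r in once.records]

    def test_record_outside_extent_dropped_with_warning(self):
        occ = self._occ(("in", 0.5, 9.5, 1, "winter"), ("out", 55.0, 9.5, 1, "winter"))
        with pytest.warns(UserWarning, match="outside the grid"):
            out = dedup_occurrences(occ, self.grid)
        assert [r.id for r in out.records] == ["in"]


class TestExtractEnv:
    def _stack(self):
        grid = GridSpec(3, 3, 0.0, 3.0, 1.0)
        layers = []
        for month in (5, 6):
            for i, var in enumerate(("tmax", "tmin", "prec")):
                vals = (np.arange(9, dtype=float).reshape(3, 3)
                        + 100 * i + 1000 * (month - 5))
                layers.append(Layer(grid, var, month, vals))
        return ClimateStack(layers)

    def test_point_at_cell_center(self):
        stack = self._stack()
        occ = OccurrenceSet([OccurrenceRecord("a", 0.5, 2.5, 5)])
        env = extract_env(stack, occ, 5)
        np.testing.assert_allclose(env.values[0], [0.0, 100.0, 200.0])

    def test_boundary_point_assigned_south_east(self):
        stack = self._stack()
        # lon exactly on the edge between col 0 and col 1 -> col 1
        occ = OccurrenceSet([OccurrenceRecord("e", 1.0, 2.5, 5)])
        env = extract_env(stack, occ, 5)
        np.testing.assert_allclose(env.values[0], [1.0, 101.0, 201.0])

    def test_season_mean_equals_monthly_mean_per_record(self):
        stack = self._stack()
        occ = OccurrenceSet([OccurrenceRecord("a", 1.5, 1.5, 5),
                             OccurrenceRecord("b", 2.5, 0.5, 6)])
        season = extract_env(stack, occ, [5, 6])
        m5 = extract_env(stack, occ, 5)
        m6 = extract_env(stack, occ, 6)
        np.testing.assert_allclose(season.values, (m5.values + m6.values) / 2)

    def test_record_on_nodata_dropped_with_warning(self):
        grid = GridSpec(2, 2, 0.0, 2.0, 1.0)
        layers = []
        for var in ("tmax", "tmin", "prec"):
            vals = np.ones((2, 2))
            vals[0, 0] = grid.nodata
            layers.append(Layer(grid, var, 5, vals))
        stack = ClimateStack(layers)
        occ = OccurrenceSet([OccurrenceRecord("bad", 0.5, 1.5, 5),
                             OccurrenceRecord("good", 1.5, 0.5, 5)])
        with pytest.warns(UserWarning, match="nodata"):
            env = extract_env(stack, occ, 5)
        assert env.row_keys == ["good"]

    def test_all_records_on_nodata_errors(self):
        grid = GridSpec(1, 1, 0.0, 1.0, 1.0)
        layers = [Layer(grid, v, 5, np.full((1, 1), grid.nodata))
                  for v in ("tmax", "tmin", "prec")]
        stack = ClimateStack(layers)
        occ = OccurrenceSet([OccurrenceRecord("a", 0.5, 0.5, 5)] * 5)
        with pytest.warns(UserWarning):
            with pytest.raises(ValueError, match="no records"):
                extract_env(stack, occ, 5)


class TestOccurrenceCSV:
    def test_roundtrip(self, tmp_path):
        occ = OccurrenceSet([OccurrenceRecord("a", -105.2, 48.1, 5, "breeding"),
                             OccurrenceRecord("b", -103.0, 31.0, 1, "winter")])
        path = tmp_path / "occ.csv"
        write_occurrences(occ, path)
        again = read_occurrences(path)
        assert [(r.id, r.month, r.season) for r in again.records] == [
            ("a", 5, "breeding"), ("b", 1, "winter")]

    def test_date_column_parsed_to_month(self, tmp_path):
        path = tmp_path / "occ.csv"
        pd.DataFrame({"id": ["x"], "lon": [-105.0], "lat": [40.0],
                      "date": ["2001-10-14"]}).to_csv(path, index=False)
        occ = read_occurrences(path)
        assert occ.records[0].month == 10

    def test_missing_columns_error(self, tmp_path):
        path = tmp_path / "occ.csv"
        pd.DataFrame({"id": ["x"], "lon": [1.0]}).to_csv(path, index=False)
        with pytest.raises(ValueError, match="lat"):
            read_occurrences(path)
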