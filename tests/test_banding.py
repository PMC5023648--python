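"""Band construction: equal-elevation tiling, areas, equal-area split."""

import numpy as np
import pandas as pd
import pytest

import altiband as ab
from altiband.banding import jitter_elevations


def grid_from(values, cell_area=900.0):
    return ab.ElevationGrid(np.atleast_2d(np.asarray(values, dtype=int)),
                            cell_area=cell_area)


class TestEqualElevation:
    def test_canonical_37_bands(self):
        scheme = ab.make_equal_elevation_bands(1350, 5050, 100)
        assert scheme.n_bands == 37
        assert (scheme.lowers[0], scheme.uppers[0]) == (1350, 1450)
        assert (scheme.lowers[-1], scheme.uppers[-1]) == (4950, 5050)
        assert np.all(np.diff(scheme.mids) > 0)

    def test_single_band(self):
        assert ab.make_equal_elevation_bands(0, 100, 100).n_bands == 1

    def test_non_divisible_span_rejected(self):
        with pytest.raises(ValueError, match="multiple"):
            ab.make_equal_elevation_bands(0, 250, 100)

    def test_bands_tile_domain(self):
        scheme = ab.make_equal_elevation_bands(1350, 5050, 100)
        assert np.allclose(scheme.uppers[:-1], scheme.lowers[1:])


class TestBandAreas:
    def test_direct_product(self):
        scheme = ab.make_equal_elevation_bands(0, 1000, 100)
        scheme = ab.assign_band_areas(scheme, grid_from([150] * 10))
        areas = scheme.bands["area_km2"].to_numpy()
        assert areas[1] == pytest.approx(0.009)  # 10 cells x 900 m^2
        assert areas.sum() == pytest.approx(0.009)

    def test_boundary_cell_goes_to_upper_band(self):
        """An elevation equal to a boundary belongs to the band it opens."""
        scheme = ab.make_equal_elevation_bands(0, 1000, 100)
        scheme = ab.assign_band_areas(scheme, grid_from([100]))
        assert scheme.bands["cell_count"].tolist() == [0, 1] + [0] * 8

    def test_top_band_closed(self):
        scheme = ab.make_equal_elevation_bands(0, 1000, 100)
        scheme = ab.assign_band_areas(scheme, grid_from([1000]))
        assert scheme.bands["cell_count"].iloc[-1] == 1

    def test_outside_cells_counted_not_dropped_silently(self):
        scheme = ab.make_equal_elevation_bands(100, 200, 100)
        scheme = ab.assign_band_areas(scheme, grid_from([50, 150, 250]))
        assert scheme.n_outside == 2
        assert scheme.bands["cell_count"].sum() == 1

    def test_hump_grid_matches_histogram_oracle(self, climate_grid, ee_scheme):
        counts, _ = np.histogram(climate_grid.elevations_flat(),
                                 bins=np.arange(1350, 5051, 100))
        assert np.array_equal(ee_scheme.bands["cell_count"].to_numpy(), counts)
        assert ee_scheme.mids[ee_scheme.bands["cell_count"].idxmax()] == 2700

    def test_empty_grid_rejected(self):
        scheme = ab.make_equal_elevation_bands(0, 100, 100)
        with pytest.raises(ValueError):
            ab.ElevationGrid(np.empty((0, 0)))


class TestEqualArea:
    def test_exact_divisibility(self):
        grid = grid_from(np.arange(74) * 10 + 100)
        scheme = ab.make_equal_area_bands(grid, 37, seed=0)
        assert (scheme.bands["cell_count"] == 2).all()

    def test_floor_ceil_split(self):
        grid = grid_from(np.arange(75) * 10 + 100)
        scheme = ab.make_equal_area_bands(grid, 37, seed=0)
        counts = scheme.bands["cell_count"]
        assert set(counts) == {2, 3} and (counts == 3).sum() == 1

    def test_cell_counts_differ_by_at_most_one(self, climate_grid):
        scheme = ab.make_equal_area_bands(climate_grid, 37, seed=5, domain=(1350, 5050))
        counts = scheme.bands["cell_count"]
        assert counts.max() - counts.min() <= 1

    def test_total_area_conserved(self, climate_grid, ee_scheme):
        ea = ab.make_equal_area_bands(climate_grid, 37, seed=5, domain=(1350, 5050))
        assert ea.bands["area_km2"].sum() == pytest.approx(
            ee_scheme.bands["area_km2"].sum())

    def test_width_profile_tracks_hypsography(self, climate_grid):
        """Narrowest band near the hypsographic mode; widest band in a sparse tail."""
        scheme = ab.make_equal_area_bands(climate_grid, 37, seed=5, domain=(1350, 5050))
        bands = scheme.bands
        narrow = bands.loc[bands["width_m"].idxmin()]
        assert narrow["lower"] <= 3000 and narrow["upper"] >= 2400
        assert bands["width_m"].idxmax() in (bands.index[0], bands.index[-1])

    def test_widest_band_on_top_for_bottom_heavy_mountain(self):
        """With hypsographic mass concentrated low, the topmost equal-area band
        must sweep the sparse summit and is the widest (the classic pattern)."""
        rng = np.random.default_rng(11)
        elev = (1350 + 3700 * rng.beta(1.2, 6.0, 4000)).astype(int)
        grid = ab.ElevationGrid(elev.reshape(50, 80))
        scheme = ab.make_equal_area_bands(grid, 37, seed=1, domain=(1350, 5050))
        bands = scheme.bands
        assert bands["width_m"].idxmax() == bands.index[-1]
        assert bands["width_m"].idxmin() < 18  # narrow where density peaks (low)

    def test_jitter_reproducible(self, climate_grid):
        a = ab.make_equal_area_bands(climate_grid, 37, seed=9, domain=(1350, 5050))
        b = ab.make_equal_area_bands(climate_grid, 37, seed=9, domain=(1350, 5050))
        pd.testing.assert_frame_equal(a.bands, b.bands)

    def test_jitter_is_rowmajor_uniform(self):
        elev = np.arange(10)
        j = jitter_elevations(elev, seed=4)
        rng = np.random.default_rng(4)
        assert np.allclose(j, elev + rng.uniform(-0.5, 0.5, 10))
        assert np.all(np.abs(j - elev) <= 0.5)

    def test_too_many_bands_rejected(self):
        with pytest.raises(ValueError):
            ab.make_equal_area_bands(grid_from([1, 2, 3]), 5, seed=0)

    def test_boundaries_are_straddle_midpoints(self):
        grid = grid_from([100, 200, 300, 400])
        scheme = ab.make_equal_area_bands(grid, 2, seed=0)
        j = np.sort(jitter_elevations(grid.elevations_flat(), seed=0))
        assert scheme.uppers[0] == pytest.approx((j[1] + j[2]) / 2)
        assert scheme.lowers[0] == 100 and scheme.uppers[-1] == 400


class TestBandClimate:
    def test_constant_layer(self):
        grid = ab.ElevationGrid(np.array([[100, 250, 420]]),
                                mat=np.full((1, 3), 5.0), map_=np.full((1, 3), 800.0))
        scheme = ab.make_equal_elevation_bands(0, 500, 100)
        scheme = ab.summarize_band_climate(scheme, grid)
        got = scheme.bands["mat_mean"].dropna()
        assert (got == 5.0).all()

    def test_linear_mat_monotone_band_means(self, ee_scheme):
        means = ee_scheme.bands["mat_mean"].dropna().to_numpy()
        assert np.all(np.diff(means) < 0)

    def test_matches_groupby_oracle(self, climate_grid, ee_scheme):
        df = pd.DataFrame({
            "band": ee_scheme.assign_cells(climate_grid.elevations_flat()),
            "mat": climate_grid.mat.ravel(),
            "map": climate_grid.map_.ravel(),
        })
        oracle = df[df["band"] >= 0].groupby("band")[["mat", "map"]].mean()
        bands = ee_scheme.bands
        for b, row in oracle.iterrows():
            assert bands["mat_mean"].iloc[b] == pytest.approx(row["mat"])
            assert bands["map_mean"].iloc[b] == pytest.approx(row["map"])

    def test_empty_bands_get_nan(self):
        grid = ab.ElevationGrid(np.array([[50]]), mat=np.array([[1.0]]),
                                map_=np.array([[2.0]]))
        scheme = ab.summarize_band_climate(ab.make_equal_elevation_bands(0, 300, 100), grid)
        assert np.isnan(scheme.bands["mat_mean"].iloc[2])

    def test_missing_climate_rejected(self, ee_scheme):
        bare = ab.ElevationGrid(np.array([[100]]))
        with pytest.raises(ValueError, match="climate"):
            ab.summarize_band_climate(ee_scheme, bare)
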