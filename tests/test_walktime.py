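"""Water thresholding, Tobler speeds, and the least-cost accumulation.

The accumulation is checked against an independent oracle: a networkx
Dijkstra over the explicitly enumerated weighted digraph of cell-to-cell
moves, with edge times computed here from the closed-form speed.
"""

import math

import networkx as nx
import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from foragescape import (
    GridRaster,
    threshold_water,
    tobler_speed,
    walking_time,
    water_accessibility,
)
from foragescape.walktime import FLAT_SPEED_KMH

from conftest import CELL, raster


def oracle_hours(dem: GridRaster, water_cells: set, connectivity: int = 8) -> np.ndarray:
    """Brute-force multi-source Dijkstra over the explicit edge list."""
    z = dem.values
    nrow, ncol = z.shape
    offs = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1) if (dr, dc) != (0, 0)]
    if connectivity == 16:
        offs += [(a, b) for a in (-2, -1, 1, 2) for b in (-2, -1, 1, 2) if abs(a) != abs(b)]
    G = nx.DiGraph()
    for r in range(nrow):
        for c in range(ncol):
            if np.isnan(z[r, c]):
                continue
            for dr, dc in offs:
                r2, c2 = r + dr, c + dc
                if not (0 <= r2 < nrow and 0 <= c2 < ncol) or np.isnan(z[r2, c2]):
                    continue
                dist = math.hypot(dr, dc) * CELL
                slope = (z[r2, c2] - z[r, c]) / dist
                speed = 6.0 * math.exp(-3.5 * abs(slope + 0.05))
                # reversed edge: path water -> cell accumulates cell -> water cost
                G.add_edge((r2, c2), (r, c), weight=(dist / 1000.0) / speed)
    dists = nx.multi_source_dijkstra_path_length(G, water_cells, weight="weight")
    out = np.full(z.shape, np.inf)
    for (r, c), d in dists.items():
        out[r, c] = d
    for w in water_cells:
        out[w] = 0.0
    out[np.isnan(z)] = np.nan
    return out


def water_mask_at(dem: GridRaster, cells: set):
    occ = np.zeros(dem.shape)
    for r, c in cells:
        occ[r, c] = 80.0
    return threshold_water(dem.with_values(occ))


class TestThreshold:
    def test_strictly_greater_than_cutoff(self):
        occ = raster(np.array([[5.0, 5.01], [0.0, 100.0]]))
        m = threshold_water(occ, cutoff=5.0)
        assert m.values.tolist() == [[0.0, 1.0], [0.0, 1.0]]

    def test_nodata_propagates(self):
        m = threshold_water(raster(np.array([[np.nan, 50.0]])))
        assert np.isnan(m.values[0, 0]) and m.values[0, 1] == 1.0

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="percentage"):
            threshold_water(raster(np.array([[120.0]])))

    def test_synthetic_survivor_count(self):
        from foragescape.synth import LandscapeConfig, generate_dem, generate_water_occurrence

        cfg = LandscapeConfig(
            shape=(30, 30), n_persistent_waters=3, n_ephemeral_waters=7, seed=5
        )
        dem = generate_dem(cfg)
        occ = generate_water_occurrence(cfg, dem)
        assert threshold_water(occ).n_water == 3  # ephemeral all <= 5.0 by construction


class TestToblerSpeed:
    def test_flat_ground(self):
        assert tobler_speed(0.0) == pytest.approx(6 * math.exp(-0.175), rel=1e-12)
        assert FLAT_SPEED_KMH == pytest.approx(5.03674, abs=1e-5)

    def test_maximum_at_gentle_downhill(self):
        assert tobler_speed(-0.05) == 6.0
        for s in (-0.2, -0.1, 0.0, 0.1):
            assert tobler_speed(s) < 6.0

    def test_climbing_is_slower_than_descending(self):
        # symmetric about -0.05: +s is always farther from the optimum
        # than -s for s > 0, so ascending is strictly slower
        assert tobler_speed(0.05) < tobler_speed(-0.05)
        assert tobler_speed(0.10) < tobler_speed(-0.10)

    def test_nonfinite_slope_rejected(self):
        with pytest.raises(ValueError):
            tobler_speed(np.nan)


class TestWalkingTime:
    def test_water_cell_is_zero(self, flat_dem):
        wt = walking_time(flat_dem, water_mask_at(flat_dem, {(5, 5)}))
        assert wt.hours[5, 5] == 0.0

    def test_flat_terrain_closed_form_east(self, flat_dem):
        # 10x10 flat: cell 9 columns due east of water, shortest lattice
        # path is 9 straight edges of 30 m at the flat-ground speed
        wt = walking_time(flat_dem, water_mask_at(flat_dem, {(5, 0)}))
        expected = (9 * CELL / 1000.0) / FLAT_SPEED_KMH
        assert wt.hours[5, 9] == pytest.approx(expected, rel=1e-9)

    def test_flat_terrain_diagonal_closed_form(self, flat_dem):
        wt = walking_time(flat_dem, water_mask_at(flat_dem, {(0, 0)}))
        expected = (4 * math.sqrt(2) * CELL / 1000.0) / FLAT_SPEED_KMH
        assert wt.hours[4, 4] == pytest.approx(expected, rel=1e-9)

    def test_no_water_all_unreachable(self, flat_dem):
        wt = walking_time(flat_dem, water_mask_at(flat_dem, set()))
        assert np.isinf(wt.hours[flat_dem.valid]).all()

    def test_island_cells_unreachable(self):
        z = np.full((3, 5), 100.0)
        z[:, 2] = np.nan  # nodata wall splits the grid
        dem = raster(z)
        wt = walking_time(dem, water_mask_at(dem, {(1, 0)}))
        assert np.isfinite(wt.hours[:, :2]).all()
        assert np.isinf(wt.hours[:, 3:]).all()
        assert np.isnan(wt.hours[:, 2]).all()

    @pytest.mark.parametrize("connectivity", [8, 16])
    def test_matches_bruteforce_dijkstra(self, connectivity):
        rng = np.random.default_rng(42)
        z = rng.uniform(0, 60, size=(7, 7))
        dem = raster(z)
        water = {(0, 3), (6, 6)}
        wt = walking_time(dem, water_mask_at(dem, water), connectivity)
        expected = oracle_hours(dem, water, connectivity)
        assert wt.hours == pytest.approx(expected, rel=1e-9)

    @given(st.integers(0, 2**31 - 1))
    def test_adding_water_never_increases_time(self, seed):
        rng = np.random.default_rng(seed)
        z = rng.uniform(0, 40, size=(6, 6))
        dem = raster(z)
        t1 = walking_time(dem, water_mask_at(dem, {(0, 0)})).hours
        t2 = walking_time(dem, water_mask_at(dem, {(0, 0), (5, 5)})).hours
        assert np.all(t2 <= t1 + 1e-12)

    def test_anisotropy_on_uniform_slope(self):
        # 1 x 21 strip rising east, water in the middle: reaching water
        # from the east mirror cell means walking downhill (fast),
        # from the west means climbing (slow)
        g = 0.1
        z = (np.arange(21.0) * CELL * g)[None, :]
        dem = raster(z)
        wt = walking_time(dem, water_mask_at(dem, {(0, 10)}))
        for d in range(1, 10):
            assert wt.hours[0, 10 - d] > wt.hours[0, 10 + d]

    def test_triangle_property(self):
        rng = np.random.default_rng(3)
        z = rng.uniform(0, 50, size=(6, 6))
        dem = raster(z)
        wt = walking_time(dem, water_mask_at(dem, {(2, 2)}))
        h = wt.hours
        for r in range(6):
            for c in range(5):
                dist = CELL / 1000.0
                slope = (z[r, c + 1] - z[r, c]) / CELL
                edge = dist / tobler_speed(slope)
                assert h[r, c] <= h[r, c + 1] + edge + 1e-12

    def test_max_hours_cutoff_maps_far_cells_to_inf(self, flat_dem):
        wt = walking_time(flat_dem, water_mask_at(flat_dem, {(0, 0)}), max_hours=0.03)
        assert np.isinf(wt.hours[9, 9])
        assert wt.hours[0, 1] < 0.03

    def test_misaligned_inputs_rejected(self, flat_dem):
        other = raster(np.zeros((5, 5)))
        with pytest.raises(ValueError, match="misaligned"):
            walking_time(flat_dem, water_mask_at(other, {(0, 0)}))


class TestWaterAccessibility:
    def test_membership_anchors(self, flat_dem):
        wt = walking_time(flat_dem, water_mask_at(flat_dem, {(0, 0)}))
        wt.hours[0, 1] = 8.0
        wt.hours[0, 2] = 16.0
        wt.hours[0, 3] = 36.5
        wt.hours[0, 4] = 4.0
        wt.hours[1, 0] = np.inf
        m = water_accessibility(wt)
        assert m.values[0, 0] == 1.0
        assert m.values[0, 1] == 0.5
        assert m.values[0, 2] == 0.0
        assert m.values[0, 3] == 0.0
        assert m.values[0, 4] == 0.75
        assert m.values[1, 0] == 0.0  # unreachable -> no accessibility
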