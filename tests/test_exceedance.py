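"""Along-shore stationing/interpolation and the barrier-geodesic IDW."""

import numpy as np
import pytest

from conftest import make_grid
from oracles import barrier_idw_oracle, densified_station_oracle

from ebeem.core import ShorelinePath, TideGaugeRecord
from ebeem.exceedance import (
    StationedSample,
    interpolate_alongshore,
    interpolate_with_barriers,
    station_along_shoreline,
)


def _gauge(gid, x, y, delta):
    return TideGaugeRecord(gauge_id=gid, x=x, y=y, ex50_above_mhhw=delta)


class TestStationing:
    def test_gauge_on_vertex_and_perpendicular_foot(self):
        path = ShorelinePath.from_coords(
            [(0, 0), (1000, 0), (1000, 500)], roles=("stationing",))
        samples = station_along_shoreline(
            path, [_gauge("a", 1000, 0, 0.5), _gauge("b", 600, 200, 0.6)])
        by_id = {round(s.delta, 3): s for s in samples}
        assert by_id[0.5].station_m == pytest.approx(1000.0)
        # foot of the perpendicular from (600, 200) onto the first segment
        assert by_id[0.6].station_m == pytest.approx(600.0)

    def test_matches_densified_arclength_oracle(self, rng):
        coords = [(0, 0), (800, 300), (1500, 250), (2100, 900)]
        path = ShorelinePath.from_coords(coords, roles=("stationing",))
        gauges = [_gauge(f"g{i}", float(x), float(y), 0.5)
                  for i, (x, y) in enumerate(
                      rng.uniform(0, 2000, size=(3, 2)).tolist())]
        samples = station_along_shoreline(path, gauges)
        stations = sorted(s.station_m for s in samples)
        expected = sorted(densified_station_oracle(coords, (g.x, g.y))
                          for g in gauges)
        np.testing.assert_allclose(stations, expected, atol=1.0)

    def test_distant_gauge_warns_but_is_retained(self):
        path = ShorelinePath.from_coords([(0, 0), (100, 0)], roles=("stationing",))
        with pytest.warns(UserWarning, match="retained"):
            samples = station_along_shoreline(
                path, [_gauge("far", 0, 80_000, 0.4)])
        assert len(samples) == 1

    def test_requires_stationing_role_and_gauges(self):
        bare = ShorelinePath.from_coords([(0, 0), (1, 0)], roles=("barrier",))
        with pytest.raises(ValueError):
            station_along_shoreline(bare, [_gauge("a", 0, 0, 0.1)])
        path = ShorelinePath.from_coords([(0, 0), (1, 0)], roles=("stationing",))
        with pytest.raises(ValueError):
            station_along_shoreline(path, [])


class TestAlongshore:
    def test_exact_at_nodes_linear_between_clamped_beyond(self):
        samples = [StationedSample(0.0, 0, 0, 0.4),
                   StationedSample(100.0, 100, 0, 0.6)]
        out = interpolate_alongshore(samples, np.array([0.0, 50.0, 100.0, -50.0, 250.0]))
        np.testing.assert_allclose(out, [0.4, 0.5, 0.6, 0.4, 0.6])

    def test_exactness_at_an_observed_delta(self):
        samples = [StationedSample(1234.0, 0, 0, 0.81)]
        assert interpolate_alongshore(samples, np.array([1234.0]))[0] == 0.81

    def test_bounded_by_sample_range(self, rng):
        samples = [StationedSample(float(s), 0, 0, float(d))
                   for s, d in zip(np.sort(rng.uniform(0, 1e4, 8)),
                                   rng.uniform(0.2, 1.4, 8))]
        q = rng.uniform(-1e3, 1.2e4, 200)
        out = interpolate_alongshore(samples, q)
        deltas = [s.delta for s in samples]
        assert out.min() >= min(deltas) - 1e-12
        assert out.max() <= max(deltas) + 1e-12


def _center_sample(grid, r, c, delta, station=0.0):
    cs = grid.cell_size
    return StationedSample(station,
                           grid.origin_x + (c + 0.5) * cs,
                           grid.origin_y - (r + 0.5) * cs, delta)


class TestBarrierIDW:
    def test_constant_samples_give_constant_field(self):
        grid = make_grid(np.zeros((8, 8)))
        barrier = np.zeros((8, 8), dtype=bool)
        samples = [_center_sample(grid, 0, 0, 0.5), _center_sample(grid, 7, 7, 0.5, 1.0)]
        out = interpolate_with_barriers(samples, barrier, grid)
        np.testing.assert_allclose(out.values, 0.5)

    def test_walled_off_cells_are_nodata(self):
        grid = make_grid(np.zeros((6, 6)))
        barrier = np.zeros((6, 6), dtype=bool)
        barrier[:, 3] = True  # full wall, no gap
        samples = [_center_sample(grid, 2, 0, 0.7)]
        out = interpolate_with_barriers(samples, barrier, grid)
        assert (out.values[:, 4:] == grid.nodata).all()
        assert (out.values[:, :3] != grid.nodata).all()

    def test_sample_on_barrier_cell_is_an_error(self):
        grid = make_grid(np.zeros((4, 4)))
        barrier = np.zeros((4, 4), dtype=bool)
        barrier[1, 1] = True
        with pytest.raises(ValueError, match="barrier"):
            interpolate_with_barriers([_center_sample(grid, 1, 1, 0.5)],
                                      barrier, grid)

    def test_matches_shortest_path_oracle_through_gap(self):
        """Two samples separated by a wall with one gap: field equals the
        heap-Dijkstra + IDW oracle."""
        n = 16
        grid = make_grid(np.zeros((n, n)))
        barrier = np.zeros((n, n), dtype=bool)
        barrier[:, 8] = True
        barrier[5, 8] = False  # the gap
        samples = [(3, 2, 0.4), (12, 13, 0.9)]
        got = interpolate_with_barriers(
            [_center_sample(grid, r, c, v) for r, c, v in samples],
            barrier, grid)
        expected = barrier_idw_oracle(barrier, samples, grid.origin_x,
                                      grid.origin_y, grid.cell_size)
        np.testing.assert_allclose(got.values, expected, atol=1e-9)

    def test_matches_oracle_on_random_barrier_layouts(self, rng):
        for _ in range(5):
            n = 16
            grid = make_grid(np.zeros((n, n)))
            barrier = rng.random((n, n)) < 0.2
            free = np.argwhere(~barrier)
            picks = free[rng.choice(len(free), size=4, replace=False)]
            samples = [(int(r), int(c), float(rng.uniform(0.2, 1.0)))
                       for r, c in picks]
            got = interpolate_with_barriers(
                [_center_sample(grid, r, c, v) for r, c, v in samples],
                barrier, grid)
            expected = barrier_idw_oracle(barrier, samples, grid.origin_x,
                                          grid.origin_y, grid.cell_size)
            np.testing.assert_allclose(got.values, expected, atol=1e-9)

    def test_values_bounded_by_reachable_sample_range(self, rng):
        n = 12
        grid = make_grid(np.zeros((n, n)))
        barrier = rng.random((n, n)) < 0.15
        free = np.argwhere(~barrier)
        picks = free[rng.choice(len(free), size=5, replace=False)]
        vals = rng.uniform(0.1, 1.5, 5)
        samples = [_center_sample(grid, int(r), int(c), float(v))
                   for (r, c), v in zip(picks, vals)]
        out = interpolate_with_barriers(samples, barrier, grid)
        valid = out.values != grid.nodata
        assert out.values[valid].min() >= vals.min() - 1e-9
        assert out.values[valid].max() <= vals.max() + 1e-9

    def test_collinear_no_barrier_equals_euclidean_idw(self):
        """On a single row with no barriers, grid-path distance is exactly
        Euclidean, so the field matches plain inverse-distance weighting."""
        grid = make_grid(np.zeros((1, 10)))
        samples = [_center_sample(grid, 0, 0, 0.2), _center_sample(grid, 0, 9, 1.0)]
        out = interpolate_with_barriers(samples, np.zeros((1, 10), dtype=bool), grid)
        cs = grid.cell_size
        for c in range(10):
            d0, d1 = c * cs, (9 - c) * cs
            if d0 == 0 or d1 == 0:
                expected = 0.2 if d0 == 0 else 1.0
            else:
                w0, w1 = 1 / d0 ** 2, 1 / d1 ** 2
                expected = (w0 * 0.2 + w1 * 1.0) / (w0 + w1)
            assert out.values[0, c] == pytest.approx(expected, abs=1e-6)
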