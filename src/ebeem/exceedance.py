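"""Interpolating EX50−MHHW deltas: along-shore between tide gauges, then
inland with a barrier-respecting interpolator.

Only a few long-term gauges provide extreme-water-level exceedance analyses,
so the EX50−MHHW offset must be interpolated along the coast between them and
then spread across each estuary.  The spreading step must treat landmasses as
impenetrable: two cells close in Euclidean distance but separated by a
peninsula should not share water-level information.

The interpolator used here is a barrier-geodesic inverse-distance weighting:
distances are shortest-path lengths over the 8-connected grid graph with
barrier cells removed (diagonal steps cost sqrt(2)·cell_size and may not cut
the corner between two orthogonally adjacent barrier cells), and each
non-barrier cell receives the IDW (power 2) combination of its k nearest
*reachable* samples.  Sample cells reproduce their sample values exactly;
cells with no reachable sample stay nodata.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra
from shapely.geometry import LineString, MultiLineString, Point
from shapely.geometry.base import BaseGeometry

from .core import RasterGrid, ShorelinePath, TideGaugeRecord

__all__ = [
    "StationedSample",
    "station_along_shoreline",
    "interpolate_alongshore",
    "interpolate_with_barriers",
    "rasterize_barriers",
    "seed_samples_along_path",
]

DEFAULT_SNAP_TOLERANCE_M = 50_000.0


@dataclass(frozen=True)
class StationedSample:
    """A sampled EX50−MHHW delta at an arc-length position along shore."""

    station_m: float
    x: float
    y: float
    delta: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.delta):
            raise ValueError("delta must be finite")


def _shoreline_geometry(shoreline: ShorelinePath) -> BaseGeometry:
    lines = [LineString(part) for part in shoreline.parts]
    return lines[0] if len(lines) == 1 else MultiLineString(lines)


def station_along_shoreline(
    shoreline: ShorelinePath,
    gauges: list[TideGaugeRecord],
    snap_tolerance_m: float = DEFAULT_SNAP_TOLERANCE_M,
) -> list[StationedSample]:
    """Project each gauge onto the stationing shoreline.

    Each gauge maps to the arc-length position of its nearest point on the
    path.  Gauges farther than ``snap_tolerance_m`` from the path raise a
    warning but are retained.  Output is sorted by station.
    """
    if "stationing" not in shoreline.roles:
        raise ValueError("shoreline must carry the stationing role")
    if not gauges:
        raise ValueError("at least one gauge is required")
    geom = _shoreline_geometry(shoreline)
    samples = []
    for g in gauges:
        p = Point(g.x, g.y)
        dist = geom.distance(p)
        if dist > snap_tolerance_m:
            warnings.warn(
                f"gauge {g.gauge_id} is {dist:.0f} m from the stationing "
                f"shoreline (tolerance {snap_tolerance_m:.0f} m); retained",
                stacklevel=2,
            )
        station = geom.project(p)
        foot = geom.interpolate(station)
        samples.append(StationedSample(station_m=float(station), x=foot.x, y=foot.y,
                                       delta=g.ex50_above_mhhw))
    samples.sort(key=lambda s: s.station_m)
    return samples


def interpolate_alongshore(
    samples: list[StationedSample], query_stations: np.ndarray
) -> np.ndarray:
    """Piecewise-linear delta in station, clamped to the terminal sample
    values beyond the first/last station (deltas are bounded physical
    offsets, so extrapolation is not attempted)."""
    if not samples:
        raise ValueError("at least one sample is required")
    ordered = sorted(samples, key=lambda s: s.station_m)
    st = np.array([s.station_m for s in ordered])
    dv = np.array([s.delta for s in ordered])
    return np.interp(np.asarray(query_stations, dtype=float), st, dv)


# ---------------------------------------------------------------------------
# Barrier-geodesic inverse-distance interpolation
# ---------------------------------------------------------------------------

def rasterize_barriers(grid: RasterGrid, barriers) -> np.ndarray:
    """Boolean grid, True where a cell is crossed/covered by a barrier.

    A cell is a barrier cell if its square footprint intersects any barrier
    geometry (ShorelinePath with the barrier role, or shapely geometry)."""
    import shapely

    mask = np.zeros(grid.shape, dtype=bool)
    geoms: list[BaseGeometry] = []
    for b in barriers:
        if isinstance(b, ShorelinePath):
            geoms.append(_shoreline_geometry(b))
        elif isinstance(b, BaseGeometry):
            geoms.append(b)
        else:
            raise TypeError(f"unsupported barrier type {type(b)!r}")
    if not geoms:
        return mask
    union = shapely.union_all(geoms)
    nrow, ncol = grid.shape
    cs = grid.cell_size
    x0 = grid.origin_x + np.arange(ncol) * cs
    y1 = grid.origin_y - np.arange(nrow) * cs
    xmin = np.broadcast_to(x0, (nrow, ncol)).ravel()
    ymax = np.broadcast_to(y1[:, None], (nrow, ncol)).ravel()
    boxes = shapely.box(xmin, ymax - cs, xmin + cs, ymax)
    hits = shapely.intersects(union, boxes)
    return hits.reshape(grid.shape)


def _grid_graph(barrier: np.ndarray, cell_size: float) -> coo_matrix:
    """Sparse 8-connected graph over non-barrier cells; corner cutting
    through a diagonal pair of barriers is disallowed."""
    nrow, ncol = barrier.shape
    n = nrow * ncol
    free = ~barrier
    rows_i, cols_j, weights = [], [], []

    def add_edges(dr: int, dc: int, w: float, need_corners: bool) -> None:
        r0a, r0b = max(0, -dr), min(nrow, nrow - dr)
        c0a, c0b = max(0, -dc), min(ncol, ncol - dc)
        a_free = free[r0a:r0b, c0a:c0b]
        b_free = free[r0a + dr:r0b + dr, c0a + dc:c0b + dc]
        ok = a_free & b_free
        if need_corners:
            # both orthogonal corners barred -> no diagonal pass
            corner1 = free[r0a + dr:r0b + dr, c0a:c0b]
            corner2 = free[r0a:r0b, c0a + dc:c0b + dc]
            ok &= corner1 | corner2
        rr, cc = np.nonzero(ok)
        a_idx = (rr + r0a) * ncol + (cc + c0a)
        b_idx = (rr + r0a + dr) * ncol + (cc + c0a + dc)
        rows_i.append(a_idx)
        cols_j.append(b_idx)
        weights.append(np.full(a_idx.size, w))

    add_edges(0, 1, cell_size, False)
    add_edges(1, 0, cell_size, False)
    add_edges(1, 1, np.sqrt(2.0) * cell_size, True)
    add_edges(1, -1, np.sqrt(2.0) * cell_size, True)
    if rows_i:
        i = np.concatenate(rows_i)
        j = np.concatenate(cols_j)
        w = np.concatenate(weights)
    else:
        i = j = np.array([], dtype=int)
        w = np.array([], dtype=float)
    return coo_matrix((w, (i, j)), shape=(n, n))


def interpolate_with_barriers(
    samples: list[StationedSample],
    barriers,
    grid_template: RasterGrid,
    idw_power: float = 2.0,
    idw_k: int = 8,
) -> RasterGrid:
    """Spread sampled deltas across the grid, respecting barriers.

    Every non-barrier cell receives the inverse-distance-weighted (power
    ``idw_power``) combination of its ``idw_k`` nearest reachable samples,
    where distance is the shortest barrier-avoiding path over the
    8-connected cell graph.  Samples landing on barrier cells are an error;
    unreachable cells come back nodata.
    """
    if not samples:
        raise ValueError("at least one sample is required")
    barrier_mask = (
        barriers if isinstance(barriers, np.ndarray)
        else rasterize_barriers(grid_template, barriers)
    )
    if barrier_mask.shape != grid_template.shape:
        raise ValueError("barrier mask shape does not match grid")

    nrow, ncol = grid_template.shape
    cs = grid_template.cell_size

    def cell_of(x: float, y: float) -> tuple[int, int]:
        # half-open convention: a point on a cell's south/west edge belongs
        # to that cell
        c = int(np.floor((x - grid_template.origin_x) / cs))
        r = int(np.floor((grid_template.origin_y - y) / cs))
        return min(max(r, 0), nrow - 1), min(max(c, 0), ncol - 1)

    sample_cells: dict[int, list[float]] = {}
    for s in samples:
        r, c = cell_of(s.x, s.y)
        if barrier_mask[r, c]:
            raise ValueError(
                f"sample at station {s.station_m:.1f} m falls on a barrier cell ({r},{c})"
            )
        sample_cells.setdefault(r * ncol + c, []).append(s.delta)
    nodes = np.array(sorted(sample_cells), dtype=int)
    node_values = np.array([float(np.mean(sample_cells[n])) for n in nodes])

    graph = _grid_graph(barrier_mask, cs)
    dist = dijkstra(graph, directed=False, indices=nodes)

    out = np.full((nrow * ncol,), grid_template.nodata, dtype=float)
    reachable = np.isfinite(dist).any(axis=0)
    free_flat = ~barrier_mask.ravel()
    targets = np.flatnonzero(reachable & free_flat)

    d_t = dist[:, targets]  # (n_samples, n_targets)
    k = min(idw_k, len(nodes))
    # k smallest path distances per target cell
    part = np.argpartition(d_t, k - 1, axis=0)[:k, :]
    d_k = np.take_along_axis(d_t, part, axis=0)
    v_k = node_values[part]
    # cells holding a sample reproduce it exactly
    zero_any = (d_k == 0.0).any(axis=0)
    with np.errstate(divide="ignore"):
        w = 1.0 / np.power(d_k, idw_power)
    w[~np.isfinite(d_k)] = 0.0
    w[~np.isfinite(w)] = 0.0
    denom = w.sum(axis=0)
    vals = np.where(denom > 0, (w * v_k).sum(axis=0) / np.where(denom > 0, denom, 1.0), np.nan)
    # exact reproduction at sample cells
    if zero_any.any():
        zi = np.flatnonzero(zero_any)
        for t in zi:
            hit = d_k[:, t] == 0.0
            vals[t] = v_k[hit, t].mean()
    good = np.isfinite(vals) & (denom > 0) | zero_any
    out[targets[good]] = vals[good]
    return grid_template.copy_with(out.reshape(nrow, ncol), vertical_datum="NONE")


def seed_samples_along_path(
    shoreline: ShorelinePath,
    stationed: list[StationedSample],
    grid: RasterGrid,
    spacing: float | None = None,
) -> list[StationedSample]:
    """Seed the inland interpolator: one sample per cell the stationing path
    crosses, valued by along-shore interpolation at the cell's station."""
    geom = _shoreline_geometry(shoreline)
    step = spacing if spacing is not None else grid.cell_size / 2.0
    length = geom.length
    n = max(int(np.ceil(length / step)) + 1, 2)
    stations = np.linspace(0.0, length, n)
    deltas = interpolate_alongshore(stationed, stations)
    cs = grid.cell_size
    seen: dict[tuple[int, int], StationedSample] = {}
    for st, dv in zip(stations, deltas):
        p = geom.interpolate(float(st))
        c = int(np.floor((p.x - grid.origin_x) / cs))
        r = int(np.floor((grid.origin_y - p.y) / cs))
        if not (0 <= r < grid.shape[0] and 0 <= c < grid.shape[1]):
            continue
        if (r, c) not in seen:
            # sample pinned at the cell center so path distances are exact
            x = grid.origin_x + (c + 0.5) * cs
            y = grid.origin_y - (r + 0.5) * cs
            seen[(r, c)] = StationedSample(station_m=float(st), x=x, y=y, delta=float(dv))
    return sorted(seen.values(), key=lambda s: s.station_m)
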