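"""Tidal datum surfaces: coverage-limited MHHW rasters, watershed-sealed
nearest-source extrapolation, and assembly of the 50%-exceedance surface.

Datum-transformation products rarely cover the full tidally influenced
landscape — coverage typically ends partway up coastal rivers.  The sealed
extrapolation here extends the covered surface inland by nearest-source
(Euclidean allocation) filling, with watershed polygons acting as seals so
that values from one drainage cannot contaminate a neighboring one:

* Pass 1 operates per *fine* watershed unit that contains at least one
  covered cell: each uncovered cell whose center falls in the unit takes the
  value of the nearest covered cell (center-to-center Euclidean distance in
  projected meters) whose center also falls in that unit.
* Pass 2 extends the analysis into *coarse* units that contained no covered
  cell at all, using the value-bearing cells after Pass 1 as sources (within
  the coarse unit when any exist there, otherwise the nearest value-bearing
  cell anywhere in the domain).

Cells belonging to no unit, or in units with no reachable source, stay
nodata.  Distance ties are broken by the smallest row-major source index.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .core import RasterGrid, WatershedUnit, require_aligned

__all__ = ["DatumSurface", "seal_extrapolate", "assemble_ex50", "unit_membership"]


@dataclass
class DatumSurface:
    """A datum raster plus the boolean mask of genuinely covered cells.

    Wherever ``coverage_mask`` is True the grid must hold data (not nodata).
    """

    grid: RasterGrid
    coverage_mask: np.ndarray

    def __post_init__(self) -> None:
        self.coverage_mask = np.asarray(self.coverage_mask, dtype=bool)
        if self.coverage_mask.shape != self.grid.shape:
            raise ValueError("coverage mask shape does not match grid")
        if np.any(self.coverage_mask & ~self.grid.mask_valid):
            raise ValueError("coverage mask marks nodata cells as covered")


def unit_membership(grid: RasterGrid, units: list[WatershedUnit]) -> np.ndarray:
    """Assign each cell center to the unit containing it.

    Returns an int grid of indices into ``units`` (-1 = no unit).  Units are
    visited in ascending ``unit_id`` order and a cell keeps its first
    assignment, so centers exactly on a shared boundary deterministically go
    to the unit with the smaller unit_id.
    """
    import shapely

    xs, ys = grid.cell_centers()
    member = np.full(grid.shape, -1, dtype=int)
    order = sorted(range(len(units)), key=lambda i: units[i].unit_id)
    flat_x, flat_y = xs.ravel(), ys.ravel()
    for idx in order:
        unassigned = member.ravel() == -1
        if not unassigned.any():
            break
        # intersects includes the boundary, so boundary centers are claimed
        # by the first (smallest-id) unit that reaches them.
        hit = shapely.intersects_xy(units[idx].polygon, flat_x[unassigned], flat_y[unassigned])
        target = np.flatnonzero(unassigned)[hit]
        member.ravel()[target] = idx
    return member


def _nearest_fill(
    fill_flat: np.ndarray,
    source_flat: np.ndarray,
    xs_flat: np.ndarray,
    ys_flat: np.ndarray,
    values_flat: np.ndarray,
    out_flat: np.ndarray,
    src_of: np.ndarray,
) -> None:
    """Fill cells ``fill_flat`` from the nearest of ``source_flat`` (flat
    indices), ties by smallest flat (row-major) index.  Mutates out/src_of."""
    if source_flat.size == 0 or fill_flat.size == 0:
        return
    pts_src = np.column_stack([xs_flat[source_flat], ys_flat[source_flat]])
    pts_fill = np.column_stack([xs_flat[fill_flat], ys_flat[fill_flat]])
    tree = cKDTree(pts_src)
    k = min(16, len(source_flat))
    dist, idx = tree.query(pts_fill, k=k)
    if k == 1:
        dist = dist[:, None]
        idx = idx[:, None]
    # among (near-)equidistant candidates take the smallest row-major index
    best = dist[:, 0]
    tied = dist <= best[:, None] * (1 + 1e-12) + 1e-12
    cand = np.where(tied, source_flat[idx], np.iinfo(np.int64).max)
    chosen = cand.min(axis=1)
    out_flat[fill_flat] = values_flat[chosen]
    src_of[fill_flat] = chosen


def seal_extrapolate(
    surface: DatumSurface,
    fine_units: list[WatershedUnit],
    coarse_units: list[WatershedUnit],
    return_sources: bool = False,
):
    """Extend a partially covered datum surface by watershed-sealed
    nearest-source allocation.  See the module docstring for semantics.

    With ``return_sources=True`` also returns the flat index of the source
    cell each filled cell took its value from (-1 for originally covered or
    still-nodata cells), so sealing can be audited.
    """
    if not fine_units or not coarse_units:
        raise ValueError("fine and coarse unit collections must be non-empty")
    for u in fine_units:
        if u.level != "fine":
            raise ValueError(f"unit {u.unit_id} passed as fine has level {u.level}")
    for u in coarse_units:
        if u.level != "coarse":
            raise ValueError(f"unit {u.unit_id} passed as coarse has level {u.level}")

    grid = surface.grid
    covered = surface.coverage_mask
    if not covered.any():
        raise ValueError("surface has no covered cells")

    xs, ys = grid.cell_centers()
    xs_flat, ys_flat = xs.ravel(), ys.ravel()
    values_flat = grid.values.ravel().astype(float)

    out = np.full(grid.shape, grid.nodata, dtype=float)
    out[covered] = grid.values[covered]
    out_flat = out.ravel()
    src_of = np.full(grid.values.size, -1, dtype=np.int64)

    fine_member = unit_membership(grid, fine_units)
    covered_flat = covered.ravel()

    # Pass 1: per fine unit with >=1 covered cell.
    for ui in range(len(fine_units)):
        in_unit = np.flatnonzero(fine_member.ravel() == ui)
        if in_unit.size == 0:
            continue
        src = in_unit[covered_flat[in_unit]]
        if src.size == 0:
            continue
        fill = in_unit[~covered_flat[in_unit]]
        _nearest_fill(fill, src, xs_flat, ys_flat, values_flat, out_flat, src_of)

    # Pass 2: per coarse unit with zero originally covered cells.
    coarse_member = unit_membership(grid, coarse_units)
    bearing_flat = out_flat != grid.nodata
    pass1_values = out_flat.copy()
    bearing_idx_all = np.flatnonzero(bearing_flat)
    for ui in range(len(coarse_units)):
        in_unit = np.flatnonzero(coarse_member.ravel() == ui)
        if in_unit.size == 0 or covered_flat[in_unit].any():
            continue
        fill = in_unit[~bearing_flat[in_unit]]
        src = in_unit[bearing_flat[in_unit]]
        if src.size == 0:
            src = bearing_idx_all
        _nearest_fill(fill, src, xs_flat, ys_flat, pass1_values, out_flat, src_of)

    result = DatumSurface(
        grid=grid.copy_with(out),
        coverage_mask=(out != grid.nodata),
    )
    if return_sources:
        return result, src_of.reshape(grid.shape)
    return result


def assemble_ex50(mhhw: DatumSurface, delta: RasterGrid) -> RasterGrid:
    """Cellwise EX50 = MHHW + (EX50 − MHHW) delta; nodata propagates.

    The output inherits the MHHW grid's vertical datum label, since adding
    the height-difference raster leaves the reference unchanged.
    """
    require_aligned(mhhw.grid, delta, "MHHW and delta rasters")
    m = mhhw.grid.values
    d = delta.values
    valid = (m != mhhw.grid.nodata) & (d != delta.nodata) & mhhw.coverage_mask
    out = np.full(m.shape, mhhw.grid.nodata, dtype=float)
    out[valid] = m[valid] + d[valid]
    return mhhw.grid.copy_with(out)
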