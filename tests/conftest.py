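import sys
from pathlib import Path

import numpy as np
import pytest
from shapely.geometry import box

sys.path.insert(0, str(Path(__file__).parent))  # for oracles.py

from ebeem.core import RasterGrid, WatershedUnit
from ebeem.surfaces import DatumSurface


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)


def make_grid(values, cell_size=10.0, origin_x=0.0, origin_y=None,
              nodata=-9999.0, datum="NAVD88"):
    values = np.asarray(values, dtype=float)
    if origin_y is None:
        origin_y = values.shape[0] * cell_size
    return RasterGrid(values, origin_x, origin_y, cell_size,
                      nodata=nodata, vertical_datum=datum)


def rect_unit(c0, r0, c1, r1, level, unit_id, grid):
    """Cell-index rectangle [c0,c1)x[r0,r1) as a watershed unit polygon."""
    cs = grid.cell_size
    return WatershedUnit(
        box(grid.origin_x + c0 * cs, grid.origin_y - r1 * cs,
            grid.origin_x + c1 * cs, grid.origin_y - r0 * cs),
        level, unit_id,
    )


def random_sealed_problem(rng, max_n=64):
    """A random two-level-unit sealed-extrapolation problem plus the
    cell-index rectangles its oracle needs."""
    nrow = int(rng.integers(8, max_n + 1))
    ncol = int(rng.integers(8, max_n + 1))
    values = rng.uniform(0.0, 3.0, size=(nrow, ncol))
    grid = make_grid(values)
    rbreak = int(rng.integers(2, nrow - 1))
    cbreak = int(rng.integers(2, ncol - 1))
    fine_rects = [(0, 0, cbreak, rbreak), (cbreak, 0, ncol, rbreak),
                  (0, rbreak, cbreak, nrow), (cbreak, rbreak, ncol, nrow)]
    coarse_rects = [(0, 0, cbreak, nrow), (cbreak, 0, ncol, nrow)]
    fine = [rect_unit(c0, r0, c1, r1, "fine", f"f{i}", grid)
            for i, (c0, r0, c1, r1) in enumerate(fine_rects)]
    coarse = [rect_unit(c0, r0, c1, r1, "coarse", f"c{i}", grid)
              for i, (c0, r0, c1, r1) in enumerate(coarse_rects)]
    covered = rng.random((nrow, ncol)) < 0.15
    if rng.random() < 0.5:
        covered[:, cbreak:] = False  # right coarse unit fully uncovered
    if not covered.any():
        covered[0, 0] = True
    masked = np.where(covered, values, grid.nodata)
    surface = DatumSurface(grid.copy_with(masked), covered)
    return surface, fine, coarse, fine_rects, coarse_rects, values, covered
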