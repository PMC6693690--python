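"""From surfaces to the Current and Historical Estuary Extent.

The extent is the land surface strictly below the 50%-exceedance elevation
(``dem − ex50 < 0``), polygonized from 4-connected components of the
threshold mask, then refined: qualifying tidal inventory polygons that fall
outside the contour are appended, seaward boundaries (mouth/jetty lines,
depth clips, shoreline clips) trim or bound the footprint, and supplied
override mappings (locally modeled river surfaces, manually delineated
lagoons) are merged with their own provenance.

4-connectivity is deliberate: 8-connectivity would merge diagonally touching
basins across levees, which is ecologically wrong here.  Equality with the
exceedance surface is excluded (strict ``< 0``).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional
import warnings

import numpy as np
import shapely
from scipy import ndimage
from shapely.geometry import LineString, Point, Polygon, box
from shapely.geometry.base import BaseGeometry
from shapely.ops import split as _split_geom

from .core import ExtentPolygon, NwiRecord, RasterGrid, require_aligned
from .surfaces import DatumSurface

__all__ = [
    "MouthLine",
    "DepthClip",
    "ShorelineClip",
    "mask_to_polygons",
    "threshold_extent",
    "threshold_mask",
    "append_nwi_tidal",
    "apply_seaward_boundary",
    "merge_overrides",
    "suggest_mouth_line",
    "total_area",
]


# ---------------------------------------------------------------------------
# Boundary specifications
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MouthLine:
    """A straight mouth (or jetty) line; its infinite extension splits the
    extent and the declared ``landward`` side ('left' or 'right' of the
    p1→p2 direction) is kept."""

    p1: tuple[float, float]
    p2: tuple[float, float]
    kind: str = "cusp_split"  # or "jetty"
    landward: str = "left"

    def __post_init__(self) -> None:
        if self.p1 == self.p2:
            raise ValueError("mouth line endpoints must differ")
        if self.kind not in ("cusp_split", "jetty"):
            raise ValueError(f"unknown mouth line kind {self.kind!r}")
        if self.landward not in ("left", "right"):
            raise ValueError("landward must be 'left' or 'right'")


@dataclass(frozen=True)
class DepthClip:
    """Remove extent where the bed lies deeper than ``depth_m`` below MLLW."""

    bathymetry: RasterGrid
    mllw: DatumSurface
    depth_m: float = 4.0


@dataclass(frozen=True)
class ShorelineClip:
    """Remove extent parts seaward of a shoreline path; the landward side is
    the side containing ``landward_point``."""

    path: "object"  # ShorelinePath
    landward_point: tuple[float, float]


# ---------------------------------------------------------------------------
# Mask polygonization
# ---------------------------------------------------------------------------

_STRUCTURE_4 = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=int)


def mask_to_polygons(mask: np.ndarray, grid: RasterGrid) -> list[BaseGeometry]:
    """Polygonize a boolean mask into one polygon per 4-connected component,
    with boundaries following cell edges.

    Built from per-row run rectangles unioned per component, so the total
    area equals ``cell_size**2 * mask.sum()`` exactly.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != grid.shape:
        raise ValueError("mask shape does not match grid")
    labels, n = ndimage.label(mask, structure=_STRUCTURE_4)
    cs = grid.cell_size
    polys: list[BaseGeometry] = []
    for comp in range(1, n + 1):
        rows, cols = np.nonzero(labels == comp)
        rects = []
        for r in np.unique(rows):
            cc = np.sort(cols[rows == r])
            # split into consecutive runs
            breaks = np.flatnonzero(np.diff(cc) > 1)
            starts = np.concatenate([[0], breaks + 1])
            ends = np.concatenate([breaks, [len(cc) - 1]])
            y_top = grid.origin_y - r * cs
            for s, e in zip(starts, ends):
                x0 = grid.origin_x + cc[s] * cs
                x1 = grid.origin_x + (cc[e] + 1) * cs
                rects.append(box(x0, y_top - cs, x1, y_top))
        polys.append(shapely.union_all(rects) if len(rects) > 1 else rects[0])
    return polys


def threshold_mask(dem: RasterGrid, ex50: RasterGrid) -> np.ndarray:
    """Boolean mask of cells strictly below the exceedance surface.

    Nodata in either raster excludes the cell.  Subtracting rasters in
    different vertical references is meaningless, so mismatched datum labels
    are an error.
    """
    require_aligned(dem, ex50, "DEM and EX50 rasters")
    if dem.vertical_datum != ex50.vertical_datum:
        raise ValueError(
            f"vertical datum mismatch: DEM is {dem.vertical_datum}, "
            f"EX50 is {ex50.vertical_datum}"
        )
    valid = dem.mask_valid & ex50.mask_valid
    diff = np.where(valid, dem.values - ex50.values, np.inf)
    return diff < 0.0


def threshold_extent(
    dem: RasterGrid, ex50: RasterGrid, estuary_id: str = ""
) -> list[ExtentPolygon]:
    """Threshold the DEM against the EX50 surface and polygonize."""
    mask = threshold_mask(dem, ex50)
    return [
        ExtentPolygon(polygon=p, provenance="below_ex50", estuary_id=estuary_id)
        for p in mask_to_polygons(mask, dem)
    ]


def total_area(extent: list[ExtentPolygon]) -> float:
    return float(sum(e.polygon.area for e in extent))


# ---------------------------------------------------------------------------
# Refinements
# ---------------------------------------------------------------------------

def nwi_qualifies_tidal(rec: NwiRecord) -> bool:
    """Append rule: every estuarine-system class qualifies, as do palustrine
    and riverine classes carrying one of the tidal water-regime letters
    (S, Q, R, T, V)."""
    if rec.system == "E":
        return True
    if rec.system in ("P", "R"):
        from .core import TIDAL_REGIME_LETTERS

        return rec.regime in TIDAL_REGIME_LETTERS
    return False


def append_nwi_tidal(
    extent: list[ExtentPolygon],
    nwi: list[NwiRecord],
    errors: Optional[list[str]] = None,
) -> list[ExtentPolygon]:
    """Append the parts of qualifying tidal inventory polygons lying outside
    the current extent, with provenance ``nwi_appended``.  Invalid geometries
    are skipped with a per-record report (collected into ``errors``)."""
    current = shapely.union_all([e.polygon for e in extent]) if extent else Polygon()
    out = list(extent)
    for rec in nwi:
        if rec.polygon is None:
            continue
        if not rec.polygon.is_valid or rec.polygon.is_empty:
            msg = f"invalid geometry for NWI record {rec.raw_code!r}; skipped"
            if errors is not None:
                errors.append(msg)
            warnings.warn(msg, stacklevel=2)
            continue
        if not nwi_qualifies_tidal(rec):
            continue
        outside = rec.polygon.difference(current)
        if not outside.is_empty and outside.area > 0:
            out.append(
                ExtentPolygon(polygon=outside, provenance="nwi_appended",
                              estuary_id=rec.estuary_id)
            )
    return out


def _halfplane(line: MouthLine, bounds: tuple[float, float, float, float]) -> Polygon:
    """Large polygon covering the landward side of the line's infinite
    extension, big enough to clip anything within ``bounds``."""
    (x1, y1), (x2, y2) = line.p1, line.p2
    dx, dy = x2 - x1, y2 - y1
    norm = float(np.hypot(dx, dy))
    ux, uy = dx / norm, dy / norm
    # left normal of p1->p2
    nx, ny = -uy, ux
    if line.landward == "right":
        nx, ny = -nx, -ny
    minx, miny, maxx, maxy = bounds
    diag = float(np.hypot(maxx - minx, maxy - miny)) + norm
    big = 4.0 * max(diag, 1.0)
    a = (x1 - ux * big, y1 - uy * big)
    b = (x1 + ux * big, y1 + uy * big)
    return Polygon([a, b, (b[0] + nx * big, b[1] + ny * big),
                    (a[0] + nx * big, a[1] + ny * big)])


def apply_seaward_boundary(
    extent: list[ExtentPolygon], boundary
) -> list[ExtentPolygon]:
    """Trim the extent at its seaward edge.

    ``boundary`` is a :class:`MouthLine` (keep the declared landward side of
    the line's infinite extension), a :class:`DepthClip` (drop cells with bed
    elevation below MLLW − depth_m), or a :class:`ShorelineClip` (drop parts
    seaward of the path).  A mouth line that does not cross the extent leaves
    it unchanged with a warning.  Trimming never adds area.
    """
    if isinstance(boundary, MouthLine):
        union = shapely.union_all([e.polygon for e in extent]) if extent else Polygon()
        if union.is_empty:
            return list(extent)
        hp = _halfplane(boundary, union.bounds)
        infinite_line = LineString(list(hp.exterior.coords)[:2])
        if not infinite_line.intersects(union):
            warnings.warn("mouth line does not intersect the extent; unchanged",
                          stacklevel=2)
            return list(extent)
        out = []
        for e in extent:
            clipped = e.polygon.intersection(hp)
            if not clipped.is_empty and clipped.area > 0:
                out.append(ExtentPolygon(polygon=clipped, provenance=e.provenance,
                                         estuary_id=e.estuary_id))
        return out

    if isinstance(boundary, DepthClip):
        bathy = boundary.bathymetry
        require_aligned(bathy, boundary.mllw.grid, "bathymetry and MLLW rasters")
        valid = bathy.mask_valid & boundary.mllw.grid.mask_valid & boundary.mllw.coverage_mask
        remove = np.zeros(bathy.shape, dtype=bool)
        remove[valid] = bathy.values[valid] < (
            boundary.mllw.grid.values[valid] - boundary.depth_m
        )
        if not remove.any():
            return list(extent)
        remove_geom = shapely.union_all(mask_to_polygons(remove, bathy))
        out = []
        for e in extent:
            kept = e.polygon.difference(remove_geom)
            if not kept.is_empty and kept.area > 0:
                out.append(ExtentPolygon(polygon=kept, provenance=e.provenance,
                                         estuary_id=e.estuary_id))
        return out

    if isinstance(boundary, ShorelineClip):
        from shapely.ops import split as shp_split

        from .exceedance import _shoreline_geometry

        line = _shoreline_geometry(boundary.path)
        lp = Point(boundary.landward_point)
        out = []
        for e in extent:
            pieces = []
            try:
                parts = shp_split(e.polygon, line).geoms
            except Exception:
                parts = [e.polygon]
            for piece in parts:
                rp = piece.representative_point()
                # crossing parity of the segment rep-point -> landward point
                seg = LineString([rp, lp])
                inter = seg.intersection(line)
                if inter.is_empty:
                    crossings = 0
                elif inter.geom_type == "Point":
                    crossings = 1
                else:
                    crossings = len(getattr(inter, "geoms", [inter]))
                if crossings % 2 == 0:
                    pieces.append(piece)
            if pieces:
                kept = shapely.union_all(pieces)
                if not kept.is_empty and kept.area > 0:
                    out.append(ExtentPolygon(polygon=kept, provenance=e.provenance,
                                             estuary_id=e.estuary_id))
        return out

    raise TypeError(f"unsupported boundary specification {type(boundary)!r}")


def merge_overrides(
    extent: list[ExtentPolygon],
    overrides: list[BaseGeometry],
    provenance: str,
    estuary_id: str = "",
) -> list[ExtentPolygon]:
    """Union supplied override mapping into the extent; in overlaps the
    override provenance wins.  Never removes area."""
    if provenance not in ("regional_override", "lagoon_supplied"):
        raise ValueError(f"override provenance must be regional_override or "
                         f"lagoon_supplied, got {provenance!r}")
    for g in overrides:
        if not g.is_valid or g.is_empty:
            raise ValueError("invalid override geometry")
    if not overrides:
        return list(extent)
    override_union = shapely.union_all(list(overrides))
    out = []
    for e in extent:
        remainder = e.polygon.difference(override_union)
        if not remainder.is_empty and remainder.area > 0:
            out.append(ExtentPolygon(polygon=remainder, provenance=e.provenance,
                                     estuary_id=e.estuary_id))
    out.append(ExtentPolygon(polygon=override_union, provenance=provenance,
                             estuary_id=estuary_id))
    return out


def suggest_mouth_line(
    polygon: BaseGeometry, n_boundary: int = 200, min_side_frac: float = 0.05
) -> Optional[MouthLine]:
    """Suggest the narrowest cross-section chord of a polygon as a candidate
    mouth line (manual placement remains the authoritative input).

    Scans ``n_boundary`` evenly spaced boundary points for the shortest
    interior chord splitting off at least ``min_side_frac`` of the area.
    """
    ring = polygon.exterior if hasattr(polygon, "exterior") else polygon.boundary
    L = ring.length
    pts = [ring.interpolate(i * L / n_boundary) for i in range(n_boundary)]
    best = None
    best_len = np.inf
    for i in range(n_boundary):
        for j in range(i + 2, n_boundary):
            a, b = pts[i], pts[j]
            d = a.distance(b)
            if d >= best_len or d == 0:
                continue
            chord = LineString([a, b])
            if not chord.within(polygon.buffer(1e-9)):
                continue
            halves = _split_geom(polygon, chord)
            areas = sorted(g.area for g in halves.geoms)
            if len(areas) >= 2 and areas[0] >= min_side_frac * polygon.area:
                best_len = d
                best = MouthLine(p1=(a.x, a.y), p2=(b.x, b.y), kind="cusp_split")
    return best
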