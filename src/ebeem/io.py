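"""Plain-text layer readers and writers.

Rasters travel as ESRI ASCII grids (``.asc``) with a JSON sidecar
(``<name>.asc.json``) carrying the vertical-datum label; vector layers as
GeoJSON FeatureCollections; gauge tables and attribute tables as CSV.  All
writers are deterministic (fixed float formatting, sorted keys) so that
re-running a stage on identical inputs reproduces byte-identical files.

Every layer is expected to share one projected planar coordinate reference
in meters; these functions neither reproject nor check CRS metadata.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import mapping, shape
from shapely.geometry.base import BaseGeometry

from .core import (
    EstuaryUnit,
    NwiRecord,
    RasterGrid,
    ShorelinePath,
    TideGaugeRecord,
    WatershedUnit,
    parse_nwi_code,
)
from .surfaces import DatumSurface

__all__ = [
    "write_raster", "read_raster", "write_mask", "read_mask",
    "write_features", "read_features",
    "write_gauges", "read_gauges",
    "write_nwi", "read_nwi",
    "write_units", "read_units",
    "write_estuaries", "read_estuaries",
    "write_shoreline", "read_shoreline",
]


# ---------------------------------------------------------------------------
# Rasters (ESRI ASCII grid + sidecar)
# ---------------------------------------------------------------------------

def write_raster(grid: RasterGrid, path) -> None:
    path = Path(path)
    nrow, ncol = grid.shape
    yll = grid.origin_y - nrow * grid.cell_size
    lines = [
        f"ncols {ncol}",
        f"nrows {nrow}",
        f"xllcorner {grid.origin_x!r}",
        f"yllcorner {yll!r}",
        f"cellsize {grid.cell_size!r}",
        f"NODATA_value {grid.nodata!r}",
    ]
    body = "\n".join(" ".join(repr(float(v)) for v in row) for row in grid.values)
    path.write_text("\n".join(lines) + "\n" + body + "\n")
    sidecar = {"vertical_datum": grid.vertical_datum}
    Path(str(path) + ".json").write_text(json.dumps(sidecar, sort_keys=True) + "\n")


def read_raster(path, assume_datum: Optional[str] = None) -> RasterGrid:
    path = Path(path)
    text = path.read_text().splitlines()
    header = {}
    i = 0
    while i < len(text):
        parts = text[i].split()
        if len(parts) == 2 and parts[0].lower() in (
            "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value"
        ):
            header[parts[0].lower()] = float(parts[1])
            i += 1
        else:
            break
    values = np.loadtxt(text[i:], dtype=float, ndmin=2)
    nrow, ncol = int(header["nrows"]), int(header["ncols"])
    if values.shape != (nrow, ncol):
        raise ValueError(f"{path}: grid body shape {values.shape} does not match header")
    cell = header["cellsize"]
    sidecar_path = Path(str(path) + ".json")
    if sidecar_path.exists():
        datum = json.loads(sidecar_path.read_text())["vertical_datum"]
    elif assume_datum is not None:
        datum = assume_datum
    else:
        raise ValueError(
            f"{path}: no vertical-datum sidecar; pass assume_datum to override"
        )
    return RasterGrid(
        values=values,
        origin_x=header["xllcorner"],
        origin_y=header["yllcorner"] + nrow * cell,
        cell_size=cell,
        nodata=header.get("nodata_value", -9999.0),
        vertical_datum=datum,
    )


def write_mask(mask: np.ndarray, template: RasterGrid, path) -> None:
    """0/1 byte-style mask sharing the template's georeferencing."""
    grid = RasterGrid(mask.astype(float), template.origin_x, template.origin_y,
                      template.cell_size, nodata=-9999.0, vertical_datum="NONE")
    write_raster(grid, path)


def read_mask(path) -> tuple[np.ndarray, RasterGrid]:
    grid = read_raster(path, assume_datum="NONE")
    return grid.values > 0.5, grid


# ---------------------------------------------------------------------------
# Vector features (GeoJSON)
# ---------------------------------------------------------------------------

def write_features(geoms_props: list[tuple[BaseGeometry, dict]], path) -> None:
    features = []
    for geom, props in geoms_props:
        features.append({
            "type": "Feature",
            "geometry": mapping(geom),
            "properties": props,
        })
    fc = {"type": "FeatureCollection", "features": features}
    Path(path).write_text(json.dumps(fc, sort_keys=True) + "\n")


def read_features(path) -> list[tuple[BaseGeometry, dict]]:
    fc = json.loads(Path(path).read_text())
    if fc.get("type") != "FeatureCollection":
        raise ValueError(f"{path}: not a FeatureCollection")
    return [(shape(f["geometry"]), f.get("properties") or {})
            for f in fc["features"]]


# ---------------------------------------------------------------------------
# Specific layers
# ---------------------------------------------------------------------------

def write_gauges(gauges: list[TideGaugeRecord], path) -> None:
    pd.DataFrame([{
        "gauge_id": g.gauge_id, "x": g.x, "y": g.y,
        "ex50_above_mhhw": g.ex50_above_mhhw,
        "mhhw_above_reference": g.mhhw_above_reference,
        "epoch": g.epoch,
    } for g in gauges]).to_csv(path, index=False)


def read_gauges(path) -> list[TideGaugeRecord]:
    df = pd.read_csv(path)
    out = []
    for _, r in df.iterrows():
        m = r.get("mhhw_above_reference")
        out.append(TideGaugeRecord(
            gauge_id=str(r["gauge_id"]), x=float(r["x"]), y=float(r["y"]),
            ex50_above_mhhw=float(r["ex50_above_mhhw"]),
            mhhw_above_reference=None if pd.isna(m) else float(m),
            epoch="" if pd.isna(r.get("epoch")) else str(r["epoch"]),
        ))
    return out


def write_nwi(records: list[NwiRecord], path) -> None:
    write_features(
        [(r.polygon, {"ATTRIBUTE": r.raw_code, "estuary_id": r.estuary_id})
         for r in records if r.polygon is not None],
        path,
    )


def read_nwi(path) -> list[NwiRecord]:
    out = []
    for geom, props in read_features(path):
        rec = parse_nwi_code(props["ATTRIBUTE"])
        out.append(rec.with_geometry(geom, estuary_id=props.get("estuary_id", "")))
    return out


def write_units(units: list[WatershedUnit], path) -> None:
    write_features(
        [(u.polygon, {"unit_id": u.unit_id, "level": u.level}) for u in units],
        path,
    )


def read_units(path) -> list[WatershedUnit]:
    return [WatershedUnit(geom, props["level"], props["unit_id"])
            for geom, props in read_features(path)]


def write_estuaries(estuaries: list[EstuaryUnit], path) -> None:
    pd.DataFrame([{
        "estuary_id": e.estuary_id, "name": e.name, "ecoregion": e.ecoregion,
        "phys_type": e.phys_type, "historical_area_ha": e.historical_area_ha,
    } for e in estuaries]).to_csv(path, index=False)


def read_estuaries(path) -> list[EstuaryUnit]:
    df = pd.read_csv(path)
    return [EstuaryUnit(
        estuary_id=str(r["estuary_id"]), name=str(r["name"]),
        ecoregion=str(r["ecoregion"]), phys_type=str(r["phys_type"]),
        historical_area_ha=float(r["historical_area_ha"]),
    ) for _, r in df.iterrows()]


def write_shoreline(paths: list[ShorelinePath], path) -> None:
    feats = []
    for sp in paths:
        for part in sp.parts:
            feats.append((shapely.LineString(part),
                          {"roles": ",".join(sorted(sp.roles))}))
    write_features(feats, path)


def read_shoreline(path) -> list[ShorelinePath]:
    out = []
    for geom, props in read_features(path):
        roles = tuple(x for x in props.get("roles", "").split(",") if x)
        out.append(ShorelinePath.from_coords(list(geom.coords), roles=roles))
    return out
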