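"""Self-contained synthetic coastal worlds with known truth.

The generator builds everything the pipeline consumes — bare-earth DEM,
stationing shoreline, tide gauges, MHHW datum surface with a coverage mask,
two-level watershed units, coded wetland parcels with planted dikes — from a
closed-form construction, so every stage can be tested against exact truth
without external data.

Geometry (coast on the west edge, rows north→south):

* an ocean strip, a fringing along-shore marsh band, and ``n_estuaries``
  river valleys whose floors dip below the analytic EX50 surface and rise
  inland at ``valley_slope`` until the estuary head;
* the true EX50 surface is analytic: a constant MHHW plane plus an
  along-shore EX50−MHHW delta cline between the gauge values (``full``
  coverage mode), or per-watershed-unit-constant MHHW plus a constant
  0.5 m delta with coverage truncated upriver (``truncated`` mode, which
  exercises the sealed extrapolation including its coarse-unit pass);
* the DEM is the true EX50 surface plus a relief field whose cell-center
  values are pushed outside a ±``margin_m`` band around zero, so the
  true wet/dry decision at every cell is robust to interpolation error
  smaller than the margin — exact-surface recovery is then a property of
  the method, not of floating-point luck;
* parcels tile the wet area in row-major block order; each is coded with a
  Cowardin-style string.  Diked parcels get a nontidal regime plus the ``h``
  modifier and form the planted lost set; a fraction of blocks is left
  without a parcel and is upland truth (lost); the ocean is one
  unvegetated subtidal record (excluded truth).

A single seeded pseudo-random stream drives all stochastic choices, drawn
in documented order (per block, row-major: upland? → diked? → retained code
index), so a draw-by-draw replay reproduces the truth labels exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import box

from .core import (
    EstuaryUnit,
    NwiRecord,
    RasterGrid,
    ShorelinePath,
    TideGaugeRecord,
    WatershedUnit,
    parse_nwi_code,
)
from .extent import mask_to_polygons
from .surfaces import DatumSurface

__all__ = ["FixtureSpec", "FixtureTruth", "FixtureBundle", "generate_fixture",
           "evaluate_recovery"]

#: Cowardin codes used for retained (vegetated tidal, not disconnected) parcels.
RETAINED_CODES = ("E2EM1N", "PFO1T", "PSS1R", "E2EM1P")
DIKED_CODE = "PEM1Ch"
OCEAN_CODE = "E1UBL"


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of the synthetic coastal world.

    The EX50 cline endpoints default to the observed coast-wide range
    (2.1 m at the southern end to 3.4 m at the northern end), expressed as
    gauge deltas above the MHHW baseline plane; the truncated-coverage mode
    instead uses the typical constant 0.5 m EX50−MHHW offset.
    """

    shape: tuple[int, int] = (256, 256)
    cell_size: float = 10.0
    coast_orientation: str = "west"
    n_estuaries: int = 3
    mhhw_plane: float = 1.7
    gauge_deltas: Optional[tuple[float, float]] = None  # (north, south)
    valley_slope: float = 0.0008  # m/m rise of valley floor inland
    diked_fraction: float = 0.3
    upland_fraction: float = 0.1
    margin_m: float = 0.1
    coverage: str = "full"  # or "truncated"
    parcel_block_cells: int = 16
    seed: int = 0

    def __post_init__(self) -> None:
        if self.coast_orientation != "west":
            raise ValueError("only a west-facing coast is supported")
        if not (0 <= self.diked_fraction <= 1):
            raise ValueError("diked_fraction must be in [0, 1]")
        if not (0 <= self.upland_fraction <= 1):
            raise ValueError("upland_fraction must be in [0, 1]")
        if self.coverage not in ("full", "truncated"):
            raise ValueError("coverage must be 'full' or 'truncated'")
        if min(self.shape) < 32:
            raise ValueError("grid must be at least 32x32")
        if self.cell_size <= 0 or self.margin_m <= 0 or self.valley_slope < 0:
            raise ValueError("cell_size, margin_m must be > 0; valley_slope >= 0")

    @property
    def resolved_gauge_deltas(self) -> tuple[float, float]:
        if self.gauge_deltas is not None:
            return self.gauge_deltas
        if self.coverage == "truncated":
            return (0.5, 0.5)
        return (3.4 - self.mhhw_plane, 2.1 - self.mhhw_plane)


@dataclass
class FixtureTruth:
    true_extent_mask: np.ndarray  # DEM < true EX50, by construction
    true_labels: pd.DataFrame  # parcel_id, raw_code, label, estuary_id
    ex50_true: RasterGrid
    upland_block_ids: list[str] = field(default_factory=list)


@dataclass
class FixtureBundle:
    spec: FixtureSpec
    dem: RasterGrid
    mhhw: DatumSurface
    gauges: list[TideGaugeRecord]
    shoreline: ShorelinePath
    barriers: list  # shapely polygons
    barrier_mask: np.ndarray
    fine_units: list[WatershedUnit]
    coarse_units: list[WatershedUnit]
    nwi: list[NwiRecord]
    estuaries: list[EstuaryUnit]
    truth: FixtureTruth


def _band_edges(nrow: int, n: int) -> list[tuple[int, int]]:
    """Row ranges [start, stop) of the n valley bands."""
    edges = np.linspace(0, nrow, n + 1).astype(int)
    return [(int(edges[k]), int(edges[k + 1])) for k in range(n)]


def generate_fixture(spec: FixtureSpec) -> FixtureBundle:
    """Build a fixture bundle plus its truth; deterministic in the seed."""
    nrow, ncol = spec.shape
    cs = spec.cell_size
    origin_x, origin_y = 0.0, nrow * cs
    rng = np.random.default_rng(spec.seed)

    c_coast = max(8, ncol // 8)
    c_fringe = c_coast + max(4, ncol // 32)
    c_q, c_mid, c_3q = ncol // 4, ncol // 2, 3 * ncol // 4
    c_cov = (c_q + c_mid) // 2  # coverage ends between the 1st and 2nd quarter

    rows = np.arange(nrow)[:, None].astype(float)
    cols = np.arange(ncol)[None, :].astype(float)
    bands = _band_edges(nrow, spec.n_estuaries)

    # --- analytic MHHW and delta -------------------------------------------
    d_north, d_south = spec.resolved_gauge_deltas
    if spec.coverage == "full":
        mhhw_true = np.full((nrow, ncol), spec.mhhw_plane)
        frac = rows / max(nrow - 1, 1)
        delta_true = (d_north + (d_south - d_north) * frac) * np.ones((1, ncol))
        coverage = np.ones((nrow, ncol), dtype=bool)
    else:
        mhhw_true = np.empty((nrow, ncol))
        for k, (r0, r1) in enumerate(bands):
            m_k = spec.mhhw_plane + 0.05 * k
            mhhw_true[r0:r1, :c_mid] = m_k
            mhhw_true[r0:r1, c_mid:] = m_k + 0.15
        delta_true = np.full((nrow, ncol), d_north)
        coverage = np.zeros((nrow, ncol), dtype=bool)
        coverage[:, :c_cov] = True
    delta_true = np.broadcast_to(delta_true, (nrow, ncol)).copy()
    ex50_true_vals = mhhw_true + delta_true

    # --- relief field and margin push --------------------------------------
    f = np.full((nrow, ncol), 2.0)
    # fringing along-shore band
    fringe = -0.5 + 1.3 * (cols - c_coast) / max(c_fringe - c_coast - 1, 1)
    in_fringe = (cols >= c_coast) & (cols < c_fringe)
    f = np.where(in_fringe & np.ones((nrow, 1), dtype=bool), fringe, f)
    # river valleys
    half_w = max(nrow // (spec.n_estuaries * 6), 4)
    u_min = np.full((nrow, ncol), np.inf)
    for r0, r1 in bands:
        r_c = (r0 + r1 - 1) / 2.0
        u = np.abs(rows - r_c) / half_w
        floor = -0.8 + spec.valley_slope * np.maximum(cols - c_fringe, 0.0) * cs + 1.5 * u ** 2
        inland = cols >= c_coast
        f = np.where(inland & (floor < f), floor, f)
        u_min = np.minimum(u_min, np.broadcast_to(u, (nrow, ncol)))
    f = np.minimum(f, 2.0)
    f[:, :c_coast] = -1.5  # ocean
    # push cell-center values out of the +/- margin band
    small = np.abs(f) < spec.margin_m
    f = np.where(small, np.where(f < 0, -spec.margin_m, spec.margin_m), f)

    dem_vals = ex50_true_vals + f
    true_mask = f < 0.0

    dem = RasterGrid(dem_vals, origin_x, origin_y, cs, vertical_datum="NAVD88")
    mhhw_vals = np.where(coverage, mhhw_true, -9999.0)
    mhhw = DatumSurface(
        grid=RasterGrid(mhhw_vals, origin_x, origin_y, cs, vertical_datum="NAVD88"),
        coverage_mask=coverage,
    )
    ex50_true = RasterGrid(ex50_true_vals, origin_x, origin_y, cs,
                           vertical_datum="NAVD88")

    # --- shoreline and gauges ----------------------------------------------
    x_shore = origin_x + (c_coast + 0.5) * cs
    y_top = origin_y - 0.5 * cs
    y_bot = origin_y - (nrow - 0.5) * cs
    shoreline = ShorelinePath.from_coords(
        [(x_shore, y_top), (x_shore, y_bot)], roles=("stationing",)
    )
    gauge_rows = [0, nrow // 2, nrow - 1]
    gauges = []
    frac = np.array(gauge_rows) / max(nrow - 1, 1)
    for i, (r, fr) in enumerate(zip(gauge_rows, frac)):
        gauges.append(TideGaugeRecord(
            gauge_id=f"g{i}",
            x=x_shore,
            y=origin_y - (r + 0.5) * cs,
            ex50_above_mhhw=float(d_north + (d_south - d_north) * fr),
            mhhw_above_reference=float(spec.mhhw_plane),
            epoch="1983-2001",
        ))

    # --- barriers: inter-valley ridges, cell-aligned, edge-shrunk ----------
    barrier_rows = u_min[:, 0] > 1.3  # same for every inland column
    barriers = []
    eps = 0.01 * cs
    x_b0 = origin_x + (c_fringe + 2) * cs
    r = 0
    while r < nrow:
        if barrier_rows[r]:
            r_start = r
            while r < nrow and barrier_rows[r]:
                r += 1
            barriers.append(box(
                x_b0 + eps, origin_y - r * cs + eps,
                origin_x + ncol * cs - eps, origin_y - r_start * cs - eps,
            ))
        else:
            r += 1
    barrier_mask = np.zeros((nrow, ncol), dtype=bool)
    barrier_mask[barrier_rows, c_fringe + 2:] = True

    # --- watershed units ----------------------------------------------------
    fine_units, coarse_units = [], []
    for k, (r0, r1) in enumerate(bands):
        y0 = origin_y - r1 * cs
        y1 = origin_y - r0 * cs
        col_breaks_fine = [0, c_q, c_mid, c_3q, ncol]
        for j in range(4):
            x0 = origin_x + col_breaks_fine[j] * cs
            x1 = origin_x + col_breaks_fine[j + 1] * cs
            fine_units.append(WatershedUnit(box(x0, y0, x1, y1), "fine",
                                            f"f{k}{j}"))
        for j, (ca, cb) in enumerate([(0, c_mid), (c_mid, ncol)]):
            x0 = origin_x + ca * cs
            x1 = origin_x + cb * cs
            coarse_units.append(WatershedUnit(box(x0, y0, x1, y1), "coarse",
                                              f"c{k}{j}"))

    # --- parcels ------------------------------------------------------------
    def band_of_row(r: int) -> int:
        for k, (r0, r1) in enumerate(bands):
            if r0 <= r < r1:
                return k
        return len(bands) - 1

    pb = spec.parcel_block_cells
    land_wet = true_mask.copy()
    land_wet[:, :c_coast] = False
    nwi: list[NwiRecord] = []
    truth_rows = []
    upland_blocks: list[str] = []
    pid = 0
    for br in range(0, nrow, pb):
        for bc in range(c_coast, ncol, pb):
            block = np.zeros((nrow, ncol), dtype=bool)
            block[br:br + pb, bc:bc + pb] = land_wet[br:br + pb, bc:bc + pb]
            if not block.any():
                continue
            parcel_id = f"p{pid:04d}"
            pid += 1
            est = f"est{band_of_row(br + pb // 2)}"
            # documented draw order: upland? -> diked? -> retained code index
            if rng.random() < spec.upland_fraction:
                upland_blocks.append(parcel_id)
                truth_rows.append({"parcel_id": parcel_id, "raw_code": "UPL",
                                   "label": "lost", "estuary_id": est})
                continue
            if rng.random() < spec.diked_fraction:
                code, label = DIKED_CODE, "lost"
            else:
                code = RETAINED_CODES[int(rng.integers(len(RETAINED_CODES)))]
                label = "retained"
            geom = shapely.union_all(mask_to_polygons(block, dem))
            rec = parse_nwi_code(code).with_geometry(geom, estuary_id=est)
            nwi.append(rec)
            truth_rows.append({"parcel_id": parcel_id, "raw_code": code,
                               "label": label, "estuary_id": est})

    ocean_mask = np.zeros((nrow, ncol), dtype=bool)
    ocean_mask[:, :c_coast] = True
    ocean_geom = shapely.union_all(mask_to_polygons(ocean_mask, dem))
    nwi.append(parse_nwi_code(OCEAN_CODE).with_geometry(ocean_geom, estuary_id="est0"))
    truth_rows.append({"parcel_id": "ocean", "raw_code": OCEAN_CODE,
                       "label": "excluded", "estuary_id": "est0"})

    # --- estuary metadata ----------------------------------------------------
    ha = cs * cs / 10_000.0
    estuaries = []
    for k, (r0, r1) in enumerate(bands):
        area = float(true_mask[r0:r1, c_coast:].sum()) * ha
        estuaries.append(EstuaryUnit(
            estuary_id=f"est{k}", name=f"Synthetic estuary {k}",
            ecoregion="WA/OR/N.CA", phys_type="riverine",
            historical_area_ha=area,
        ))
    # metadata-only systems exercising the scope filters
    estuaries.append(EstuaryUnit("lagoon0", "Synthetic lagoon", "Central CA",
                                 "lagoon", 5000.0))
    estuaries.append(EstuaryUnit("tiny0", "Synthetic small estuary",
                                 "S.CA Bight", "riverine", 90.0))

    truth = FixtureTruth(
        true_extent_mask=true_mask,
        true_labels=pd.DataFrame(truth_rows, columns=["parcel_id", "raw_code",
                                                      "label", "estuary_id"]),
        ex50_true=ex50_true,
        upland_block_ids=upland_blocks,
    )
    return FixtureBundle(
        spec=spec, dem=dem, mhhw=mhhw, gauges=gauges, shoreline=shoreline,
        barriers=barriers, barrier_mask=barrier_mask, fine_units=fine_units,
        coarse_units=coarse_units, nwi=nwi, estuaries=estuaries, truth=truth,
    )


def evaluate_recovery(predicted_mask: np.ndarray, truth: FixtureTruth,
                      predicted_labels: Optional[pd.DataFrame] = None) -> dict:
    """Score a predicted extent (and optionally parcel labels) against truth.

    IoU = |pred ∧ true| / |pred ∨ true|; the confusion table counts parcels
    by (true label, predicted label).
    """
    pred = np.asarray(predicted_mask, dtype=bool)
    if pred.shape != truth.true_extent_mask.shape:
        raise ValueError("predicted mask shape does not match truth")
    inter = int((pred & truth.true_extent_mask).sum())
    union = int((pred | truth.true_extent_mask).sum())
    report = {
        "iou": (inter / union) if union else 1.0,
        "n_pred": int(pred.sum()),
        "n_true": int(truth.true_extent_mask.sum()),
    }
    if predicted_labels is not None:
        merged = truth.true_labels.merge(
            predicted_labels[["parcel_id", "label"]].rename(
                columns={"label": "predicted"}),
            on="parcel_id", how="inner",
        )
        confusion: dict[tuple[str, str], int] = {}
        for _, row in merged.iterrows():
            key = (row["label"], row["predicted"])
            confusion[key] = confusion.get(key, 0) + 1
        report["confusion"] = confusion
        report["n_label_mismatch"] = int((merged["label"] != merged["predicted"]).sum())
    return report
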