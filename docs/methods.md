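# Methods

## Model and assumptions

The package maps the current-plus-historical extent of an estuary as the
land surface strictly below the 50%-exceedance annual-high-tide elevation
(EX50), and then assesses tidal-wetland loss indirectly by comparing that
footprint against a current wetland inventory.  The underlying assumptions:

* **EX50 is the upslope wetland boundary.** The elevation exceeded in half
  of all years (≈ a two-year return high water) marks the maximum extent of
  regular tidal inundation.  Field validation in the source region placed
  vegetated tidal wetlands between MHHW and EX50, with EX50 typically about
  0.5 m above MHHW.
* **A bathtub threshold is adequate.** Cells are classified independently
  by `DEM − EX50 < 0` (strict; ties excluded).  No hydrologic connectivity
  test is applied at thresholding time — diked areas *should* appear below
  the surface, since the historical footprint is the target.
* **The inventory's tidal coding is conservative.** Inventory polygons
  labeled tidal are trusted (appended to the extent when outside the
  contour; counted retained when inside and vegetated/connected).

## Pipeline stages and numerical choices

### Along-shore interpolation of the EX50−MHHW offset

Gauges are projected to arc-length stations on a stationing shoreline
(nearest-point projection; gauges farther than a 50 km snap tolerance warn
but are retained).  Between stations the offset is piecewise linear;
beyond the terminal gauges it is clamped to the terminal values rather than
extrapolated, because the offset is a bounded physical quantity.  The
"relative distance to the nearest gauges" reading adopted here is
along-shore (station-space) blending, not straight-line blending across
water bodies or headlands.

### Inland spreading with barriers

The named proprietary barrier-spline tool has no published algorithm, so
the package uses a documented interpolator with the same contract: barrier
cells are impassable, sample cells reproduce their values exactly, and
every other cell gets an inverse-distance-weighted (power 2, default k = 8
neighbors) combination of its nearest *reachable* samples, with distance
measured as the shortest path over the 8-connected cell graph (diagonal
steps cost √2·cell, and may not cut the corner between two orthogonally
adjacent barrier cells).  Cells with no reachable sample are nodata.
Samples are seeded one per cell the stationing path crosses, valued by the
along-shore interpolation at the crossing station.  The choice is
reproducible and oracle-checkable; the downstream threshold depends only on
a smooth, plausible field, not on spline-specific curvature.

### Watershed-sealed datum extrapolation

Datum-surface coverage typically ends partway up rivers.  Uncovered cells
are filled by nearest-source (Euclidean allocation) search constrained by
watershed units:

* **Pass 1** runs per *fine* unit containing at least one covered cell;
  each uncovered cell in the unit takes the value of the nearest covered
  cell **in the same unit** (cell-center Euclidean distance in projected
  meters, so anisotropic grids behave; ties broken by smallest row-major
  source index).
* **Pass 2** runs per *coarse* unit that contained no covered cell at all,
  extending the analysis extent using the value-bearing cells after Pass 1
  as sources — within the coarse unit when any exist there, otherwise the
  nearest value-bearing cell anywhere in the domain.  (Under strict
  fine-within-coarse nesting a wholly uncovered coarse unit cannot contain
  Pass-1 fills, so a literal within-unit source rule would make Pass 2
  inert; the domain-wide fallback is what "extend the analysis extent from
  the previous step's values" requires.)

Cells in no unit stay nodata.  A cell belongs to the unit containing its
center; centers exactly on a shared boundary go to the unit with the
smaller id (units are visited in ascending unit-id order).  The operation
is idempotent and never invents values.

### Extent refinement

Thresholded masks are polygonized from 4-connected components (8-
connectivity would merge diagonally touching basins across levees), with
boundaries following cell edges, so total polygon area equals
cell_size² × cell count exactly.  No minimum mapping unit is applied by
default (`mmu_ha` is available and off).  Qualifying inventory polygons —
estuarine system, or palustrine/riverine with water regime in {S, Q, R, T,
V} — are appended where they fall outside the contour.  Seaward boundaries:
a user-declared mouth or jetty line (the landward side is a declared flag,
'left'/'right' of the line direction, never inferred; a helper suggests the
narrowest-cross-section chord but placement is the user's), a depth clip
removing beds deeper than 4 m below MLLW (the seaward limit of the
estuarine coastal subsystem in the federal classification standard), or a
shoreline clip.  Supplied override mappings (locally modeled river
surfaces, manually delineated lagoons) are unioned in; override provenance
wins in overlaps.

### Loss classification

The decision table over (system, vegetated, tidal regime,
diked/drained/farmed) reduces to a compact predicate, verified exhaustively
against a literal transcription of the printed table:

* excluded — marine system, or unvegetated-tidal-connected;
* retained — vegetated, tidal, connected;
* lost — everything else, including upland (extent with no inventory
  polygon, represented by a reserved NONE system so the classifier is
  total).

Estuarine and marine systems are always treated as tidal regimes; the
S/Q/R/T/V list applies only to the palustrine, riverine, and lacustrine
systems (the printed table leaves estuarine nontidal cells blank, which
supports this).  "Diked/drained/farmed" is operationalized as special
modifiers {h, d, f}; any one suffices.  Attribute combinations the printed
table leaves blank follow the predicate and are flagged `rule_gap` in the
label's reason string and the stage log.  Subsystem and subclass digits are
parsed and kept but never consulted.

Scope filters: lagoonal estuaries are excluded (their maximum water levels
may be set by mouth closure, not tides) as are estuaries of ≤ 100 ha
historical area (inventory mapping scale inadequate).  Percent loss uses
`lost / (lost + retained)`; excluded area never enters the denominator.
Percentages are rounded half-away-from-zero to one decimal, the convention
under which every published group percentage is reproduced from its own
printed areas.  Published grand totals are always recomputed from row sums;
one published total (335,230 ha historical) is inconsistent with its own
rows (355,230 ha), and the row sum is what reproduces the published overall
85.0%.

### Agreement validation

Local categories translate to lost/retained/unclassified through editable
plain-text preset mappings (three shipped: a tidal-restriction vocabulary,
an anthropogenic-impact-modifier vocabulary with "absence means retained"
default, and a baylands-habitat vocabulary).  Cross-tab cells are pairwise
polygon intersection areas; locally unclassified area is reported but
excluded from the percentage denominator — that is the convention under
which the published 93.6% total agreement is reproducible from its printed
cells (30,369 / 32,449-ish, not / 39,172).

## The synthetic world

The generator emulates: a west-facing coast with an ocean strip, a fringing
along-shore marsh band, and 2–3 river valleys whose floors dip below EX50
and rise inland (default slope 8 × 10⁻⁴ m/m) to an estuary head; a
latitudinal EX50 cline (2.1 m south to 3.4 m north, the observed coast-wide
range) expressed as gauge deltas over a 1.7 m MHHW baseline plane; inland
ridges acting as interpolation barriers; two-level watershed units; and a
parcel tiling of the wet area with Cowardin-style codes in which a seeded
fraction (default 0.3) is diked (nontidal regime + `h`, planted lost), a
fraction (default 0.1) is left upland, and the ocean is an unvegetated
subtidal record (excluded).  One seeded stream drives all draws in
documented order (per block, row-major: upland? → diked? → code index).

Two coverage modes: `full` (datum surface fully covered; the sealed fill is
a no-op) and `truncated` (coverage ends at mid-grid; MHHW is constant per
watershed unit with a 0.15 m step into the units the coarse pass must fill,
chosen by pre-run error analysis so the mis-filled band is a few percent of
the wet area).  DEM cell-center offsets from the true EX50 surface are
pushed outside a ±0.1 m band, so recovery is exact whenever surface errors
stay below that margin — making IoU = 1.0 a property of the method rather
than floating-point luck.

What the fixture does **not** emulate, and hence what passing tests do not
show about real data: lidar vegetation bias (real DEMs sit 10–30 cm high in
marsh vegetation), datum-model error, fluvial water-level gradients within
rivers, mouth morphology (no seaward-boundary step is exercised end to
end), irregular watershed geometry, inventory mapping error, and areas
filled above the EX50 surface (which cause real-world underestimation of
historical extent).

## Problem sizes used

Recovery runs use the 256×256 default world (≈ 6.6 km square at 10 m
cells); oracle-equivalence checks use 100 random grids up to 64×64 for the
sealed fill and 20 random 16×16 barrier layouts for the interpolator;
published-table arithmetic runs on the printed group/cell areas directly.

## Known limitations

* Vector I/O is GeoJSON/CSV only and rasters are ASCII grids; no projected-
  CRS metadata is read or written — all layers must already share one
  projected planar reference in meters, and the tool refuses nothing it
  cannot see (reprojection is out of scope).
* The barrier interpolator's grid-graph distances overestimate Euclidean
  distance by up to ~8% (octile metric); fields are smooth but not
  spline-identical to the proprietary tool.
* No inland distance cap is imposed on datum extrapolation; far-upriver
  fills inherit the nearest sealed value however distant.
* Per-estuary summaries attribute upland remainder to an `unassigned`
  group unless inventory records carry estuary ids.
* Classification of whether appended inventory polygons should be trimmed
  at estuary-unit boundaries is unstated upstream; they are kept whole and
  tagged with their provenance.
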