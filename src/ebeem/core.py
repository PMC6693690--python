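"""Domain types shared across the pipeline, plus the Cowardin/NWI code parser.

The pipeline works in a single projected planar coordinate reference with
coordinates in meters.  Rasters are row-major 2-D arrays whose row 0 is the
northernmost row; a cell's value is attributed to its center.  Vertical
elevations are meters relative to a named vertical datum (NAVD88, MHHW, MLLW,
MSL, or NONE for unitless flag grids).

Wetland-inventory polygons carry Cowardin-style alphanumeric codes such as
``E2EM1N`` (Estuarine, intertidal, emergent, persistent-like subclass,
regularly-flooded regime).  :func:`parse_nwi_code` decomposes such a code into
the attributes every downstream classification rule consumes:

* ``system`` — first letter, one of M (marine), E (estuarine), R (riverine),
  P (palustrine), L (lacustrine); the reserved upland token maps to ``NONE``.
* ``veg_class`` — the two-letter class (EM/SS/FO/AB/US/UB/RS/RB, anything
  else recognized maps to OTHER).
* ``regime`` — the trailing uppercase water-regime letter (or ``NONE``).
* ``modifiers`` — trailing lowercase special modifiers.

Derived flags:

* ``vegetated`` — class is emergent, scrub-shrub, or forested.
* ``tidal_regime`` — the polygon sits in a tidally driven regime: every
  estuarine or marine polygon, or any other system whose regime letter is in
  the tidal list {S, Q, R, T, V}.
* ``disconnected`` — diked/impounded (h), drained/ditched (d) or farmed (f).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
from shapely.geometry.base import BaseGeometry

__all__ = [
    "VERTICAL_DATUMS",
    "TIDAL_REGIME_LETTERS",
    "DISCONNECT_MODIFIERS",
    "UPLAND_TOKENS",
    "RasterGrid",
    "TideGaugeRecord",
    "ShorelinePath",
    "WatershedUnit",
    "NwiRecord",
    "ExtentPolygon",
    "EstuaryUnit",
    "LossLabel",
    "NwiParseError",
    "parse_nwi_code",
]

VERTICAL_DATUMS = frozenset({"NAVD88", "MHHW", "MLLW", "MSL", "NONE"})

#: Water-regime letters treated as tidal for non-estuarine, non-marine systems.
TIDAL_REGIME_LETTERS = frozenset({"S", "Q", "R", "T", "V"})

#: Special modifiers marking hydrologic disconnection: diked/impounded,
#: drained/ditched, farmed.
DISCONNECT_MODIFIERS = frozenset({"h", "d", "f"})

#: Reserved tokens for areas inside the extent with no inventory polygon.
UPLAND_TOKENS = frozenset({"UPL", "U"})

_SYSTEMS = frozenset({"M", "E", "R", "P", "L"})
_KNOWN_CLASSES = ("EM", "SS", "FO", "AB", "US", "UB", "RS", "RB", "ML", "RF", "SB", "OW")
_ENUM_CLASSES = frozenset({"EM", "SS", "FO", "AB", "US", "UB", "RS", "RB"})
_VEG_CLASSES = frozenset({"EM", "SS", "FO"})


# ---------------------------------------------------------------------------
# Raster container
# ---------------------------------------------------------------------------

@dataclass
class RasterGrid:
    """A regular north-up grid of values with affine georeferencing.

    ``origin_x``/``origin_y`` locate the *outer corner* of the top-left
    (northwest) cell; cell centers are at
    ``(origin_x + (col + 0.5) * cell_size, origin_y - (row + 0.5) * cell_size)``.
    """

    values: np.ndarray
    origin_x: float
    origin_y: float
    cell_size: float
    nodata: float = -9999.0
    vertical_datum: str = "NONE"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("RasterGrid values must be 2-D")
        if not self.cell_size > 0:
            raise ValueError("cell_size must be positive")
        if self.vertical_datum not in VERTICAL_DATUMS:
            raise ValueError(f"unknown vertical datum {self.vertical_datum!r}")
        valid = self.values != self.nodata
        if not np.all(np.isfinite(self.values[valid])):
            raise ValueError("non-nodata raster values must be finite")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def mask_valid(self) -> np.ndarray:
        """Boolean grid, True where the cell holds data."""
        return self.values != self.nodata

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(xs, ys) arrays of cell-center coordinates, shaped like values."""
        nrow, ncol = self.values.shape
        xs = self.origin_x + (np.arange(ncol) + 0.5) * self.cell_size
        ys = self.origin_y - (np.arange(nrow) + 0.5) * self.cell_size
        return np.broadcast_to(xs, (nrow, ncol)), np.broadcast_to(ys[:, None], (nrow, ncol))

    def aligned_with(self, other: "RasterGrid") -> bool:
        return (
            self.shape == other.shape
            and math.isclose(self.origin_x, other.origin_x, abs_tol=1e-6)
            and math.isclose(self.origin_y, other.origin_y, abs_tol=1e-6)
            and math.isclose(self.cell_size, other.cell_size, rel_tol=1e-12)
        )

    def copy_with(self, values: np.ndarray, vertical_datum: Optional[str] = None) -> "RasterGrid":
        return RasterGrid(
            values=np.array(values, dtype=float),
            origin_x=self.origin_x,
            origin_y=self.origin_y,
            cell_size=self.cell_size,
            nodata=self.nodata,
            vertical_datum=self.vertical_datum if vertical_datum is None else vertical_datum,
        )


def require_aligned(a: RasterGrid, b: RasterGrid, what: str = "rasters") -> None:
    if not a.aligned_with(b):
        raise ValueError(f"{what} are not aligned (shape/origin/cell size mismatch)")


# ---------------------------------------------------------------------------
# Simple record types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TideGaugeRecord:
    """A tide gauge with its 50%-exceedance height above MHHW (the delta)."""

    gauge_id: str
    x: float
    y: float
    ex50_above_mhhw: float
    mhhw_above_reference: Optional[float] = None
    epoch: str = ""

    def __post_init__(self) -> None:
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise ValueError(f"gauge {self.gauge_id}: position must be finite")
        if not self.ex50_above_mhhw >= 0:
            raise ValueError(
                f"gauge {self.gauge_id}: annual high tide cannot be below MHHW "
                f"(ex50_above_mhhw={self.ex50_above_mhhw})"
            )


@dataclass(frozen=True)
class ShorelinePath:
    """An ordered polyline (possibly multipart) with a role set.

    Roles: ``stationing`` marks the path used to measure along-shore arc
    length; ``barrier`` marks landmass lines impassable to interpolation.
    """

    parts: tuple[tuple[tuple[float, float], ...], ...]
    roles: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not self.parts:
            raise ValueError("ShorelinePath needs at least one part")
        for part in self.parts:
            if len(part) < 2:
                raise ValueError("each shoreline part needs >= 2 vertices")

    @classmethod
    def from_coords(cls, coords: Sequence[tuple[float, float]],
                    roles: Iterable[str] = ()) -> "ShorelinePath":
        return cls(parts=(tuple((float(x), float(y)) for x, y in coords),),
                   roles=frozenset(roles))


@dataclass(frozen=True)
class WatershedUnit:
    polygon: BaseGeometry
    level: str  # "fine" or "coarse"
    unit_id: str

    def __post_init__(self) -> None:
        if self.level not in ("fine", "coarse"):
            raise ValueError(f"unit {self.unit_id}: level must be fine or coarse")
        if self.polygon.is_empty or not self.polygon.is_valid:
            raise ValueError(f"unit {self.unit_id}: polygon must be valid and non-empty")


@dataclass(frozen=True)
class ExtentPolygon:
    polygon: BaseGeometry
    provenance: str
    estuary_id: str = ""

    _PROVENANCES = ("below_ex50", "nwi_appended", "lagoon_supplied", "regional_override")

    def __post_init__(self) -> None:
        if self.provenance not in self._PROVENANCES:
            raise ValueError(f"unknown provenance {self.provenance!r}")
        if not self.polygon.is_valid:
            raise ValueError("extent polygon must be valid")


ECOREGIONS = ("Salish Sea", "WA/OR/N.CA", "Central CA", "S.CA Bight")
PHYS_TYPES = ("embayment", "lagoon", "major_river_delta", "riverine")


@dataclass(frozen=True)
class EstuaryUnit:
    estuary_id: str
    name: str
    ecoregion: str
    phys_type: str
    historical_area_ha: float

    def __post_init__(self) -> None:
        if self.historical_area_ha < 0:
            raise ValueError("historical_area_ha must be >= 0")
        if self.phys_type not in PHYS_TYPES:
            raise ValueError(f"unknown phys_type {self.phys_type!r}")


@dataclass(frozen=True)
class LossLabel:
    label: str  # lost | retained | excluded
    reason: str  # decision-table cell identifier, "|gap"-suffixed for blanks
    area_ha: float = 0.0

    def __post_init__(self) -> None:
        if self.label not in ("lost", "retained", "excluded"):
            raise ValueError(f"unknown loss label {self.label!r}")
        if self.area_ha < 0:
            raise ValueError("area_ha must be >= 0")


# ---------------------------------------------------------------------------
# Cowardin/NWI code parsing
# ---------------------------------------------------------------------------

class NwiParseError(ValueError):
    """Raised for a code that does not follow the positional grammar."""

    def __init__(self, raw_code: str, position: int, message: str):
        self.raw_code = raw_code
        self.position = position
        super().__init__(f"cannot parse NWI code {raw_code!r} at position {position}: {message}")


@dataclass(frozen=True)
class NwiRecord:
    """A wetland polygon with its raw code and parsed attributes.

    ``polygon`` may be None for attribute-only work (e.g. rule tables)."""

    raw_code: str
    system: str  # M, E, R, P, L, or NONE (upland)
    veg_class: str  # EM, SS, FO, AB, US, UB, RS, RB, OTHER, or NONE
    regime: str  # single uppercase letter or NONE
    modifiers: frozenset[str] = frozenset()
    subsystem: str = ""  # parsed, never consulted by rules
    subclass: str = ""  # parsed, never consulted by rules
    polygon: Optional[BaseGeometry] = None
    estuary_id: str = ""

    @property
    def vegetated(self) -> bool:
        return self.veg_class in _VEG_CLASSES

    @property
    def tidal_regime(self) -> bool:
        return self.system in ("E", "M") or self.regime in TIDAL_REGIME_LETTERS

    @property
    def disconnected(self) -> bool:
        return bool(self.modifiers & DISCONNECT_MODIFIERS)

    @property
    def is_upland(self) -> bool:
        return self.system == "NONE"

    def with_geometry(self, polygon: BaseGeometry, estuary_id: str = "") -> "NwiRecord":
        return NwiRecord(
            raw_code=self.raw_code, system=self.system, veg_class=self.veg_class,
            regime=self.regime, modifiers=self.modifiers, subsystem=self.subsystem,
            subclass=self.subclass, polygon=polygon,
            estuary_id=estuary_id or self.estuary_id,
        )


def parse_nwi_code(raw_code: str) -> NwiRecord:
    """Decompose a Cowardin-style code into its positional attributes.

    Grammar (positional): system letter, optional subsystem digit, optional
    two-letter class, optional subclass digit, optional water-regime uppercase
    letter, optional trailing lowercase special modifiers.  The reserved
    upland tokens (``UPL``/``U``) yield ``system='NONE'``.

    Parsing is total and deterministic; anything outside the grammar raises
    :class:`NwiParseError` naming the offending position.
    """
    code = raw_code.strip()
    if not code:
        raise NwiParseError(raw_code, 0, "empty code")
    if code.upper() in UPLAND_TOKENS:
        return NwiRecord(raw_code=raw_code, system="NONE", veg_class="NONE", regime="NONE")

    pos = 0
    system = code[0]
    if system not in _SYSTEMS:
        raise NwiParseError(raw_code, 0, f"unknown system letter {system!r}")
    pos = 1

    subsystem = ""
    if pos < len(code) and code[pos].isdigit():
        subsystem = code[pos]
        pos += 1

    veg_class = "NONE"
    if pos + 1 < len(code) and code[pos:pos + 2] in _KNOWN_CLASSES:
        pair = code[pos:pos + 2]
        veg_class = pair if pair in _ENUM_CLASSES else "OTHER"
        pos += 2

    subclass = ""
    if pos < len(code) and code[pos].isdigit():
        if veg_class == "NONE":
            raise NwiParseError(raw_code, pos, "subclass digit without a class")
        subclass = code[pos]
        pos += 1

    regime = "NONE"
    if pos < len(code) and code[pos].isupper():
        if code[pos].isalpha():
            regime = code[pos]
            pos += 1
        else:
            raise NwiParseError(raw_code, pos, f"unexpected character {code[pos]!r}")

    modifiers: set[str] = set()
    while pos < len(code):
        ch = code[pos]
        if ch.islower() and ch.isalpha():
            modifiers.add(ch)
            pos += 1
        else:
            raise NwiParseError(raw_code, pos, f"unexpected character {ch!r}")

    return NwiRecord(
        raw_code=raw_code,
        system=system,
        veg_class=veg_class,
        regime=regime,
        modifiers=frozenset(modifiers),
        subsystem=subsystem,
        subclass=subclass,
    )
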