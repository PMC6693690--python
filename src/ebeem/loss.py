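"""Indirect tidal-wetland-loss assessment.

Loss is inferred, not mapped directly: everything below the 50%-exceedance
contour was once tidal wetland; whatever inside that footprint is *not*
currently a vegetated tidal wetland in the inventory has been lost.  The
decision table over (system, vegetated, tidal regime, disconnected) is:

* ``excluded`` — marine-system polygons, and non-vegetated tidal polygons
  that are not diked/drained/farmed (aquatic beds, flats, open water): the
  assessment targets only the emergent/scrub-shrub/forested classes.
* ``retained`` — vegetated, tidal regime, and not disconnected.
* ``lost`` — everything else, including uplands (areas inside the extent
  with no inventory polygon at all).

Attribute combinations absent from the printed rule table fall through to
the same compact predicate and are flagged ``rule_gap`` for audit.

Scope filters: lagoonal estuaries are excluded outright (their maximum water
levels may be set by mouth closure, not tides), as are estuaries with at
most 100 ha of historical extent (inventory mapping scale is inadequate for
smaller systems).
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Optional, Union
import warnings

import pandas as pd
import shapely

from .core import EstuaryUnit, ExtentPolygon, LossLabel, NwiRecord, UPLAND_TOKENS

__all__ = [
    "LossSummaryRow",
    "filter_analysis_scope",
    "classify_loss",
    "classify_extent",
    "summarize_loss",
    "round_half_away",
    "M2_PER_HA",
]

M2_PER_HA = 10_000.0


def round_half_away(x: float, decimals: int = 1) -> float:
    """Round with ties away from zero (the convention every recomputed
    printed percentage follows), avoiding float banker's rounding."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class LossSummaryRow:
    group_key: str
    n_estuaries: int
    lost_ha: float
    historical_ha: float
    pct_loss: Optional[float]  # None when historical area is zero


def filter_analysis_scope(
    estuaries: Iterable[EstuaryUnit],
) -> tuple[list[EstuaryUnit], list[tuple[str, str]]]:
    """Keep non-lagoonal estuaries larger than 100 ha of historical extent.

    Returns (kept, exclusion report of (estuary_id, reason))."""
    kept: list[EstuaryUnit] = []
    excluded: list[tuple[str, str]] = []
    for e in estuaries:
        if e.phys_type == "lagoon":
            excluded.append((e.estuary_id, "lagoonal"))
        elif not e.historical_area_ha > 100.0:
            excluded.append((e.estuary_id, "size"))
        else:
            kept.append(e)
    return kept, excluded


# Cells printed in the rule table, keyed by (system, vegetated, tidal,
# disconnected).  Anything else is a gap and falls through to the predicate.
_PRINTED_CELLS = {
    ("M", False, True, False),
    ("R", True, True, False),
    ("R", False, True, False),
    ("E", True, True, True),
    ("E", True, True, False),
    ("E", False, True, True),
    ("E", False, True, False),
    ("P", True, False, True),
    ("P", True, False, False),
    ("P", True, True, True),
    ("P", True, True, False),
    ("P", False, False, True),
    ("P", False, False, False),
    ("P", False, True, True),
    ("P", False, True, False),
    ("L", True, False, True),
    ("L", True, False, False),
    ("L", True, True, True),
    ("L", True, True, False),
    ("L", False, False, True),
    ("L", False, False, False),
    ("L", False, True, True),
    ("L", False, True, False),
}


def classify_loss(
    record: Union[NwiRecord, str],
    within_extent: bool = True,
    area_ha: float = 0.0,
    rule_gaps: Optional[list[str]] = None,
) -> LossLabel:
    """Classify one inventory polygon (or the upland token) as lost,
    retained, or excluded.

    ``record`` is a parsed :class:`~ebeem.core.NwiRecord` or an upland token
    string.  Polygons outside the extent are never classified
    (``within_extent`` must be True).  Every label carries a ``reason``
    identifying the decision cell that fired; combinations not printed in
    the rule table get a ``|gap`` suffix and are appended to ``rule_gaps``
    when given.
    """
    if not within_extent:
        raise ValueError("records outside the extent are never classified")

    if isinstance(record, str):
        if record.upper() not in UPLAND_TOKENS:
            raise ValueError(f"string record must be an upland token, got {record!r}")
        return LossLabel(label="lost", reason="NONE:upland", area_ha=area_ha)
    if record.is_upland:
        return LossLabel(label="lost", reason="NONE:upland", area_ha=area_ha)

    sys_, veg, tidal, disc = (
        record.system, record.vegetated, record.tidal_regime, record.disconnected
    )
    if sys_ == "M" or (not veg and tidal and not disc):
        label = "excluded"
    elif veg and tidal and not disc:
        label = "retained"
    else:
        label = "lost"

    reason = ":".join([
        sys_,
        "veg" if veg else "nonveg",
        "tidal" if tidal else "nontidal",
        "diked" if disc else "undiked",
    ])
    if (sys_, veg, tidal, disc) not in _PRINTED_CELLS:
        reason += "|gap"
        if rule_gaps is not None:
            rule_gaps.append(reason)
    return LossLabel(label=label, reason=reason, area_ha=area_ha)


def classify_extent(
    extent: list[ExtentPolygon],
    nwi: list[NwiRecord],
    estuary_id: str = "",
    rule_gaps: Optional[list[str]] = None,
) -> pd.DataFrame:
    """Intersect the extent with the inventory and classify every piece.

    Inventory polygons are clipped to the extent; the extent remainder with
    no inventory polygon is upland (lost).  Returns a frame with columns
    estuary_id, raw_code, label, reason, area_ha, geometry (shapely).
    """
    extent_union = shapely.union_all([e.polygon for e in extent])
    rows = []
    covered = []
    for rec in nwi:
        if rec.polygon is None:
            continue
        clipped = rec.polygon.intersection(extent_union)
        if clipped.is_empty or clipped.area <= 0:
            continue
        covered.append(clipped)
        lab = classify_loss(rec, within_extent=True,
                            area_ha=clipped.area / M2_PER_HA, rule_gaps=rule_gaps)
        rows.append({
            "estuary_id": rec.estuary_id or estuary_id,
            "raw_code": rec.raw_code,
            "label": lab.label,
            "reason": lab.reason,
            "area_ha": lab.area_ha,
            "geometry": clipped,
        })
    upland = extent_union.difference(shapely.union_all(covered)) if covered else extent_union
    if not upland.is_empty and upland.area > 0:
        lab = classify_loss("UPL", within_extent=True, area_ha=upland.area / M2_PER_HA)
        rows.append({
            "estuary_id": estuary_id,
            "raw_code": "UPL",
            "label": lab.label,
            "reason": lab.reason,
            "area_ha": lab.area_ha,
            "geometry": upland,
        })
    return pd.DataFrame(rows, columns=["estuary_id", "raw_code", "label",
                                       "reason", "area_ha", "geometry"])


def summarize_loss(
    labels: pd.DataFrame,
    group_col: str = "group",
    total_label: str = "Total",
) -> pd.DataFrame:
    """Grouped loss summary.

    ``labels`` needs columns [group_col, estuary_id, label, area_ha].  Per
    group: lost_ha = Σ lost areas, historical_ha = Σ lost + Σ retained
    (excluded areas never enter the denominator), pct_loss = 100·lost/hist
    rounded half-away-from-zero to one decimal.  A grand-total row sums the
    group rows.  Groups with zero historical area get an empty percentage
    and a warning.
    """
    required = {group_col, "estuary_id", "label", "area_ha"}
    missing = required - set(labels.columns)
    if missing:
        raise ValueError(f"labels frame missing columns {sorted(missing)}")
    rows = []
    for key, sub in labels.groupby(group_col, sort=True):
        lost = float(sub.loc[sub["label"] == "lost", "area_ha"].sum())
        retained = float(sub.loc[sub["label"] == "retained", "area_ha"].sum())
        hist = lost + retained
        counted = sub.loc[sub["label"].isin(["lost", "retained"]), "estuary_id"]
        n = int(counted.nunique())
        if hist > 0:
            pct = round_half_away(100.0 * lost / hist, 1)
        else:
            warnings.warn(f"group {key!r} has zero historical area; "
                          f"percent loss undefined", stacklevel=2)
            pct = None
        rows.append(LossSummaryRow(str(key), n, lost, hist, pct))
    lost_tot = sum(r.lost_ha for r in rows)
    hist_tot = sum(r.historical_ha for r in rows)
    n_tot = int(labels.loc[labels["label"].isin(["lost", "retained"]),
                           "estuary_id"].nunique())
    pct_tot = round_half_away(100.0 * lost_tot / hist_tot, 1) if hist_tot > 0 else None
    rows.append(LossSummaryRow(total_label, n_tot, lost_tot, hist_tot, pct_tot))
    return pd.DataFrame(
        [{
            "group": r.group_key,
            "n_estuaries": r.n_estuaries,
            "lost_ha": r.lost_ha,
            "historical_ha": r.historical_ha,
            "pct_loss": r.pct_loss,
        } for r in rows]
    )
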