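"""Agreement validation against independent local loss classifications.

A regional lost/retained map can be checked wherever a well-studied estuary
has its own direct mapping of tidal restriction (dikes, levees, fill).  The
local categories are first translated to lost/retained/unclassified with a
named preset (or a custom mapping), the two layers are cross-tabulated by
polygon intersection, and agreement percentages are computed over the
classified area only — area the local effort did not classify is reported
but excluded from the denominator.

Presets ship as editable plain-text mapping files (``data/presets/*.tsv``),
one ``local_label<TAB>category`` pair per line; a ``*`` row supplies a
default for otherwise-unknown labels (used by the anthropogenic-impact-
modifier preset, where absence of the modifier means retained).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources

import shapely
from shapely.geometry.base import BaseGeometry
from shapely.strtree import STRtree

from .loss import round_half_away

__all__ = [
    "AgreementCrossTab",
    "load_preset",
    "map_local_categories",
    "crosstab_agreement",
    "agreement_metrics",
    "PRESETS",
]

PRESETS = ("lcep", "ocmp_ai07", "sfei")
_CATEGORIES = ("lost", "retained", "unclassified")


@dataclass(frozen=True)
class AgreementCrossTab:
    """Areas (ha) in the four agree/disagree cells plus locally unclassified."""

    agree_lost_ha: float
    agree_retained_ha: float
    disagree_region_lost_ha: float  # region says lost, local says retained
    disagree_region_retained_ha: float  # region says retained, local says lost
    unclassified_local_ha: float = 0.0

    def __post_init__(self) -> None:
        for name in ("agree_lost_ha", "agree_retained_ha", "disagree_region_lost_ha",
                     "disagree_region_retained_ha", "unclassified_local_ha"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def classified_total_ha(self) -> float:
        return (self.agree_lost_ha + self.agree_retained_ha
                + self.disagree_region_lost_ha + self.disagree_region_retained_ha)


def load_preset(preset: str) -> dict[str, str]:
    """Load a named local-category mapping from its packaged text file."""
    if preset not in PRESETS:
        raise ValueError(f"unknown preset {preset!r}; choose from {PRESETS}")
    text = resources.files("ebeem").joinpath(f"data/presets/{preset}.tsv").read_text()
    mapping: dict[str, str] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        label, _, category = line.partition("\t")
        category = category.strip()
        if category not in _CATEGORIES:
            raise ValueError(f"preset {preset}: bad category {category!r}")
        mapping[label.strip().lower()] = category
    return mapping


def map_local_categories(local_label: str, preset) -> str:
    """Translate a local classification label to lost/retained/unclassified.

    ``preset`` is a preset name or an explicit mapping dict (lowercased
    labels; optional ``*`` default).  Unknown labels map to unclassified
    with a warning.
    """
    mapping = load_preset(preset) if isinstance(preset, str) else preset
    key = local_label.strip().lower()
    if key in mapping:
        return mapping[key]
    if "*" in mapping:
        return mapping["*"]
    warnings.warn(f"local label {local_label!r} not in mapping; unclassified",
                  stacklevel=2)
    return "unclassified"


def crosstab_agreement(
    region: list[tuple[BaseGeometry, str]],
    local: list[tuple[BaseGeometry, str]],
) -> AgreementCrossTab:
    """Cross-tabulate region lost/retained polygons against local
    lost/retained/unclassified polygons by pairwise intersection area.

    Region-excluded polygons must not be passed (they are omitted from the
    assessment).  Region area not covered by any local polygon, or covered
    only by locally unclassified polygons, accumulates into the
    unclassified cell.  Invalid geometries are skipped with a warning.
    """
    m2_per_ha = 10_000.0
    cells = {("lost", "lost"): 0.0, ("lost", "retained"): 0.0,
             ("retained", "lost"): 0.0, ("retained", "retained"): 0.0}
    unclassified = 0.0

    good_local = []
    for geom, lab in local:
        if lab not in _CATEGORIES:
            raise ValueError(f"local label must be one of {_CATEGORIES}, got {lab!r}")
        if not geom.is_valid or geom.is_empty:
            warnings.warn("invalid local geometry skipped", stacklevel=2)
            continue
        good_local.append((geom, lab))

    tree = STRtree([g for g, _ in good_local]) if good_local else None
    for rgeom, rlab in region:
        if rlab == "excluded":
            continue
        if rlab not in ("lost", "retained"):
            raise ValueError(f"region label must be lost/retained/excluded, got {rlab!r}")
        if not rgeom.is_valid or rgeom.is_empty:
            warnings.warn("invalid region geometry skipped", stacklevel=2)
            continue
        covered = 0.0
        if tree is not None:
            for idx in tree.query(rgeom):
                lgeom, llab = good_local[idx]
                inter = rgeom.intersection(lgeom)
                if inter.is_empty:
                    continue
                a = inter.area
                covered += a
                if llab == "unclassified":
                    unclassified += a / m2_per_ha
                else:
                    cells[(rlab, llab)] += a / m2_per_ha
        leftover = rgeom.area - covered
        if leftover > 0:
            unclassified += leftover / m2_per_ha
    return AgreementCrossTab(
        agree_lost_ha=cells[("lost", "lost")],
        agree_retained_ha=cells[("retained", "retained")],
        disagree_region_lost_ha=cells[("lost", "retained")],
        disagree_region_retained_ha=cells[("retained", "lost")],
        unclassified_local_ha=unclassified,
    )


def agreement_metrics(tab: AgreementCrossTab, decimals: int = 1) -> dict[str, float]:
    """Percentages over the classified total (unclassified area excluded
    from the denominator), ties rounded away from zero."""
    total = tab.classified_total_ha
    if not total > 0:
        raise ValueError("classified total must be positive")

    def pct(x: float) -> float:
        return round_half_away(100.0 * x / total, decimals)

    return {
        "total_classified_ha": total,
        "agree_lost_pct": pct(tab.agree_lost_ha),
        "agree_retained_pct": pct(tab.agree_retained_ha),
        "disagree_region_lost_pct": pct(tab.disagree_region_lost_ha),
        "disagree_region_retained_pct": pct(tab.disagree_region_retained_ha),
        "total_agreement_ha": tab.agree_lost_ha + tab.agree_retained_ha,
        "total_agreement_pct": pct(tab.agree_lost_ha + tab.agree_retained_ha),
    }
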