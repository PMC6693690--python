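"""Stage orchestration: simulate → surface → extent → loss → agree.

Each stage reads its inputs from files, writes new files (inputs are never
mutated), and drops a JSON provenance sidecar (``<stage>.provenance.json``)
recording inputs, parameters, package version, and a timestamp.  Primary
outputs are deterministic: re-running a stage on identical inputs yields
byte-identical files (the sidecar carries the only timestamps).
"""

from __future__ import annotations

import datetime
import json
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .agreement import agreement_metrics, crosstab_agreement, map_local_categories
from .core import ExtentPolygon
from .exceedance import (
    interpolate_with_barriers,
    seed_samples_along_path,
    station_along_shoreline,
)
from .extent import append_nwi_tidal, threshold_extent
from .fixtures import FixtureSpec, generate_fixture
from .loss import classify_extent, filter_analysis_scope, summarize_loss
from .surfaces import DatumSurface, assemble_ex50, seal_extrapolate
from . import io as eio

__all__ = ["PipelineConfig", "run_pipeline", "read_config", "STAGES",
           "run_fixture_in_memory"]


def run_fixture_in_memory(bundle, idw_power: float = 2.0, idw_k: int = 8) -> dict:
    """Run surface → extent → loss on a generated fixture bundle without
    touching disk.  Returns the predicted mask, the assembled EX50 grid,
    the classified frame, and per-parcel predicted labels (aligned with the
    truth table by draw order)."""
    from .core import parse_nwi_code
    from .extent import threshold_mask
    from .loss import classify_loss

    sealed = seal_extrapolate(bundle.mhhw, bundle.fine_units, bundle.coarse_units)
    stationed = station_along_shoreline(bundle.shoreline, bundle.gauges)
    samples = seed_samples_along_path(bundle.shoreline, stationed, bundle.dem)
    delta = interpolate_with_barriers(samples, bundle.barrier_mask, bundle.dem,
                                      idw_power=idw_power, idw_k=idw_k)
    ex50 = assemble_ex50(sealed, delta)
    mask = threshold_mask(bundle.dem, ex50)
    extent = threshold_extent(bundle.dem, ex50)
    extent = append_nwi_tidal(extent, bundle.nwi)
    classified = classify_extent(extent, bundle.nwi)

    # per-parcel predicted labels, keyed like the truth table
    code_by_pid = dict(zip(bundle.truth.true_labels["parcel_id"],
                           bundle.truth.true_labels["raw_code"]))
    pred_rows = [
        {"parcel_id": pid, "label": classify_loss(parse_nwi_code(code)).label}
        for pid, code in code_by_pid.items()
    ]
    predicted_labels = pd.DataFrame(pred_rows)
    return {"mask": mask, "ex50": ex50, "extent": extent,
            "classified": classified, "predicted_labels": predicted_labels,
            "sealed": sealed, "delta": delta}

STAGES = ("simulate", "surface", "extent", "loss", "agree", "all")

_DEFAULTS = {
    "depth_clip_m": 4.0,
    "idw_power": 2.0,
    "idw_k": 8,
    "snap_tolerance_m": 50_000.0,
    "mmu_ha": 0.0,
    "decimals": 1,
    "seed": 0,
    "coverage": "full",
    "grid_n": 256,
    "preset": "lcep",
}


class PipelineConfig(dict):
    """Flat key/value configuration; unknown keys are preserved."""

    def param(self, key: str):
        return self.get(key, _DEFAULTS.get(key))

    def path(self, key: str, default_name: Optional[str] = None) -> Optional[Path]:
        if key in self:
            return Path(self[key])
        if default_name is not None:
            return Path(self.param("out_dir") or ".") / default_name
        return None


def read_config(path) -> PipelineConfig:
    cfg = PipelineConfig()
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        key, _, value = line.partition("=")
        cfg[key.strip()] = value.strip()
    return cfg


def _sidecar(out_dir: Path, stage: str, inputs: dict, params: dict) -> None:
    payload = {
        "stage": stage,
        "inputs": {k: str(v) for k, v in inputs.items()},
        "parameters": params,
        "software": f"ebeem {__version__}",
        "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(),
    }
    (out_dir / f"{stage}.provenance.json").write_text(
        json.dumps(payload, sort_keys=True, indent=1) + "\n")


def _require(path: Path, stage: str, needed_by: str) -> Path:
    if not path.exists():
        raise FileNotFoundError(
            f"stage '{needed_by}' needs {path.name}, produced by stage "
            f"'{stage}'; run that stage first"
        )
    return path


def run_pipeline(config: PipelineConfig, stage: str) -> dict:
    """Execute one stage (or 'all' = surface→extent→loss[→agree]).

    Returns a small report dict of the primary outputs written."""
    if stage not in STAGES:
        raise ValueError(f"unknown stage {stage!r}; choose from {STAGES}")
    out_dir = Path(config.param("out_dir") or ".")
    out_dir.mkdir(parents=True, exist_ok=True)

    if stage == "all":
        report = {}
        for s in ("surface", "extent", "loss"):
            report.update(run_pipeline(config, s))
        if config.path("local") is not None:
            report.update(run_pipeline(config, "agree"))
        return report

    if stage == "simulate":
        n = int(config.param("grid_n"))
        spec = FixtureSpec(
            shape=(n, n),
            coverage=str(config.param("coverage")),
            seed=int(config.param("seed")),
        )
        b = generate_fixture(spec)
        eio.write_raster(b.dem, out_dir / "dem.asc")
        eio.write_raster(b.mhhw.grid, out_dir / "mhhw.asc")
        eio.write_mask(b.mhhw.coverage_mask, b.dem, out_dir / "mhhw_coverage.asc")
        eio.write_mask(b.barrier_mask, b.dem, out_dir / "barrier_mask.asc")
        eio.write_gauges(b.gauges, out_dir / "gauges.csv")
        eio.write_shoreline([b.shoreline], out_dir / "shoreline.geojson")
        eio.write_features([(g, {"kind": "barrier"}) for g in b.barriers],
                           out_dir / "barriers.geojson")
        eio.write_units(b.fine_units + b.coarse_units, out_dir / "units.geojson")
        eio.write_nwi(b.nwi, out_dir / "nwi.geojson")
        eio.write_estuaries(b.estuaries, out_dir / "estuaries.csv")
        eio.write_mask(b.truth.true_extent_mask, b.dem, out_dir / "truth_mask.asc")
        b.truth.true_labels.to_csv(out_dir / "truth_labels.csv", index=False)
        _sidecar(out_dir, stage, {}, {"seed": spec.seed, "coverage": spec.coverage,
                                      "grid_n": n})
        return {"simulate": str(out_dir)}

    if stage == "surface":
        mhhw_p = _require(config.path("mhhw", "mhhw.asc"), "simulate", stage)
        cov_p = _require(config.path("mhhw_coverage", "mhhw_coverage.asc"),
                         "simulate", stage)
        units_p = _require(config.path("units", "units.geojson"), "simulate", stage)
        gauges_p = _require(config.path("gauges", "gauges.csv"), "simulate", stage)
        shore_p = _require(config.path("shoreline", "shoreline.geojson"),
                           "simulate", stage)
        mhhw_grid = eio.read_raster(mhhw_p)
        coverage, _ = eio.read_mask(cov_p)
        units = eio.read_units(units_p)
        fine = [u for u in units if u.level == "fine"]
        coarse = [u for u in units if u.level == "coarse"]
        sealed = seal_extrapolate(DatumSurface(mhhw_grid, coverage), fine, coarse)
        eio.write_raster(sealed.grid, out_dir / "mhhw_filled.asc")
        eio.write_mask(sealed.coverage_mask, sealed.grid,
                       out_dir / "mhhw_filled_coverage.asc")

        gauges = eio.read_gauges(gauges_p)
        shorelines = eio.read_shoreline(shore_p)
        stationing = next(s for s in shorelines if "stationing" in s.roles)
        stationed = station_along_shoreline(
            stationing, gauges, float(config.param("snap_tolerance_m")))
        samples = seed_samples_along_path(stationing, stationed, mhhw_grid)
        # exportable audit trail of the along-shore samples
        pd.DataFrame([{
            "station_m": s.station_m, "x": s.x, "y": s.y, "delta": s.delta,
        } for s in samples]).to_csv(out_dir / "samples.csv", index=False)
        bmask_p = config.path("barrier_mask", "barrier_mask.asc")
        if bmask_p is not None and bmask_p.exists():
            barriers, _ = eio.read_mask(bmask_p)
        else:
            barriers = [g for g, _ in
                        eio.read_features(config.path("barriers", "barriers.geojson"))]
        delta = interpolate_with_barriers(
            samples, barriers, mhhw_grid,
            idw_power=float(config.param("idw_power")),
            idw_k=int(config.param("idw_k")),
        )
        eio.write_raster(delta, out_dir / "delta.asc")
        ex50 = assemble_ex50(sealed, delta)
        eio.write_raster(ex50, out_dir / "ex50.asc")
        _sidecar(out_dir, stage,
                 {"mhhw": mhhw_p, "units": units_p, "gauges": gauges_p,
                  "shoreline": shore_p},
                 {"idw_power": float(config.param("idw_power")),
                  "idw_k": int(config.param("idw_k")),
                  "snap_tolerance_m": float(config.param("snap_tolerance_m"))})
        return {"surface": str(out_dir / "ex50.asc")}

    if stage == "extent":
        dem_p = _require(config.path("dem", "dem.asc"), "simulate", stage)
        ex50_p = _require(config.path("ex50", "ex50.asc"), "surface", stage)
        nwi_p = _require(config.path("nwi", "nwi.geojson"), "simulate", stage)
        dem = eio.read_raster(dem_p)
        ex50 = eio.read_raster(ex50_p)
        extent = threshold_extent(dem, ex50)
        nwi = eio.read_nwi(nwi_p)
        extent = append_nwi_tidal(extent, nwi)
        mmu = float(config.param("mmu_ha"))
        if mmu > 0:
            extent = [e for e in extent if e.polygon.area / 10_000.0 >= mmu]
        eio.write_features(
            [(e.polygon, {"provenance": e.provenance, "estuary_id": e.estuary_id})
             for e in extent],
            out_dir / "extent.geojson",
        )
        _sidecar(out_dir, stage, {"dem": dem_p, "ex50": ex50_p, "nwi": nwi_p},
                 {"mmu_ha": mmu})
        return {"extent": str(out_dir / "extent.geojson")}

    if stage == "loss":
        extent_p = _require(config.path("extent", "extent.geojson"), "extent", stage)
        nwi_p = _require(config.path("nwi", "nwi.geojson"), "simulate", stage)
        est_p = _require(config.path("estuaries", "estuaries.csv"), "simulate", stage)
        extent = [ExtentPolygon(g, p["provenance"], p.get("estuary_id", ""))
                  for g, p in eio.read_features(extent_p)]
        nwi = eio.read_nwi(nwi_p)
        estuaries = eio.read_estuaries(est_p)
        kept, excluded = filter_analysis_scope(estuaries)
        kept_ids = {e.estuary_id for e in kept}
        rule_gaps: list[str] = []
        classified = classify_extent(extent, nwi, rule_gaps=rule_gaps)
        classified["estuary_id"] = classified["estuary_id"].replace("", "unassigned")
        in_scope = classified[
            classified["estuary_id"].isin(kept_ids | {"unassigned"})].copy()
        in_scope["group"] = in_scope["estuary_id"]
        summary = summarize_loss(in_scope, group_col="group")
        eio.write_features(
            [(row["geometry"], {"label": row["label"], "reason": row["reason"],
                                "area_ha": row["area_ha"],
                                "estuary_id": row["estuary_id"]})
             for _, row in classified.iterrows()],
            out_dir / "classified.geojson",
        )
        summary.to_csv(out_dir / "loss_summary.csv", index=False)
        pd.DataFrame(excluded, columns=["estuary_id", "reason"]).to_csv(
            out_dir / "scope_exclusions.csv", index=False)
        _sidecar(out_dir, stage,
                 {"extent": extent_p, "nwi": nwi_p, "estuaries": est_p},
                 {"rule_gaps": sorted(set(rule_gaps))})
        return {"loss": str(out_dir / "loss_summary.csv")}

    if stage == "agree":
        local_p = config.path("local")
        if local_p is None:
            raise FileNotFoundError(
                "stage 'agree' needs a local classification layer; set "
                "local=<path> in the configuration")
        _require(local_p, "external", stage)
        region_p = _require(config.path("classified", "classified.geojson"),
                            "loss", stage)
        preset = str(config.param("preset"))
        region = [(g, p["label"]) for g, p in eio.read_features(region_p)]
        local = [(g, map_local_categories(str(p.get("local_label", "")), preset))
                 for g, p in eio.read_features(local_p)]
        tab = crosstab_agreement(region, local)
        metrics = agreement_metrics(tab, int(config.param("decimals")))
        rows = [
            {"determination": "Agree: lost", "area_ha": tab.agree_lost_ha,
             "pct": metrics["agree_lost_pct"]},
            {"determination": "Agree: retained", "area_ha": tab.agree_retained_ha,
             "pct": metrics["agree_retained_pct"]},
            {"determination": "Disagree: Region = lost, Local = retained",
             "area_ha": tab.disagree_region_lost_ha,
             "pct": metrics["disagree_region_lost_pct"]},
            {"determination": "Disagree: Region = retained, Local = lost",
             "area_ha": tab.disagree_region_retained_ha,
             "pct": metrics["disagree_region_retained_pct"]},
            {"determination": "Not classified in Local",
             "area_ha": tab.unclassified_local_ha, "pct": None},
            {"determination": "Total area (agree + disagree)",
             "area_ha": metrics["total_classified_ha"], "pct": None},
            {"determination": "Total agreement",
             "area_ha": metrics["total_agreement_ha"],
             "pct": metrics["total_agreement_pct"]},
        ]
        pd.DataFrame(rows).to_csv(out_dir / "agreement.csv", index=False)
        _sidecar(out_dir, stage, {"region": region_p, "local": local_p},
                 {"preset": preset})
        return {"agree": str(out_dir / "agreement.csv")}

    raise AssertionError("unreachable")
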