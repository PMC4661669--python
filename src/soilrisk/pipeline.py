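"""Pipeline orchestration: simulate -> health -> factory -> map ->
integrate -> report, with deterministic outputs and a machine-readable
run summary.

Any contiguous suffix of the stage list can be run against a directory
holding the earlier stages' outputs; re-running with identical config
and seed reproduces byte-identical CSV/ASC files.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np

from . import io
from .config import Config, LandUseClass, RiskLevel
from .factory import comprehensive_risk_index
from .health import assess_samples
from .idw import GridSpec, classify_raster, idw_grid, loo_rmse
from .overlay import (LAND_USE_CODES, factory_surface, overlay,
                      summarize_classes)
from .scene import generate_scene, grid_spec_for

log = logging.getLogger("soilrisk")

STAGES = ("simulate", "health", "factory", "map", "integrate", "report")

FILES = {
    "samples": "samples.csv",
    "factories": "factories.csv",
    "landuse": "landuse.asc",
    "truth": "truth.json",
    "health": "health_results.csv",
    "cri": "cri_results.csv",
    "tcr": "tcr.asc",
    "tcr_class": "tcr_class.asc",
    "integrated": "integrated.asc",
    "factory_cri": "factory_cri.asc",
    "summary": "summary.json",
}


def scenario_lookup(cfg: Config, landuse_raster):
    """Scenario selector: the scenario of the sample's land-use cell,
    falling back to residential off-grid or on nodata cells."""
    fallback = cfg.scenarios[LandUseClass.residential]

    def pick(sample):
        try:
            row, col = landuse_raster.spec.rowcol_of(sample.x, sample.y)
        except ValueError:
            return fallback
        if landuse_raster.mask[row, col]:
            return fallback
        code = int(landuse_raster.values[row, col])
        return cfg.scenarios.get(LAND_USE_CODES.get(code), fallback)

    return pick


def run_pipeline(cfg: Config, out_dir, seed: int | None = None,
                 stages=STAGES) -> dict:
    """Execute the requested stage suffix; returns the run summary."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = cfg.seed if seed is None else int(seed)
    stages = tuple(stages)
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stage(s) {sorted(unknown)}")
    order = [s for s in STAGES if s in stages]

    summary: dict = {
        "seed": seed,
        "config_digest": io.config_digest(cfg.raw),
        "stages": order,
        "timings_s": {},
    }
    if (out / FILES["summary"]).exists():
        try:
            with open(out / FILES["summary"], "r", encoding="utf-8") as fh:
                prev = json.load(fh)
            for key in ("tcr_range", "thi_range", "loo_rmse_tcr",
                        "cri_distribution", "integrated_areas"):
                if key in prev:
                    summary.setdefault(key, prev[key])
        except (json.JSONDecodeError, OSError):
            pass

    cell = cfg.grid["cell_size"]
    spec = grid_spec_for(cfg.scene, cell, nodata=cfg.grid["nodata"])

    for stage in order:
        t0 = time.perf_counter()
        log.info("stage %s starting", stage)
        _run_stage(stage, cfg, out, seed, spec, summary)
        summary["timings_s"][stage] = round(time.perf_counter() - t0, 4)
        log.info("stage %s done in %.3fs", stage, summary["timings_s"][stage])

    with open(out / FILES["summary"], "w", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return summary


def _need(out: Path, key: str, stage: str) -> Path:
    p = out / FILES[key]
    if not p.exists():
        raise FileNotFoundError(
            f"stage {stage!r}: required input {p} missing "
            f"(run the earlier stages first)"
        )
    return p


def _run_stage(stage: str, cfg: Config, out: Path, seed: int,
               spec: GridSpec, summary: dict) -> None:
    if stage == "simulate":
        scene = generate_scene(cfg.scene, seed, cfg.ruleset, cell_size=spec.cell_size)
        io.write_samples(scene.samples, out / FILES["samples"],
                         pollutant_order=list(cfg.pollutants))
        io.write_factories(scene.factories, out / FILES["factories"])
        io.write_raster(scene.landuse, out / FILES["landuse"])
        io.write_truth(scene.truth, out / FILES["truth"])
        summary["n_samples"] = len(scene.samples)
        summary["n_factories"] = len(scene.factories)

    elif stage == "health":
        samples = io.read_samples(_need(out, "samples", stage))
        landuse = io.read_raster(_need(out, "landuse", stage))
        results = assess_samples(samples, cfg.pollutants,
                                 scenario_lookup(cfg, landuse), cfg.thresholds)
        io.write_health_results(results, samples, out / FILES["health"])
        tcrs = [r.tcr for r in results]
        this = [r.thi for r in results]
        summary["tcr_range"] = [min(tcrs), max(tcrs)]
        summary["thi_range"] = [min(this), max(this)]

    elif stage == "factory":
        factories = io.read_factories(_need(out, "factories", stage))
        results = [comprehensive_risk_index(f, cfg.ruleset, cfg.thresholds)
                   for f in factories]
        io.write_cri_results(results, factories, out / FILES["cri"])
        dist = {lvl.name: 0 for lvl in RiskLevel}
        for r in results:
            dist[r.level.name] += 1
        summary["cri_distribution"] = dist

    elif stage == "map":
        df = io.read_health_results(_need(out, "health", stage))
        landuse = io.read_raster(_need(out, "landuse", stage))
        pts = df[["x", "y"]].to_numpy()
        vals = df["tcr"].to_numpy()
        tcr_raster = idw_grid(pts, vals, landuse.spec, cfg.idw, mask=landuse.mask)
        io.write_raster(tcr_raster, out / FILES["tcr"])
        io.write_raster(classify_raster(tcr_raster, cfg.thresholds.tcr_breaks),
                        out / FILES["tcr_class"])
        summary["loo_rmse_tcr"] = loo_rmse(pts, vals, cfg.idw)

    elif stage == "integrate":
        tcr_class = io.read_raster(_need(out, "tcr_class", stage))
        landuse = io.read_raster(_need(out, "landuse", stage))
        cri_df = io.read_cri_results(_need(out, "cri", stage))
        surface = factory_surface(
            cri_df[["x", "y", "cri"]].itertuples(index=False),
            landuse.spec, cfg.idw, mask=landuse.mask)
        provenance = {
            "config_digest": summary["config_digest"],
            "seed": summary["seed"],
            "inputs": {
                k: io.file_digest(out / FILES[k])
                for k in ("tcr_class", "landuse", "cri")
            },
        }
        result = overlay(tcr_class, landuse, cfg.matrix,
                         factory_cri=surface, provenance=provenance)
        io.write_raster(result.integrated, out / FILES["integrated"])
        io.write_raster(surface, out / FILES["factory_cri"])
        summary["provenance"] = provenance

    elif stage == "report":
        integrated = io.read_raster(_need(out, "integrated", stage))
        summary["integrated_areas"] = summarize_classes(integrated)
        if (out / FILES["factory_cri"]).exists():
            surface = io.read_raster(out / FILES["factory_cri"])
            vals = surface.valid_values()
            summary["factory_cri_surface_range"] = [float(vals.min()), float(vals.max())]
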