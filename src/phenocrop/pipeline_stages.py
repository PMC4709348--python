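"""End-to-end pipeline execution: config in, run directory out.

Chains the stages in method order — scene acquisition (synthetic
generation or manifest loading), radiometric correction of raw scenes,
per-period NDVI compositing, segmentation of one scene per period, zonal
attribution, water masking, threshold classification with the slope mask,
the four-period overlay, and stratified accuracy/area assessment — and
writes every intermediate artifact as text rasters / GeoJSON / CSV plus a
machine-readable ``report.json``.

Reports contain no timestamps, and every random draw descends from the
single configured seed, so identical config + seed reproduce the run
byte-for-byte.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, fields as dc_fields
from pathlib import Path

import numpy as np
import pandas as pd
from shapely.geometry import mapping, shape

from . import accuracy as acc
from . import classification_change as cc
from . import compositing, radiometry, segmentation
from . import synthetic_scene as synth
from .grid import RasterGrid, write_raster
from .io_pipeline import SamplePoint, load_manifest, read_points, write_points

log = logging.getLogger(__name__)

PERIODS = ("A", "B", "C", "D")


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage and the input."""


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            log.info("stage %s: start", name)
            try:
                return fn(*args, **kwargs)
            except StageError:
                raise
            except Exception as e:
                raise StageError(f"stage '{name}' failed: {e}") from e
        return wrapped
    return deco


def write_segments_geojson(layer: segmentation.SegmentLayer, path: Path) -> None:
    feats = []
    for seg in layer.segments.values():
        if seg.polygon is None:
            continue
        feats.append({
            "type": "Feature",
            "geometry": mapping(seg.polygon),
            "properties": {
                "id": seg.id, "n_cells": seg.n_cells,
                "area_km2": seg.area_km2, "perimeter_m": seg.perimeter_m,
                "mean_ndvi_diff": None if np.isnan(seg.mean_ndvi_diff)
                else seg.mean_ndvi_diff,
                "mean_slope": None if np.isnan(seg.mean_slope)
                else seg.mean_slope,
                "class": seg.class_label, "masked": seg.masked,
            },
        })
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps({"type": "FeatureCollection", "features": feats},
                               sort_keys=True))


def read_water_geojson(path: Path) -> list:
    doc = json.loads(Path(path).read_text())
    feats = doc["features"] if doc.get("type") == "FeatureCollection" else [doc]
    return [shape(f["geometry"]) for f in feats]


def write_water_geojson(polys: list, path: Path) -> None:
    feats = [{"type": "Feature", "geometry": mapping(p), "properties": {}}
             for p in polys]
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps({"type": "FeatureCollection", "features": feats},
                               sort_keys=True))


# ---------------------------------------------------------------------------
# Inputs


@_stage("synth")
def _generate(cfg: dict, seed: int) -> synth.TruthBundle:
    tpl_kwargs = dict(cfg.get("synthetic") or {})
    tpl_kwargs.setdefault("seed", seed)
    allowed = {f.name for f in dc_fields(synth.SceneTemplate)}
    unknown = set(tpl_kwargs) - allowed
    if unknown:
        raise ValueError(f"unknown synthetic template keys: {sorted(unknown)}")
    return synth.generate_scene_collection(synth.SceneTemplate(**tpl_kwargs))


@_stage("correct")
def _correct_scene(scene, record):
    """DN scenes get DOS correction; reflectance scenes pass through."""
    if scene.value_kind != "digital_number":
        return scene
    caldoc = record.calibration
    if not caldoc:
        raise ValueError(f"scene {record.date_string} is digital_number but "
                         "has no calibration metadata")
    meta = radiometry.CalibrationMeta(
        bands={r: radiometry.BandCalibration(**b)
               for r, b in caldoc["bands"].items()},
        solar_zenith_deg=caldoc["solar_zenith_deg"],
        view_zenith_deg=caldoc.get("view_zenith_deg", 0.0),
        earth_sun_distance_au=caldoc.get("earth_sun_distance_au", 1.0))
    return radiometry.dos_correct(scene, meta,
                                  caldoc.get("dark_fraction", 0.01))


# ---------------------------------------------------------------------------
# Execution


def execute(cfg: dict, base_dir: Path = Path(".")) -> Path:
    seed = int(cfg.get("seed", 1))
    outdir = Path(cfg.get("outdir", "phenocrop_run"))
    if not outdir.is_absolute():
        outdir = base_dir / outdir
    outdir.mkdir(parents=True, exist_ok=True)

    # ---- acquire scenes, DEM, water, points ------------------------------
    synthetic_run = cfg.get("synthetic") is not None or "manifest" not in cfg
    if synthetic_run:
        bundle = _generate(cfg, seed)
        dem = bundle.dem
        water = bundle.water
        scenes_by_period = {p: bundle.scenes_of(p) for p in PERIODS}
        seg_scene = {p: bundle.segmentation_scene(p) for p in PERIODS}
        training = bundle.training
        validation = dict(bundle.validation)
        write_points(training + validation["D"], outdir / "points.csv")
        write_water_geojson(water, outdir / "water.geojson")
        for p in PERIODS:
            write_raster(bundle.truth[p], outdir / "truth" / f"{p}.asc")
        true_areas = bundle.true_crop_area_km2
    else:
        manifest = load_manifest(base_dir / cfg["manifest"])
        if "dem" not in cfg:
            raise StageError("stage 'slope-masking' failed: no DEM configured "
                             "(config key 'dem' is required for manifest runs)")
        dem = _read_grid(base_dir / cfg["dem"])
        water = (read_water_geojson(base_dir / cfg["water"])
                 if cfg.get("water") else [])
        scenes_by_period = {}
        seg_scene = {}
        for info in manifest.periods:
            loaded = []
            for rec in info.scenes:
                scene = rec.load(manifest.base_dir)
                scene = _correct_scene(scene, rec)
                loaded.append((rec, scene))
            scenes_by_period[info.id] = [s for _, s in loaded]
            seg_recs = [s for r, s in loaded
                        if r.use_for_segmentation and r.season == "spring"]
            seg_scene[info.id] = seg_recs[0] if seg_recs else \
                [s for r, s in loaded if r.season == "spring"][0]
        pts = read_points(base_dir / cfg["points"]) if cfg.get("points") else []
        training = [p for p in pts if p.role == "training"]
        vpts = [p for p in pts if p.role == "validation"]
        validation = {p: vpts for p in scenes_by_period}
        true_areas = None

    # ---- composites ------------------------------------------------------
    composites = {}
    for p, scenes in scenes_by_period.items():
        comp = compositing.build_period_composite(p, scenes)
        composites[p] = comp
        d = outdir / "composites"
        write_raster(comp.spring_mvc, d / f"{p}_spring_mvc.asc")
        write_raster(comp.summer_median, d / f"{p}_summer_median.asc")
        write_raster(comp.difference, d / f"{p}_difference.asc")
        write_raster(comp.spring_count, d / f"{p}_spring_count.asc")
        write_raster(comp.summer_count, d / f"{p}_summer_count.asc")

    # ---- slope -----------------------------------------------------------
    ref = next(iter(composites.values())).difference
    if not dem.same_geometry(ref):
        raise StageError("stage 'slope-masking' failed: DEM geometry does not "
                         "match the imagery grid")
    slope = cc.slope_grid(dem)
    write_raster(slope, outdir / "slope.asc")

    # ---- segmentation + attributes + water mask --------------------------
    seg_cfg = dict(cfg.get("segmentation") or {})
    if synthetic_run:
        # synthetic scenes are [0, 1] reflectance; the DN-scale default
        # would merge the whole scene into one object
        seg_cfg.setdefault("scale", segmentation.REFLECTANCE_SCALE)
    params = segmentation.SegmentationParams(**seg_cfg)
    layers = {}
    for p in scenes_by_period:
        layer = segmentation.multiresolution_segment(seg_scene[p], params,
                                                     seed=seed)
        segmentation.zonal_attributes(
            layer, {"ndvi_diff": composites[p].difference, "slope": slope})
        segmentation.mask_water(layer, water)
        layers[p] = layer
        write_raster(layer.labels, outdir / "segments" / f"{p}_labels.asc")
        write_segments_geojson(layer, outdir / "segments" / f"{p}.geojson")

    # ---- thresholds ------------------------------------------------------
    thr_cfg = dict(cfg.get("thresholds") or {})
    mode = thr_cfg.get("mode", "derived" if training else "stated")
    if mode == "derived":
        if not training:
            raise StageError("stage 'thresholds' failed: derived mode needs "
                             "training points")
        stats = cc.derive_thresholds(
            training, composites["D"].difference, slope,
            k_ndvi=float(thr_cfg.get("k_ndvi", cc.DEFAULT_K_NDVI)),
            k_slope=float(thr_cfg.get("k_slope", cc.DEFAULT_K_SLOPE)))
    else:
        stats = cc.TrainingStats.from_defaults()
        if "t_ndvi" in thr_cfg:
            stats.t_ndvi = float(thr_cfg["t_ndvi"])
        if "t_slope" in thr_cfg:
            stats.t_slope = float(thr_cfg["t_slope"])
    (outdir / "thresholds.json").write_text(json.dumps(
        {k: v for k, v in asdict(stats).items() if k != "per_cover"}
        | {"per_cover": stats.per_cover}, sort_keys=True, indent=1,
        default=float))

    # ---- classification --------------------------------------------------
    classifications = {}
    for p, layer in layers.items():
        cl = cc.classify_period(layer, stats, period=p)
        classifications[p] = cl
        write_raster(cl.crop_mask, outdir / "classification" / f"{p}_crop.asc")

    # ---- overlay ---------------------------------------------------------
    overlay = None
    if set(PERIODS).issubset(classifications):
        ov_cfg = dict(cfg.get("overlay") or {})
        overlay = cc.overlay_periods(
            classifications,
            min_report_area_km2=float(ov_cfg.get("min_report_area_km2", 100.0)))
        write_raster(overlay.code_grid, outdir / "overlay" / "codes.asc")
        rows = [{"code": k,
                 "periods": "".join(p for p, b in zip("ABCD", (3, 2, 1, 0))
                                    if k >> b & 1),
                 "area_km2": v}
                for k, v in sorted(overlay.area_by_code.items())]
        pd.DataFrame(rows).to_csv(outdir / "overlay" / "combination_areas.csv",
                                  index=False)

    # ---- accuracy / adjusted areas ---------------------------------------
    a_tot = cfg.get("area_total_km2")
    if a_tot is None:
        a_tot = sum(s.area_km2 for s in layers[next(iter(layers))].segments.values()
                    if not s.masked)
    report: dict = {"seed": seed, "area_total_km2": float(a_tot),
                    "thresholds": {"t_ndvi": stats.t_ndvi,
                                   "t_slope": stats.t_slope},
                    "periods": {}}
    est_rows = []
    for p, cl in classifications.items():
        entry: dict = {"mapped_crop_area_km2": cl.crop_area_km2,
                       "w_crop": cl.proportions[cc.CROP]}
        if true_areas is not None:
            entry["true_crop_area_km2"] = true_areas[p]
        pts = validation.get(p) or []
        if pts:
            m = acc.build_error_matrix(pts, cl)
            stats_p = acc.accuracy_stats(m, W=cl.proportions)
            est = acc.adjusted_area(m, cl.proportions, float(a_tot))
            entry.update({
                "error_matrix": m.counts.astype(int).tolist(),
                "user_accuracy": stats_p.user,
                "producer_accuracy": stats_p.producer,
                "overall_accuracy": stats_p.overall,
                "kappa": stats_p.kappa,
                "adjusted_crop_area_km2": est.estimate_km2,
                "ci_half_width_km2": est.half_width_km2,
            })
            est_rows.append({"period": p, "mapped_km2": cl.crop_area_km2,
                             "adjusted_km2": est.estimate_km2,
                             "half_width_km2": est.half_width_km2})
        report["periods"][p] = entry
    if overlay is not None:
        report["overlay"] = {
            "categories_km2": overlay.categories,
            "union_km2": overlay.union_area_km2,
            "area_by_code_km2": {str(k): v
                                 for k, v in overlay.area_by_code.items()},
        }
    (outdir / "report.json").write_text(
        json.dumps(report, sort_keys=True, indent=1, default=float))
    if est_rows:
        pd.DataFrame(est_rows).to_csv(outdir / "area_estimates.csv", index=False)
    log.info("run complete: %s", outdir)
    return outdir


def _read_grid(path: Path) -> RasterGrid:
    from .grid import read_raster
    return read_raster(path)
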