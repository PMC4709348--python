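"""Domain types, manifest/config handling, point I/O and the pipeline runner.

A *period manifest* is a YAML file describing the four analysis epochs
(A pre-Anfal 1984-1987, B post-Anfal 1989-1991, C reconstruction 1998-2002,
D present 2011-2014) and the scenes belonging to each, with acquisition
dates encoded as ``YYYY-DDD`` (year and Julian day of year).  Spring scenes
are the pre-harvest window (March-June), summer scenes post-harvest
(July-September).

The :func:`run_pipeline` entry point chains every stage — synthetic scene
generation (or scene loading), radiometric correction, per-period NDVI
compositing, segmentation of one scene per period, threshold
classification with slope and water masking, the four-period overlay, and
stratified accuracy/area assessment — writing all intermediate and final
artifacts to a run directory.
"""

from __future__ import annotations

import datetime
import json
import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .grid import RasterGrid, read_raster, write_raster

log = logging.getLogger(__name__)

__all__ = [
    "BandStack",
    "PeriodInfo",
    "PeriodManifest",
    "SamplePoint",
    "SceneRecord",
    "parse_scene_date",
    "season_of_date",
    "load_manifest",
    "read_points",
    "write_points",
    "run_pipeline",
    "configure_logging",
]

PERIOD_ORDER = ("A", "B", "C", "D")
SEASONS = ("spring", "summer")
VALUE_KINDS = ("digital_number", "toa_reflectance", "surface_reflectance")

# Pre/post-harvest month windows for the winter-cereal calendar.
SEASON_MONTHS = {"spring": (3, 6), "summer": (7, 9)}


def configure_logging(level: str = "INFO") -> None:
    logging.basicConfig(
        level=getattr(logging, level.upper(), logging.INFO),
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
    )


# ---------------------------------------------------------------------------
# Domain types


@dataclass
class BandStack:
    """One acquisition's co-registered bands plus acquisition metadata.

    ``bands`` maps role ("blue", "green", "red", "nir") to a RasterGrid;
    ``quality`` is an optional per-cell contamination flag grid (nonzero =
    cloud/snow/haze) honoured by NDVI and compositing.
    """

    bands: dict[str, RasterGrid]
    acquisition_date: datetime.date
    season: str
    period: str
    value_kind: str = "surface_reflectance"
    quality: RasterGrid | None = None
    provenance: str = ""

    def __post_init__(self) -> None:
        if self.season not in SEASONS:
            raise ValueError(f"season must be one of {SEASONS}, got {self.season!r}")
        if self.value_kind not in VALUE_KINDS:
            raise ValueError(f"value_kind must be one of {VALUE_KINDS}")
        grids = list(self.bands.values())
        for g in grids[1:]:
            grids[0].require_same_geometry(g, "band")
        if self.quality is not None and grids:
            grids[0].require_same_geometry(self.quality, "quality mask")

    @property
    def geometry(self) -> RasterGrid:
        return next(iter(self.bands.values()))

    def with_bands(self, bands: dict[str, RasterGrid], value_kind: str | None = None,
                   provenance: str | None = None) -> "BandStack":
        return replace(
            self, bands=bands,
            value_kind=self.value_kind if value_kind is None else value_kind,
            provenance=self.provenance if provenance is None else provenance,
        )


@dataclass(frozen=True)
class SamplePoint:
    """A labeled ground point used for training or validation."""

    x: float
    y: float
    reference_label: str
    role: str  # "training" | "validation"

    def __post_init__(self) -> None:
        if self.role not in ("training", "validation"):
            raise ValueError(f"sample role must be training/validation, got {self.role!r}")


@dataclass
class SceneRecord:
    """Manifest entry for one acquisition (band rasters may be unresolved)."""

    date: datetime.date
    date_string: str
    season: str
    period: str
    value_kind: str = "surface_reflectance"
    band_paths: dict[str, str] = field(default_factory=dict)
    quality_path: str | None = None
    use_for_segmentation: bool = False
    calibration: dict | None = None

    def load(self, base: Path) -> BandStack:
        bands = {role: read_raster(base / p) for role, p in self.band_paths.items()}
        quality = read_raster(base / self.quality_path) if self.quality_path else None
        return BandStack(bands=bands, acquisition_date=self.date, season=self.season,
                         period=self.period, value_kind=self.value_kind, quality=quality)


@dataclass
class PeriodInfo:
    id: str
    label: str
    year_range: tuple[int, int]
    scenes: list[SceneRecord] = field(default_factory=list)

    def scenes_in_season(self, season: str) -> list[SceneRecord]:
        return [s for s in self.scenes if s.season == season]


@dataclass
class PeriodManifest:
    periods: list[PeriodInfo]
    crs_id: str = "local"
    base_dir: Path = Path(".")

    def period(self, pid: str) -> PeriodInfo:
        for p in self.periods:
            if p.id == pid:
                return p
        raise KeyError(f"no period {pid!r} in manifest")

    @property
    def n_scenes(self) -> int:
        return sum(len(p.scenes) for p in self.periods)

    def season_counts(self) -> dict[tuple[str, str], int]:
        return {(p.id, s): len(p.scenes_in_season(s))
                for p in self.periods for s in SEASONS}


# ---------------------------------------------------------------------------
# Dates and manifest parsing


def parse_scene_date(text: str) -> datetime.date:
    """Parse a ``YYYY-DDD`` year/Julian-day scene date, e.g. ``"1984-158"``."""
    try:
        year_s, doy_s = text.split("-")
        year, doy = int(year_s), int(doy_s)
    except ValueError:
        raise ValueError(f"scene date {text!r} is not of the form YYYY-DDD") from None
    if not 1 <= doy <= 366:
        raise ValueError(f"day-of-year {doy} out of range in scene date {text!r}")
    return datetime.date(year, 1, 1) + datetime.timedelta(days=doy - 1)


def season_of_date(date: datetime.date) -> str | None:
    """Season window containing the date, or None if outside both."""
    for season, (m0, m1) in SEASON_MONTHS.items():
        if m0 <= date.month <= m1:
            return season
    return None


def load_manifest(config: str | Path) -> PeriodManifest:
    """Load and validate a period/scene manifest YAML file.

    Raises ``ValueError`` if a scene's year falls outside its period's
    declared year range or a period lacks a spring or summer scene.  A
    scene whose calendar date falls outside its tagged season window is
    accepted with a warning (archive scene lists occasionally stretch the
    windows, e.g. an early-February spring acquisition).
    """
    config = Path(config)
    if not config.exists():
        raise FileNotFoundError(f"manifest not found: {config}")
    doc = yaml.safe_load(config.read_text())
    periods: list[PeriodInfo] = []
    for pdoc in doc.get("periods", []):
        pid = str(pdoc["id"])
        y0, y1 = (int(v) for v in pdoc["years"])
        info = PeriodInfo(id=pid, label=str(pdoc.get("label", pid)), year_range=(y0, y1))
        for sdoc in pdoc.get("scenes", []):
            date_s = str(sdoc["date"])
            date = parse_scene_date(date_s)
            if not y0 <= date.year <= y1:
                raise ValueError(
                    f"scene {date_s} lies outside period {pid} year range {y0}-{y1}")
            season = str(sdoc["season"])
            if season not in SEASONS:
                raise ValueError(f"scene {date_s}: unknown season {season!r}")
            window = season_of_date(date)
            if window != season:
                warnings.warn(
                    f"scene {date_s} tagged {season} falls outside the "
                    f"{season} month window", stacklevel=2)
            info.scenes.append(SceneRecord(
                date=date, date_string=date_s, season=season, period=pid,
                value_kind=str(sdoc.get("value_kind", "surface_reflectance")),
                band_paths=dict(sdoc.get("bands", {})),
                quality_path=sdoc.get("quality"),
                use_for_segmentation=bool(sdoc.get("segmentation", False)),
                calibration=sdoc.get("calibration"),
            ))
        for season in SEASONS:
            if not info.scenes_in_season(season):
                raise ValueError(f"period {pid} has no {season} scene")
        periods.append(info)
    ids = [p.id for p in periods]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate period ids in manifest")
    return PeriodManifest(periods=periods, crs_id=str(doc.get("crs", "local")),
                          base_dir=config.parent)


# ---------------------------------------------------------------------------
# Point I/O  (CSV with columns x, y, label, role)


def read_points(path: str | Path) -> list[SamplePoint]:
    df = pd.read_csv(path)
    required = {"x", "y", "label", "role"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: points CSV needs columns {sorted(required)}")
    return [SamplePoint(float(r.x), float(r.y), str(r.label), str(r.role))
            for r in df.itertuples()]


def write_points(points: list[SamplePoint], path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        [{"x": p.x, "y": p.y, "label": p.reference_label, "role": p.role}
         for p in points]
    ).to_csv(path, index=False)
    return path


# ---------------------------------------------------------------------------
# Pipeline runner (stage modules imported lazily to keep the layering acyclic)


def run_pipeline(config: str | Path, outdir: str | Path | None = None,
                 seed: int | None = None) -> Path:
    """Run the full mapping chain from a declarative config file.

    The config must either request synthetic scenes (``synthetic:`` block)
    or reference a manifest of real scenes plus DEM, water and point files.
    Returns the run directory containing per-period composites, segment
    layers, classifications, the overlay, and area/accuracy reports.
    """
    from . import pipeline_stages

    config = Path(config)
    cfg = yaml.safe_load(config.read_text()) or {}
    if seed is not None:
        cfg["seed"] = int(seed)
    if outdir is not None:
        cfg["outdir"] = str(outdir)
    return pipeline_stages.execute(cfg, base_dir=config.parent)
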