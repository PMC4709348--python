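"""Threshold derivation, winter-crop classification, and multi-period overlay.

Classification is a two-threshold rule on segment attributes.  A segment
is *active winter cropland* iff

    mean NDVI difference >= T_ndvi   (inclusive)
and mean slope          <  T_slope  (slopes at or above the cut are filtered)
and it is not water-masked.

T_ndvi comes from training statistics as mean(cropland NDVI difference)
minus k standard deviations (k = 2.3 keeps ~99 % of a normal cropland
population); T_slope is mean(cropland slope) plus k standard deviations
(k = 2), which removes the grassland confusers concentrated on steeper
terrain.  The Duhok study's published decision values are T_ndvi = 0.30291
and T_slope = 7.625 degrees; these are the pipeline defaults for
stated-threshold runs, while :func:`derive_thresholds` recomputes the rule
from fresh training data.

The per-period boolean crop maps are overlaid on the common raster grid
into a 4-bit presence code per cell (bit order A, B, C, D), from which the
change categories of interest are read off: stable cropland (all four
periods), land reclaimed after the post-Anfal gap (B, C and D only),
abandonment limited to period B (all but B), and new cultivation appearing
only in the present period.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .grid import RasterGrid
from .io_pipeline import SamplePoint
from .segmentation import SegmentLayer

log = logging.getLogger(__name__)

__all__ = [
    "TrainingStats",
    "PeriodClassification",
    "OverlayResult",
    "DEFAULT_T_NDVI",
    "DEFAULT_T_SLOPE",
    "derive_thresholds",
    "slope_grid",
    "classify_period",
    "overlay_periods",
    "CROP",
    "OTHER",
]

CROP = "active_winter_cropland"
OTHER = "other"

# Published decision values of the Duhok winter-crop assessment.
DEFAULT_T_NDVI = 0.30291
DEFAULT_T_SLOPE = 7.625
DEFAULT_K_NDVI = 2.3
DEFAULT_K_SLOPE = 2.0


@dataclass
class TrainingStats:
    """Training-sample statistics and the thresholds derived from them."""

    ndvi_mean: float
    ndvi_sd: float
    k_ndvi: float
    t_ndvi: float
    slope_mean: float
    slope_sd: float
    k_slope: float
    t_slope: float
    n_cropland: int
    n_total: int
    per_cover: dict[str, dict[str, float]] = field(default_factory=dict)

    @classmethod
    def from_defaults(cls) -> "TrainingStats":
        """The published Duhok decision thresholds (stated-thresholds runs)."""
        return cls(ndvi_mean=0.5713, ndvi_sd=0.113, k_ndvi=DEFAULT_K_NDVI,
                   t_ndvi=DEFAULT_T_NDVI, slope_mean=float("nan"),
                   slope_sd=float("nan"), k_slope=DEFAULT_K_SLOPE,
                   t_slope=DEFAULT_T_SLOPE, n_cropland=51, n_total=333)


@dataclass
class PeriodClassification:
    period: str
    layer: SegmentLayer
    crop_area_km2: float
    proportions: dict[str, float]   # W_i over the unmasked study area
    crop_mask: RasterGrid           # 1 = active winter cropland


@dataclass
class OverlayResult:
    """Four-period presence-code overlay with per-code area accounting."""

    code_grid: RasterGrid                  # 0..15, bit 3 = A ... bit 0 = D
    area_by_code: dict[int, float]         # km2, includes code 0
    categories: dict[str, float]           # named change categories, km2
    union_area_km2: float
    min_report_area_km2: float
    reported_codes: list[int]              # codes above the map-report filter

    @staticmethod
    def code_of(present: dict[str, bool]) -> int:
        code = 0
        for bit, pid in enumerate("DCBA"):
            if present.get(pid, False):
                code |= 1 << bit
        return code


def _sample_at_points(points: list[SamplePoint], grid: RasterGrid) -> np.ndarray:
    vals = []
    for p in points:
        r, c = grid.index_of(p.x, p.y)
        if not (0 <= r < grid.shape[0] and 0 <= c < grid.shape[1]):
            raise ValueError(f"training point ({p.x}, {p.y}) outside the grid")
        vals.append(grid.values[r, c])
    return np.asarray(vals, dtype=float)


def derive_thresholds(train: list[SamplePoint], diff: RasterGrid,
                      slope: RasterGrid, k_ndvi: float = DEFAULT_K_NDVI,
                      k_slope: float = DEFAULT_K_SLOPE) -> TrainingStats:
    """Derive T_ndvi and T_slope from training points.

    T_ndvi = mean - k_ndvi * sd of the cropland points' NDVI difference;
    T_slope = mean + k_slope * sd of their slope.  Also tabulates
    mean/sd/median of the NDVI difference per cover label.  Sample
    standard deviations (ddof=1); at least two cropland points required.
    """
    train = [p for p in train if p.role == "training"]
    crop = [p for p in train if p.reference_label == "cropland"]
    if len(crop) < 2:
        raise ValueError("need at least 2 cropland training points "
                         "(standard deviation undefined otherwise)")
    diff_c = _sample_at_points(crop, diff)
    slope_c = _sample_at_points(crop, slope)
    mu, sd = float(np.mean(diff_c)), float(np.std(diff_c, ddof=1))
    smu, ssd = float(np.mean(slope_c)), float(np.std(slope_c, ddof=1))
    per_cover: dict[str, dict[str, float]] = {}
    for label in sorted({p.reference_label for p in train}):
        pts = [p for p in train if p.reference_label == label]
        v = _sample_at_points(pts, diff)
        per_cover[label] = {
            "n": len(v), "mean": float(np.mean(v)),
            "sd": float(np.std(v, ddof=1)) if len(v) > 1 else float("nan"),
            "median": float(np.median(v)),
        }
    stats = TrainingStats(
        ndvi_mean=mu, ndvi_sd=sd, k_ndvi=k_ndvi, t_ndvi=mu - k_ndvi * sd,
        slope_mean=smu, slope_sd=ssd, k_slope=k_slope,
        t_slope=smu + k_slope * ssd,
        n_cropland=len(crop), n_total=len(train), per_cover=per_cover)
    log.info("thresholds: T_ndvi=%.5f (mu=%.4f sd=%.4f k=%.2f)  "
             "T_slope=%.3f deg (mu=%.3f sd=%.3f k=%.2f)",
             stats.t_ndvi, mu, sd, k_ndvi, stats.t_slope, smu, ssd, k_slope)
    return stats


def slope_grid(dem: RasterGrid) -> RasterGrid:
    """Terrain slope in degrees via the Horn 3x3 finite-difference operator.

    Edge cells use clamped (edge-replicated) neighborhoods.  Nodata DEM
    cells propagate to nodata slope.
    """
    if dem.shape[0] < 2 or dem.shape[1] < 2:
        raise ValueError("DEM must have at least 2 rows and 2 columns")
    z = np.pad(dem.values.astype(float), 1, mode="edge")
    a = z[:-2, :-2]; b_ = z[:-2, 1:-1]; c = z[:-2, 2:]
    d = z[1:-1, :-2];                   f = z[1:-1, 2:]
    g = z[2:, :-2];  h = z[2:, 1:-1];   i = z[2:, 2:]
    cell = dem.cell_size
    dzdx = ((c + 2 * f + i) - (a + 2 * d + g)) / (8 * cell)
    dzdy = ((g + 2 * h + i) - (a + 2 * b_ + c)) / (8 * cell)
    slope = np.degrees(np.arctan(np.hypot(dzdx, dzdy)))
    out = np.where(dem.mask, slope, dem.nodata)
    return dem.like(out)


def classify_period(layer: SegmentLayer, stats: TrainingStats,
                    period: str = "?") -> PeriodClassification:
    """Label segments as active winter cropland by the two-threshold rule.

    The NDVI-difference boundary is inclusive (a segment exactly at T_ndvi
    is cropland); the slope boundary is exclusive (a segment exactly at
    T_slope is filtered out).  Masked (water) segments are never cropland
    and are excluded from the proportion denominators.
    """
    crop_cells = np.zeros(layer.labels.shape, dtype=np.int8)
    labels = layer.labels.values
    area_crop = 0.0
    area_all = 0.0
    for seg in layer.segments.values():
        if seg.masked:
            seg.class_label = None
            continue
        if math.isnan(seg.mean_ndvi_diff) or math.isnan(seg.mean_slope):
            raise ValueError(f"segment {seg.id} lacks mean_ndvi_diff/mean_slope "
                             "attributes; run zonal_attributes first")
        is_crop = (seg.mean_ndvi_diff >= stats.t_ndvi
                   and seg.mean_slope < stats.t_slope)
        seg.class_label = CROP if is_crop else OTHER
        area_all += seg.area_km2
        if is_crop:
            area_crop += seg.area_km2
            crop_cells[labels == seg.id] = 1
    if area_all <= 0:
        raise ValueError("no unmasked segments to classify")
    w_crop = area_crop / area_all
    return PeriodClassification(
        period=period, layer=layer, crop_area_km2=area_crop,
        proportions={CROP: w_crop, OTHER: 1.0 - w_crop},
        crop_mask=layer.labels.like(crop_cells, nodata=-1),
    )


def overlay_periods(classifications: dict[str, PeriodClassification],
                    min_report_area_km2: float = 100.0) -> OverlayResult:
    """Overlay the four per-period crop maps into presence-code areas.

    Every cell of the common grid receives a 4-bit code (bit set = mapped
    as cropland that period).  Areas are tabulated for all 16 codes so the
    total — including the all-absent code — equals the study area.  The
    ``min_report_area_km2`` filter only limits which combinations are
    flagged for the map product (``reported_codes``); it never removes
    area from the totals.
    """
    try:
        stack = [classifications[p] for p in "ABCD"]
    except KeyError as e:
        raise ValueError(f"overlay requires periods A-D; missing {e}") from None
    ref = stack[0].crop_mask
    for cl in stack[1:]:
        ref.require_same_geometry(cl.crop_mask, "period crop mask")
    code = np.zeros(ref.shape, dtype=np.int64)
    for bit, cl in zip((3, 2, 1, 0), stack):  # A=bit3 ... D=bit0
        code |= (cl.crop_mask.values == 1).astype(np.int64) << bit
    cell_area = ref.cell_area_km2()
    counts = np.bincount(code.ravel(), minlength=16)
    area_by_code = {k: float(counts[k] * cell_area) for k in range(16)}
    categories = {
        "stable_all_periods": area_by_code[0b1111],
        "reclaimed_B_C_D": area_by_code[0b0111],
        "all_but_B": area_by_code[0b1011],
        "new_in_D": area_by_code[0b0001],
    }
    union = float(np.sum(counts[1:]) * cell_area)
    reported = [k for k in range(1, 16) if area_by_code[k] > min_report_area_km2]
    return OverlayResult(
        code_grid=ref.like(code, nodata=-1), area_by_code=area_by_code,
        categories=categories, union_area_km2=union,
        min_report_area_km2=min_report_area_km2, reported_codes=reported)
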