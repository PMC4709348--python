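"""Per-period NDVI compositing.

For each analysis period the pre-harvest (spring) scenes are reduced to a
per-cell maximum value composite (MVC), capturing each pixel at its
greenest and suppressing clouds, haze and single-year fallow; the
post-harvest (summer) scenes are reduced to a per-cell median, which
rejects both residual green fallow vegetation (a maximum would keep it)
and cloud-contaminated low outliers (a minimum would keep those).  The
spring-minus-summer difference of the two composites is the phenology
signal winter cereals are mapped from: green in spring, senesced after the
June harvest.

Cells flagged in a scene's quality mask enter compositing as nodata for
that scene; a difference cell is valid only where at least one valid
spring and one valid summer observation exist.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .grid import RasterGrid
from .radiometry import ndvi

log = logging.getLogger(__name__)

__all__ = [
    "NDVIComposite",
    "max_value_composite",
    "median_composite",
    "difference_layer",
    "build_period_composite",
]


@dataclass
class NDVIComposite:
    """Spring MVC, summer median and their difference for one period."""

    period: str
    spring_mvc: RasterGrid
    summer_median: RasterGrid
    difference: RasterGrid
    spring_count: RasterGrid  # contributing valid observations per cell
    summer_count: RasterGrid


def _stacked(grids: list[RasterGrid]) -> tuple[np.ndarray, RasterGrid]:
    if not grids:
        raise ValueError("compositing requires at least one grid")
    ref = grids[0]
    for g in grids[1:]:
        ref.require_same_geometry(g, "composite input")
    cube = np.stack([g.filled_nan() for g in grids])
    return cube, ref


def max_value_composite(ndvi_stack: list[RasterGrid]) -> RasterGrid:
    """Per-cell maximum over valid observations; all-nodata cells stay nodata."""
    cube, ref = _stacked(ndvi_stack)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN cells
        out = np.nanmax(cube, axis=0)
    out = np.where(np.isnan(out), ref.nodata, out)
    return ref.like(out)


def median_composite(ndvi_stack: list[RasterGrid]) -> RasterGrid:
    """Per-cell median over valid observations (even count: midpoint of the
    central pair); all-nodata cells stay nodata."""
    cube, ref = _stacked(ndvi_stack)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN cells
        out = np.nanmedian(cube, axis=0)
    out = np.where(np.isnan(out), ref.nodata, out)
    return ref.like(out)


def valid_count(ndvi_stack: list[RasterGrid]) -> RasterGrid:
    cube, ref = _stacked(ndvi_stack)
    return ref.like(np.sum(~np.isnan(cube), axis=0).astype(np.int64), nodata=-1)


def difference_layer(spring: RasterGrid, summer: RasterGrid) -> RasterGrid:
    """Spring composite minus summer composite; nodata propagates."""
    spring.require_same_geometry(summer, "composite")
    valid = spring.mask & summer.mask
    out = np.where(valid, spring.values - summer.values, spring.nodata)
    return spring.like(out)


def build_period_composite(period: str, scenes: list) -> NDVIComposite:
    """Composite one period's reflectance scenes into the difference layer.

    ``scenes`` are BandStacks (reflectance value_kind) tagged spring or
    summer; NDVI is computed per scene (quality-flagged cells dropped),
    spring scenes are max-composited and summer scenes median-composited.
    """
    spring = [ndvi(s) for s in scenes if s.season == "spring"]
    summer = [ndvi(s) for s in scenes if s.season == "summer"]
    if not spring or not summer:
        raise ValueError(f"period {period}: need at least one spring and one "
                         f"summer scene ({len(spring)} spring, {len(summer)} summer)")
    mvc = max_value_composite(spring)
    med = median_composite(summer)
    diff = difference_layer(mvc, med)
    log.info("period %s: composited %d spring + %d summer scenes",
             period, len(spring), len(summer))
    return NDVIComposite(period=period, spring_mvc=mvc, summer_median=med,
                         difference=diff, spring_count=valid_count(spring),
                         summer_count=valid_count(summer))
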