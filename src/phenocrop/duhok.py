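"""Published inputs of the Duhok governorate winter-crop assessment.

The pipeline was designed around a four-epoch Landsat analysis of the
Duhok governorate (Iraqi Kurdistan, ~6600 km2): pre-Anfal (A, 1984-1987),
post-Anfal (B, 1989-1991), reconstruction (C, 1998-2002) and present
(D, 2011-2014).  This module bundles the published pieces of that study
that act as *inputs* to the statistics stages — the scene-date manifest,
the per-period validation error matrices, and the published adjusted area
estimates — so that accuracy statistics, confidence intervals and
interval-overlap change bounds can be recomputed from them.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import numpy as np

from .accuracy import AreaEstimate, ErrorMatrix
from .classification_change import CROP

__all__ = [
    "AREA_TOTAL_KM2",
    "ERROR_MATRICES",
    "PUBLISHED_ESTIMATES",
    "published_area_estimate",
    "scene_manifest_path",
]

AREA_TOTAL_KM2 = 6600.0  # Duhok governorate

# Validation error matrices per period; rows = mapped (crop, other),
# columns = reference (crop, other).  Period D was validated with 240
# road-transect ground points, A-C by visual interpretation of the same
# locations (points falling on clouds etc. drop the totals below 240).
ERROR_MATRICES: dict[str, ErrorMatrix] = {
    "A": ErrorMatrix(np.array([[30, 13], [16, 174]])),
    "B": ErrorMatrix(np.array([[34, 7], [2, 184]])),
    "C": ErrorMatrix(np.array([[36, 16], [7, 171]])),
    "D": ErrorMatrix(np.array([[38, 8], [10, 174]])),
}

# Published adjusted winter-crop areas (km2) with 95 % CI half-widths.
PUBLISHED_ESTIMATES: dict[str, tuple[float, float]] = {
    "A": (1200.0, 263.0),
    "B": (868.0, 141.0),
    "C": (1040.0, 216.0),
    "D": (1300.0, 222.0),
}


def published_area_estimate(period: str) -> AreaEstimate:
    """The published adjusted crop-area estimate wrapped for interval math."""
    est, hw = PUBLISHED_ESTIMATES[period]
    return AreaEstimate.from_published(CROP, est, hw, AREA_TOTAL_KM2)


def scene_manifest_path() -> Path:
    """Path of the bundled 47-scene period/date manifest."""
    return Path(str(resources.files("phenocrop").joinpath("data/duhok_scenes.yaml")))
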