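"""Error matrices, accuracy statistics, and stratified adjusted area estimates.

Validation points are cross-tabulated against the mapped class into a
2-class error matrix (rows = mapped class, columns = reference class).
From the matrix come user's and producer's accuracies, overall accuracy
and Cohen's kappa, and — following the good-practice stratified estimator
for map-based area estimation — adjusted class areas with standard errors
and confidence intervals.

With mapped-class proportions W_i (fraction of the study area mapped as
class i, the stratum weights), cell proportions are estimated as

    p_hat_ij = W_i * n_ij / n_i.

The adjusted area of reference class j is A_hat_j = A_tot * p_hat_.j with
standard error

    S(p_hat_.j) = sqrt( sum_i W_i^2 * (n_ij/n_i.) * (1 - n_ij/n_i.) / (n_i. - 1) )

and confidence half-width z * A_tot * S(p_hat_.j) (z = 1.96 at 95 %).
Because mapped areas are rarely published alongside the adjusted
estimates, :func:`solve_mapped_proportion` inverts the estimator to
recover W_crop from a published adjusted area.

Interval comparison between two periods uses the overlap of the two
confidence intervals and the extreme changes they admit: the maximum
increase is (upper of the later) - (lower of the earlier), the maximum
decrease (upper of the earlier) - (lower of the later), floored at zero.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .classification_change import CROP, OTHER, PeriodClassification
from .io_pipeline import SamplePoint

log = logging.getLogger(__name__)

__all__ = [
    "ErrorMatrix",
    "AccuracyStats",
    "AreaEstimate",
    "ChangeBound",
    "build_error_matrix",
    "accuracy_stats",
    "adjusted_area",
    "change_bounds",
    "coverage_simulation",
    "solve_mapped_proportion",
]

Z_95 = 1.96  # normal multiplier for the 95 % confidence level


def collapse_label(label: str) -> str:
    """Collapse finer cover names (bare soil, orchard, ...) to the 2-class scheme."""
    return CROP if label in (CROP, "cropland", "crop", "agriculture") else OTHER


@dataclass
class ErrorMatrix:
    """2-class confusion counts: rows mapped, columns reference."""

    counts: np.ndarray
    classes: tuple[str, str] = (CROP, OTHER)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != (len(self.classes),) * 2:
            raise ValueError("error-matrix shape does not match class list")
        if np.any(self.counts < 0):
            raise ValueError("error-matrix counts must be non-negative")

    @property
    def row_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def col_totals(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    @property
    def n(self) -> float:
        return float(self.counts.sum())


@dataclass
class AccuracyStats:
    """Accuracy figures from one error matrix (NaN where undefined)."""

    user: dict[str, float]
    producer: dict[str, float]
    overall: float
    kappa: float
    area_weighted_overall: float | None = None
    area_weighted_producer: dict[str, float] | None = None


@dataclass
class AreaEstimate:
    """Stratified adjusted area for one class with its confidence interval."""

    class_name: str
    area_total_km2: float
    mapped_proportions: dict[str, float]
    estimate_km2: float
    proportion: float
    standard_error: float        # of the proportion p_hat_.j
    z: float
    half_width_km2: float

    @property
    def lower(self) -> float:
        return self.estimate_km2 - self.half_width_km2

    @property
    def upper(self) -> float:
        return self.estimate_km2 + self.half_width_km2

    @classmethod
    def from_published(cls, class_name: str, estimate_km2: float,
                       half_width_km2: float, area_total_km2: float,
                       z: float = Z_95) -> "AreaEstimate":
        """Wrap a published estimate +/- half-width for interval arithmetic."""
        return cls(class_name=class_name, area_total_km2=area_total_km2,
                   mapped_proportions={}, estimate_km2=estimate_km2,
                   proportion=estimate_km2 / area_total_km2,
                   standard_error=half_width_km2 / (z * area_total_km2),
                   z=z, half_width_km2=half_width_km2)


@dataclass
class ChangeBound:
    """CI-overlap comparison of the same class between two periods."""

    earlier: AreaEstimate
    later: AreaEstimate
    overlap_km2: float
    max_increase_km2: float
    max_decrease_km2: float


# ---------------------------------------------------------------------------
# Building the matrix from validation points


def build_error_matrix(points: list[SamplePoint],
                       classification: PeriodClassification) -> ErrorMatrix:
    """Cross-tabulate validation points against the mapped class.

    Points outside the study grid, on nodata cells, or inside masked
    (water) segments are excluded with a logged count.  Reference labels
    are collapsed to {cropland, other}.
    """
    points = [p for p in points if p.role == "validation"]
    if not points:
        raise ValueError("no validation points supplied")
    labels = classification.layer.labels
    crop = classification.crop_mask.values
    counts = np.zeros((2, 2))
    excluded = 0
    for p in points:
        r, c = labels.index_of(p.x, p.y)
        if not (0 <= r < labels.shape[0] and 0 <= c < labels.shape[1]):
            excluded += 1
            continue
        seg_id = int(labels.values[r, c])
        if seg_id < 0 or classification.layer.segments[seg_id].masked:
            excluded += 1
            continue
        mapped = 0 if crop[r, c] == 1 else 1
        ref = 0 if collapse_label(p.reference_label) == CROP else 1
        counts[mapped, ref] += 1
    if excluded:
        log.info("build_error_matrix: excluded %d points outside the "
                 "study area or in masked segments", excluded)
    if counts.sum() == 0:
        raise ValueError("no validation point fell inside the study area")
    return ErrorMatrix(counts=counts)


# ---------------------------------------------------------------------------
# Accuracy statistics


def _safe_div(num: float, den: float) -> float:
    return num / den if den > 0 else float("nan")


def _p_hat(m: ErrorMatrix, W: dict[str, float]) -> np.ndarray:
    w = np.array([W[c] for c in m.classes], dtype=float)
    rows = m.row_totals
    with np.errstate(invalid="ignore", divide="ignore"):
        out = (w / rows)[:, None] * m.counts
    return out


def accuracy_stats(m: ErrorMatrix, W: dict[str, float] | None = None) -> AccuracyStats:
    """User/producer/overall accuracy and Cohen's kappa.

    Count-based statistics always; when mapped proportions ``W`` are
    given, the area-weighted overall and producer's accuracies (based on
    p_hat_ij = W_i n_ij / n_i.) are added.  User's accuracy is row-
    conditional and identical under both weightings.  Zero rows/columns
    yield NaN rather than 0.
    """
    if m.n <= 0:
        raise ValueError("empty error matrix")
    rows, cols = m.row_totals, m.col_totals
    diag = np.diag(m.counts)
    user = {c: _safe_div(diag[i], rows[i]) for i, c in enumerate(m.classes)}
    producer = {c: _safe_div(diag[j], cols[j]) for j, c in enumerate(m.classes)}
    overall = float(diag.sum() / m.n)
    p_e = float(np.sum((rows / m.n) * (cols / m.n)))
    kappa = (overall - p_e) / (1 - p_e) if p_e < 1 else float("nan")
    aw_overall = aw_producer = None
    if W is not None:
        p = _p_hat(m, W)
        aw_overall = float(np.nansum(np.diag(p)))
        col_p = p.sum(axis=0)
        aw_producer = {c: _safe_div(p[j, j], col_p[j])
                       for j, c in enumerate(m.classes)}
    return AccuracyStats(user=user, producer=producer, overall=overall,
                         kappa=float(kappa),
                         area_weighted_overall=aw_overall,
                         area_weighted_producer=aw_producer)


# ---------------------------------------------------------------------------
# Stratified adjusted area estimation


def adjusted_area(m: ErrorMatrix, W: dict[str, float], area_total_km2: float,
                  class_name: str = CROP, z: float = Z_95) -> AreaEstimate:
    """Adjusted area of ``class_name`` with its confidence interval.

    Requires every mapped stratum to hold at least two validation points
    (the variance term divides by n_i. - 1) and the stratum weights to
    sum to one.
    """
    w = np.array([W[c] for c in m.classes], dtype=float)
    if abs(w.sum() - 1.0) > 1e-6:
        raise ValueError(f"mapped proportions must sum to 1, got {w.sum()}")
    rows = m.row_totals
    if np.any(rows < 2):
        raise ValueError("each mapped class needs >= 2 validation points "
                         "for the variance estimate")
    j = m.classes.index(class_name)
    frac = m.counts[:, j] / rows
    p_col = float(np.sum(w * frac))
    var = float(np.sum(w ** 2 * frac * (1 - frac) / (rows - 1)))
    se = math.sqrt(var)
    return AreaEstimate(
        class_name=class_name, area_total_km2=area_total_km2,
        mapped_proportions=dict(W), estimate_km2=area_total_km2 * p_col,
        proportion=p_col, standard_error=se, z=z,
        half_width_km2=z * area_total_km2 * se)


def solve_mapped_proportion(m: ErrorMatrix, published_estimate_km2: float,
                            area_total_km2: float,
                            class_name: str = CROP) -> dict[str, float]:
    """Recover the 2-class stratum weights W from a published adjusted area.

    Inverts A_hat = A_tot * (W_c * n_cj/n_c. + (1 - W_c) * n_oj/n_o.) for
    W_c.  Only defined when the two rows disagree in their reference-class
    fraction.
    """
    j = m.classes.index(class_name)
    rows = m.row_totals
    if np.any(rows == 0):
        raise ValueError("cannot invert with an empty mapped stratum")
    f = m.counts[:, j] / rows
    if abs(f[0] - f[1]) < 1e-12:
        raise ValueError("rows have identical class fractions; W unidentifiable")
    p = published_estimate_km2 / area_total_km2
    w_first = (p - f[1]) / (f[0] - f[1])
    if not 0 <= w_first <= 1:
        raise ValueError(f"recovered proportion {w_first:.4f} outside [0, 1]; "
                         "published estimate inconsistent with the matrix")
    return {m.classes[0]: float(w_first), m.classes[1]: float(1 - w_first)}


def coverage_simulation(classification: PeriodClassification,
                        truth_crop: np.ndarray, n_points: int = 240,
                        n_reps: int = 500,
                        rng: np.random.Generator | None = None,
                        z: float = Z_95) -> float:
    """Monte-Carlo calibration of the stratified interval estimator.

    Repeatedly draws a stratified validation sample (allocation
    proportional to the mapped strata, at least two points per stratum)
    from the classified map, reads the reference label off the truth
    mask, forms the error matrix and the adjusted crop-area CI, and
    reports the fraction of replicates whose interval covers the true
    crop area.  A well-calibrated 95 % interval should cover in roughly
    95 % of replicates.
    """
    rng = rng or np.random.default_rng()
    labels = classification.layer.labels
    unmasked = labels.values >= 0
    for seg in classification.layer.segments.values():
        if seg.masked:
            unmasked &= labels.values != seg.id
    mapped_crop = (classification.crop_mask.values == 1) & unmasked
    mapped_other = unmasked & ~mapped_crop
    ref_crop = truth_crop.astype(bool)
    cell_area = labels.cell_area_km2()
    a_tot = float(unmasked.sum()) * cell_area
    true_area = float((ref_crop & unmasked).sum()) * cell_area
    w_crop = float(mapped_crop.sum()) / float(unmasked.sum())
    W = {CROP: w_crop, OTHER: 1.0 - w_crop}
    n_c = max(2, int(round(n_points * w_crop)))
    n_o = max(2, n_points - n_c)
    strata = [(np.flatnonzero((ref_crop & mapped_crop).ravel()),
               np.flatnonzero(mapped_crop.ravel()), n_c),
              (np.flatnonzero((ref_crop & mapped_other).ravel()),
               np.flatnonzero(mapped_other.ravel()), n_o)]
    is_crop = {0: np.isin(strata[0][1], strata[0][0]),
               1: np.isin(strata[1][1], strata[1][0])}
    covered = 0
    for _ in range(n_reps):
        counts = np.zeros((2, 2))
        for row, (_, pool, n_s) in enumerate(strata):
            take = rng.choice(len(pool), size=min(n_s, len(pool)), replace=False)
            k = int(is_crop[row][take].sum())
            counts[row, 0] = k
            counts[row, 1] = len(take) - k
        est = adjusted_area(ErrorMatrix(counts), W, a_tot, z=z)
        if est.lower <= true_area <= est.upper:
            covered += 1
    return covered / n_reps


def change_bounds(e1: AreaEstimate, e2: AreaEstimate) -> ChangeBound:
    """Interval overlap and extreme-change bounds between two estimates."""
    if e1.class_name != e2.class_name:
        raise ValueError("change bounds compare the same class across periods")
    if abs(e1.area_total_km2 - e2.area_total_km2) > 1e-6:
        raise ValueError("estimates refer to different total areas")
    overlap = max(0.0, min(e1.upper, e2.upper) - max(e1.lower, e2.lower))
    return ChangeBound(
        earlier=e1, later=e2, overlap_km2=overlap,
        max_increase_km2=max(0.0, e2.upper - e1.lower),
        max_decrease_km2=max(0.0, e1.upper - e2.lower))
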