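"""Synthetic multi-period scene generator.

Builds small scenes with the statistical structure the winter-crop mapping
method assumes, plus full truth labels, so every downstream stage can be
exercised and checked without the real Landsat archive:

* a DEM combining a gently tilted plain, smoothed random bumps, and a
  mountain belt along the northern edge — yielding both low-slope cropland
  terrain and the steep grassland terrain that confuses the NDVI signal;
* rectangular crop fields on the plain with a per-period activity schedule
  (stable fields, fields abandoned only in the post-Anfal period, fields
  reclaimed from period B on, fields newly cultivated in the present
  period).  An *active* field is green in spring and harvested stubble in
  summer; within a period it may lie fallow (stubble both seasons) in
  individual years, so only the multi-year composites recover the full
  cropland.  A field *abandoned* for a period reverts to grassland;
* per-cover seasonal NDVI models: active cropland's spring-minus-summer
  NDVI difference is drawn with mean 0.5713 and total sd 0.113 (split into
  a field-level and a cell-level component), matching the training
  statistics the threshold rule is built from; every other cover keeps its
  mean difference well below the classification threshold, and water NDVI
  is negative in both seasons;
* haze patches in some spring scenes (additive blue/green offset plus an
  NDVI depression) flagged in a per-scene quality mask;
* a serpentine road across the plain for right-hand-side transect
  validation sampling, and stratified training points (default 333, of
  which 51 cropland, mirroring the study's training set).

Bands are synthesised from the per-cell NDVI v and a per-cover brightness
sum s = NIR + Red: NIR = s (1 + v) / 2, Red = s (1 - v) / 2, with green
and blue tied to red.  All reflectances are truncated to [0, 1].
"""

from __future__ import annotations

import datetime
import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter
from shapely.geometry import LineString, box
from shapely.ops import unary_union

from .classification_change import DEFAULT_T_NDVI, DEFAULT_T_SLOPE, slope_grid
from .grid import RasterGrid
from .io_pipeline import BandStack, SamplePoint
from .radiometry import CalibrationMeta

log = logging.getLogger(__name__)

__all__ = [
    "SceneTemplate",
    "TruthBundle",
    "generate_scene_collection",
    "sample_points",
    "to_digital_numbers",
    "COVER_CODES",
]

COVER_CODES = {
    "cropland": 1,
    "grassland": 2,
    "woodland": 3,
    "shrub": 4,
    "bare soil": 5,
    "built-up": 6,
    "water": 7,
}
CODE_NAMES = {v: k for k, v in COVER_CODES.items()}

PERIODS = ("A", "B", "C", "D")
PERIOD_YEARS = {"A": 1984, "B": 1989, "C": 1998, "D": 2011}

# (spring NDVI mean, summer NDVI mean, cell sd) for the static covers.
COVER_NDVI = {
    "grassland": (0.35, 0.18, 0.04),
    "woodland": (0.55, 0.50, 0.04),
    "shrub": (0.30, 0.22, 0.04),
    "bare soil": (0.12, 0.10, 0.03),
    "built-up": (0.10, 0.10, 0.02),
    "water": (-0.30, -0.30, 0.05),
    "stubble": (0.20, 0.18, 0.03),   # fallow / post-harvest crop fields
}

# brightness sum NIR + Red per cover and season
COVER_BRIGHTNESS = {
    "cropland": (0.42, 0.50),
    "grassland": (0.38, 0.35),
    "woodland": (0.40, 0.40),
    "shrub": (0.38, 0.36),
    "bare soil": (0.44, 0.46),
    "built-up": (0.50, 0.50),
    "water": (0.08, 0.08),
    "stubble": (0.55, 0.55),
}


@dataclass
class SceneTemplate:
    """Parameters of the synthetic study area and its seasonal model."""

    rows: int = 96
    cols: int = 96
    cell_size: float = 30.0
    origin: tuple[float, float] = (400_000.0, 4_070_000.0)
    crs_id: str = "EPSG:32638"
    seed: int = 1

    # terrain
    mountain_fraction: float = 0.28      # northern rows occupied by mountains
    plain_bump_sd_m: float = 4.0
    mountain_height_m: float = 600.0

    # fields and schedule
    field_cells: int = 8                 # field edge length in cells
    crop_block_fraction: float = 0.45    # plain blocks that are crop fields
    profile_probs: dict[str, float] = field(default_factory=lambda: {
        "stable": 0.45,        # active A, B, C, D
        "reclaimed_bcd": 0.10, # inactive A, active B, C, D
        "all_but_b": 0.12,     # abandoned only in the post-Anfal period
        "new_in_d": 0.08,      # first cultivated in the present period
        "random": 0.25,        # independent per-period activity
    })
    random_period_activity: dict[str, float] = field(default_factory=lambda: {
        "A": 0.9, "B": 0.35, "C": 0.55, "D": 0.75})
    year_activity: float = 0.75          # P(active field cultivated in a year)
    years_per_period: int = 3
    summer_scenes_per_period: int = 2

    # seasonal NDVI model for active cropland
    crop_diff_mean: float = 0.5713
    crop_diff_field_sd: float = 0.05     # between-field component
    crop_diff_cell_sd: float = 0.1013    # within-field component (total sd 0.113)
    crop_summer_ndvi: float = 0.18
    crop_summer_sd: float = 0.03
    observation_sd: float = 0.01         # per-scene NDVI repeat noise

    # haze / cloud contamination of spring scenes (the archive scenes were
    # picked for low cloud cover, so contamination is patchy and moderate)
    haze_probability: float = 0.4
    haze_offset: float = 0.06            # additive blue/green reflectance
    haze_patch_cells: tuple[int, int] = (10, 20)

    # masking thresholds the generator respects when placing covers
    slope_mask_deg: float = DEFAULT_T_SLOPE
    slope_margin_deg: float = 2.5

    @property
    def total_diff_sd(self) -> float:
        return math.hypot(self.crop_diff_field_sd, self.crop_diff_cell_sd)


@dataclass
class TruthBundle:
    """Everything the downstream stages need, plus the ground truth."""

    template: SceneTemplate
    scenes: list[BandStack]
    truth: dict[str, RasterGrid]           # per-period cover-code maps
    dem: RasterGrid
    water: list
    road: LineString
    training: list[SamplePoint]
    validation: dict[str, list[SamplePoint]]
    true_crop_area_km2: dict[str, float]
    field_blocks: list[tuple[int, int, int, int]]  # (r0, r1, c0, c1) crop fields
    schedule: dict[str, np.ndarray]        # period -> bool per field (active)

    def scenes_of(self, period: str, season: str | None = None) -> list[BandStack]:
        out = [s for s in self.scenes if s.period == period]
        if season is not None:
            out = [s for s in out if s.season == season]
        return out

    def segmentation_scene(self, period: str) -> BandStack:
        """The designated (first-year) spring scene of a period."""
        return self.scenes_of(period, "spring")[0]


# ---------------------------------------------------------------------------
# Terrain and cover layout


def _build_dem(t: SceneTemplate, rng: np.random.Generator) -> np.ndarray:
    rr = np.arange(t.rows)[:, None].astype(float)
    plane = 420.0 + 0.15 * (t.rows - rr) * np.ones((1, t.cols))
    bumps = gaussian_filter(rng.normal(size=(t.rows, t.cols)), 6.0)
    bumps *= t.plain_bump_sd_m / max(bumps.std(), 1e-9)
    m_end = max(2, int(t.rows * t.mountain_fraction))
    profile = np.clip((m_end - rr) / m_end, 0.0, None) ** 1.5
    ridge = gaussian_filter(rng.normal(size=(t.rows, t.cols)), 4.0)
    ridge *= 0.15 / max(ridge.std(), 1e-9)
    mountain = t.mountain_height_m * profile * (1.0 + ridge)
    return plane + bumps + mountain


def _layout_covers(t: SceneTemplate, dem: RasterGrid,
                   rng: np.random.Generator):
    """Static cover map (code per cell, cropland blocks marked), the list of
    crop-field blocks, and the water polygons."""
    slope = slope_grid(dem).values
    cover = np.full((t.rows, t.cols), COVER_CODES["bare soil"], dtype=np.int64)

    # mountain belt: grassland on steep cells, shrub/woodland mixed in
    m_end = max(2, int(t.rows * t.mountain_fraction))
    mnoise = rng.random((t.rows, t.cols))
    mountain_zone = np.zeros((t.rows, t.cols), dtype=bool)
    mountain_zone[:m_end + 4, :] = True
    steep = slope >= t.slope_mask_deg - t.slope_margin_deg
    grass = mountain_zone | steep
    cover[grass] = COVER_CODES["grassland"]
    cover[grass & (mnoise < 0.25)] = COVER_CODES["shrub"]
    cover[grass & (mnoise > 0.85)] = COVER_CODES["woodland"]

    # lake: ellipse on the plain, east side (placed before blocks so no
    # crop field straddles the shoreline)
    fs = t.field_cells
    r_start = m_end + 6
    cy = (r_start + t.rows) // 2
    cx = int(t.cols * 0.8)
    yy, xx = np.mgrid[0:t.rows, 0:t.cols]
    lake = (((yy - cy) / 5.0) ** 2 + ((xx - cx) / 8.0) ** 2) <= 1.0

    # blocks on the plain
    blocks = []
    for r0 in range(r_start, t.rows - fs + 1, fs):
        for c0 in range(2, t.cols - fs + 1, fs):
            blk = (r0, r0 + fs, c0, c0 + fs)
            blk_slope = slope[r0:r0 + fs, c0:c0 + fs].mean()
            wet = lake[r0:r0 + fs, c0:c0 + fs].any()
            blocks.append((blk, blk_slope, wet))
    usable = [b for b, s, wet in blocks
              if s < t.slope_mask_deg - t.slope_margin_deg and not wet]
    rng.shuffle(usable)
    n_fields = int(round(t.crop_block_fraction * len(usable)))
    fields = usable[:n_fields]
    rest = usable[n_fields:]
    for r0, r1, c0, c1 in fields:
        cover[r0:r1, c0:c1] = COVER_CODES["cropland"]
    # non-field blocks: mostly bare, some grass and woodland patches
    for i, (r0, r1, c0, c1) in enumerate(rest):
        u = rng.random()
        if u < 0.20:
            cover[r0:r1, c0:c1] = COVER_CODES["grassland"]
        elif u < 0.30:
            cover[r0:r1, c0:c1] = COVER_CODES["woodland"]
        elif u < 0.36:
            cover[r0:r1, c0:c1] = COVER_CODES["shrub"]
        # else leave bare soil
    if rest:
        r0, r1, c0, c1 = rest[0]
        cover[r0:r1, c0:c1] = COVER_CODES["built-up"]

    cover[lake] = COVER_CODES["water"]

    x0, y0 = t.origin
    cell = t.cell_size
    wboxes = [box(x0 + c * cell, y0 - (r + 1) * cell,
                  x0 + (c + 1) * cell, y0 - r * cell)
              for r, c in zip(*np.nonzero(lake))]
    water_polys = [unary_union(wboxes)] if wboxes else []
    return cover, fields, water_polys, r_start


def _make_schedule(t: SceneTemplate, n_fields: int,
                   rng: np.random.Generator) -> dict[str, np.ndarray]:
    """Per-period active flag per field according to the profile mix."""
    profiles = {
        "stable": (1, 1, 1, 1),
        "reclaimed_bcd": (0, 1, 1, 1),
        "all_but_b": (1, 0, 1, 1),
        "new_in_d": (0, 0, 0, 1),
    }
    names = list(t.profile_probs)
    probs = np.array([t.profile_probs[n] for n in names], dtype=float)
    probs /= probs.sum()
    choice = rng.choice(len(names), size=n_fields, p=probs)
    active = {p: np.zeros(n_fields, dtype=bool) for p in PERIODS}
    for i, ci in enumerate(choice):
        name = names[ci]
        if name == "random":
            flags = tuple(int(rng.random() < t.random_period_activity[p])
                          for p in PERIODS)
        else:
            flags = profiles[name]
        for p, f in zip(PERIODS, flags):
            active[p][i] = bool(f)
    return active


# ---------------------------------------------------------------------------
# Seasonal NDVI fields and band synthesis


def _bands_from_ndvi(v: np.ndarray, s: np.ndarray,
                     rng: np.random.Generator) -> dict[str, np.ndarray]:
    nir = s * (1.0 + v) / 2.0
    red = s * (1.0 - v) / 2.0
    green = red * 0.85 + 0.03 + rng.normal(0, 0.005, v.shape)
    blue = red * 0.75 + 0.02 + rng.normal(0, 0.005, v.shape)
    return {r: np.clip(b, 0.001, 1.0)
            for r, b in (("blue", blue), ("green", green),
                         ("red", red), ("nir", nir))}


def generate_scene_collection(template: SceneTemplate | None = None) -> TruthBundle:
    """Generate the full multi-period scene collection with truth labels."""
    t = template or SceneTemplate()
    threshold = t.crop_diff_mean  # degenerate-template check below
    if threshold < DEFAULT_T_NDVI:
        warnings.warn("template crop NDVI-difference mean lies below the "
                      "classification threshold; downstream recovery will be "
                      "poor (degenerate scenario)", stacklevel=2)
    rng = np.random.default_rng(t.seed)
    dem_vals = _build_dem(t, rng)
    dem = RasterGrid(dem_vals, cell_size=t.cell_size, origin=t.origin,
                     crs_id=t.crs_id)
    cover_static, fields, water_polys, plain_start = _layout_covers(t, dem, rng)
    schedule = _make_schedule(t, len(fields), rng)

    cell_area = dem.cell_area_km2()
    shape = (t.rows, t.cols)

    # field-id raster: -1 outside fields
    field_id = -np.ones(shape, dtype=np.int64)
    for i, (r0, r1, c0, c1) in enumerate(fields):
        field_id[r0:r1, c0:c1] = i

    truth: dict[str, RasterGrid] = {}
    true_area: dict[str, float] = {}
    scenes: list[BandStack] = []

    for period in PERIODS:
        active = schedule[period]
        # per-period truth: active fields are cropland, abandoned fields
        # revert to grassland; everything else keeps the static cover
        cov = cover_static.copy()
        in_field = field_id >= 0
        act_cells = (in_field & active[np.clip(field_id, 0, None)]
                     if len(fields) else np.zeros(shape, dtype=bool))
        cov[in_field] = COVER_CODES["grassland"]
        cov[act_cells] = COVER_CODES["cropland"]
        truth[period] = dem.like(cov, nodata=-1)
        true_area[period] = float(act_cells.sum()) * cell_area

        # per-period, per-cell seasonal NDVI (stable across the period's
        # scenes; only observation noise and haze vary per scene)
        v_spring = np.empty(shape)
        v_summer = np.empty(shape)
        for name, (sp, su, sd) in COVER_NDVI.items():
            code = COVER_CODES.get(name)
            if code is None:
                continue
            m = cov == code
            if name == "water":
                v_spring[m] = np.minimum(rng.normal(sp, sd, int(m.sum())), -0.02)
                v_summer[m] = np.minimum(rng.normal(su, sd, int(m.sum())), -0.02)
            else:
                v_spring[m] = rng.normal(sp, sd, int(m.sum()))
                v_summer[m] = rng.normal(su, sd, int(m.sum()))
        # active cropland: summer base + field/cell difference components
        m = act_cells
        n_act = int(m.sum())
        field_effect = rng.normal(0.0, t.crop_diff_field_sd, len(fields))
        d = (t.crop_diff_mean + field_effect[field_id[m]]
             + rng.normal(0.0, t.crop_diff_cell_sd, n_act))
        su = rng.normal(t.crop_summer_ndvi, t.crop_summer_sd, n_act)
        v_summer[m] = su
        v_spring[m] = np.clip(su + d, None, 0.98)

        # per-year fallow: in a fallow year an active field shows stubble
        year_active = np.zeros((t.years_per_period, len(fields)), dtype=bool)
        for i in range(len(fields)):
            if not active[i]:
                continue
            ya = rng.random(t.years_per_period) < t.year_activity
            if not ya.any():
                ya[int(rng.integers(t.years_per_period))] = True
            year_active[:, i] = ya

        base_year = PERIOD_YEARS[period]
        stub_sp, stub_su, stub_sd = COVER_NDVI["stubble"]
        for y in range(t.years_per_period):
            v = v_spring.copy()
            s = np.empty(shape)
            for name in COVER_BRIGHTNESS:
                code = COVER_CODES.get(name)
                if code is None:
                    continue
                s[cov == code] = COVER_BRIGHTNESS[name][0]
            # fields fallow this year (or abandoned-period fields already
            # handled as grassland): stubble signature in spring
            fallow = (m & ~year_active[y][np.clip(field_id, 0, None)]
                      if len(fields) else np.zeros(shape, dtype=bool))
            v[fallow] = rng.normal(stub_sp, stub_sd, int(fallow.sum()))
            s[m] = COVER_BRIGHTNESS["cropland"][0]
            s[fallow] = COVER_BRIGHTNESS["stubble"][0]
            s = s + rng.normal(0, 0.02, shape)
            v = v + rng.normal(0, t.observation_sd, shape)
            bands = _bands_from_ndvi(np.clip(v, -0.99, 0.99), s, rng)
            quality = np.zeros(shape, dtype=np.int64)
            if rng.random() < t.haze_probability:
                lo, hi = t.haze_patch_cells
                hr = int(rng.integers(lo, min(hi, t.rows - 1)))
                hc = int(rng.integers(lo, min(hi, t.cols - 1)))
                r0 = int(rng.integers(0, t.rows - hr))
                c0 = int(rng.integers(0, t.cols - hc))
                patch = np.s_[r0:r0 + hr, c0:c0 + hc]
                bands["blue"][patch] = np.clip(
                    bands["blue"][patch] + t.haze_offset + 0.02, 0, 1)
                bands["green"][patch] = np.clip(
                    bands["green"][patch] + t.haze_offset, 0, 1)
                bands["red"][patch] = np.clip(bands["red"][patch] + 0.05, 0, 1)
                bands["nir"][patch] = np.clip(bands["nir"][patch] - 0.04, 0, 1)
                quality[patch] = 1
            date = datetime.date(base_year + y, 1, 1) + datetime.timedelta(
                days=int(100 + 15 * y))
            scenes.append(BandStack(
                bands={r: dem.like(b) for r, b in bands.items()},
                acquisition_date=date, season="spring", period=period,
                value_kind="surface_reflectance",
                quality=dem.like(quality, nodata=-1)))

        for k in range(t.summer_scenes_per_period):
            v = v_summer.copy()
            s = np.empty(shape)
            for name in COVER_BRIGHTNESS:
                code = COVER_CODES.get(name)
                if code is None:
                    continue
                s[cov == code] = COVER_BRIGHTNESS[name][1]
            s[m] = COVER_BRIGHTNESS["stubble"][1]  # harvested fields
            s = s + rng.normal(0, 0.02, shape)
            v = v + rng.normal(0, t.observation_sd, shape)
            bands = _bands_from_ndvi(np.clip(v, -0.99, 0.99), s, rng)
            date = datetime.date(base_year + min(k, t.years_per_period - 1),
                                 1, 1) + datetime.timedelta(days=int(215 + 10 * k))
            scenes.append(BandStack(
                bands={r: dem.like(b) for r, b in bands.items()},
                acquisition_date=date, season="summer", period=period,
                value_kind="surface_reflectance",
                quality=dem.like(np.zeros(shape, dtype=np.int64), nodata=-1)))

    road = _build_road(t, plain_start)
    bundle = TruthBundle(
        template=t, scenes=scenes, truth=truth, dem=dem, water=water_polys,
        road=road, training=[], validation={}, true_crop_area_km2=true_area,
        field_blocks=fields, schedule=schedule)
    training, validation = sample_points(bundle)
    bundle.training = training
    bundle.validation = validation
    log.info("generated %d scenes, %d crop fields, true areas %s km2",
             len(scenes), len(fields),
             {p: round(a, 3) for p, a in true_area.items()})
    return bundle


def _build_road(t: SceneTemplate, plain_start: int) -> LineString:
    """Serpentine road over the plain (west-east passes joined at the ends)."""
    x0, y0 = t.origin
    cell = t.cell_size
    xs_left = x0 + 1.5 * cell
    xs_right = x0 + (t.cols - 1.5) * cell
    pts = []
    direction = 0
    for r in range(plain_start + 4, t.rows - 4, 8):
        y = y0 - (r + 0.5) * cell
        xl, xr = (xs_left, xs_right) if direction == 0 else (xs_right, xs_left)
        pts.append((xl, y))
        pts.append((xr, y))
        direction ^= 1
    return LineString(pts)


# ---------------------------------------------------------------------------
# Point sampling


def sample_points(bundle: TruthBundle, n_train: int = 333,
                  n_valid: int = 240, spacing: float | None = None,
                  n_crop_train: int = 51, seed: int | None = None,
                  side_offset: float | None = None,
                  ) -> tuple[list[SamplePoint], dict[str, list[SamplePoint]]]:
    """Draw training and road-transect validation samples.

    Training points are stratified over the period-D truth covers with a
    fixed cropland quota (defaults 333 and 51, the study's training set).
    Validation points are placed every ``spacing`` meters along the road,
    offset to the right-hand side of the direction of travel; labels are
    read from each period's truth map, so the same locations validate all
    four periods.  When ``spacing`` is None it is chosen so the road
    accommodates ``n_valid`` points; a road too short for the requested
    spacing yields fewer points with a logged warning.
    """
    t = bundle.template
    rng = np.random.default_rng(t.seed + 7919 if seed is None else seed)
    truth_d = bundle.truth["D"]

    # -- training: stratified by cover, water excluded ---------------------
    cov = truth_d.values
    crop_cells = np.argwhere(cov == COVER_CODES["cropland"])
    other_cells = np.argwhere((cov != COVER_CODES["cropland"])
                              & (cov != COVER_CODES["water"]))
    n_crop = min(n_crop_train, len(crop_cells))
    if n_crop < n_crop_train:
        log.warning("only %d cropland cells available for %d requested "
                    "cropland training points", len(crop_cells), n_crop_train)
    n_other = min(n_train - n_crop, len(other_cells))
    take_c = crop_cells[rng.choice(len(crop_cells), n_crop, replace=False)] \
        if n_crop else np.empty((0, 2), dtype=int)
    take_o = other_cells[rng.choice(len(other_cells), n_other, replace=False)]
    training = []
    for r, c in np.vstack([take_c, take_o]).tolist():
        x, y = truth_d.cell_center(r, c)
        training.append(SamplePoint(x, y, CODE_NAMES[int(cov[r, c])], "training"))

    # -- validation: road transect, right-hand side ------------------------
    road = bundle.road
    if spacing is None:
        spacing = road.length / n_valid
    offset = side_offset if side_offset is not None else t.cell_size / 2.0
    n_fit = int(road.length // spacing)
    if n_fit < n_valid:
        log.warning("road (%.0f m) shorter than %d x %.0f m; placing %d "
                    "validation points", road.length, n_valid, spacing, n_fit)
    n_place = min(n_valid, n_fit)
    locations = []
    for k in range(n_place):
        s = (k + 0.5) * spacing
        p = road.interpolate(s)
        q = road.interpolate(min(s + 1.0, road.length))
        dx, dy = q.x - p.x, q.y - p.y
        norm = math.hypot(dx, dy) or 1.0
        # right-hand side of travel: rotate direction by -90 degrees
        ox, oy = dy / norm, -dx / norm
        locations.append((p.x + ox * offset, p.y + oy * offset))
    validation: dict[str, list[SamplePoint]] = {}
    for period in PERIODS:
        cov_p = bundle.truth[period]
        pts = []
        for x, y in locations:
            r, c = cov_p.index_of(x, y)
            r = min(max(r, 0), cov_p.shape[0] - 1)
            c = min(max(c, 0), cov_p.shape[1] - 1)
            pts.append(SamplePoint(x, y, CODE_NAMES[int(cov_p.values[r, c])],
                                   "validation"))
        validation[period] = pts
    return training, validation


# ---------------------------------------------------------------------------
# Forward model to raw digital numbers (for correction tests and DN runs)


def to_digital_numbers(stack: BandStack, meta: CalibrationMeta,
                       path_radiance: dict[str, float] | None = None) -> BandStack:
    """Forward-model a surface-reflectance stack to raw digital numbers.

    At-sensor radiance per band is the two-way Rayleigh-attenuated surface
    signal plus an optional additive path radiance (haze):

        L = rho * T_v * (E_sun * cos(theta_z) * T_z) / (pi * d^2) + L_p

    then DN = (L - bias) / gain, rounded to integers.  This is the exact
    inverse of the dark-object correction model, so correction recovers
    the input reflectance up to DN quantization.
    """
    from .radiometry import rayleigh_optical_thickness

    path_radiance = path_radiance or {}
    mu_z = meta.cos_solar_zenith
    mu_v = meta.cos_view_zenith
    d2 = meta.earth_sun_distance_au ** 2
    out = {}
    for role, g in stack.bands.items():
        cal = meta.band(role)
        tau = rayleigh_optical_thickness(cal.wavelength_um)
        t_v = math.exp(-tau / mu_v)
        t_z = math.exp(-tau / mu_z)
        L = (g.values.astype(float) * t_v * (cal.e_sun * mu_z * t_z)
             / (math.pi * d2)) + path_radiance.get(role, 0.0)
        dn = np.rint((L - cal.bias) / cal.gain).astype(np.int64)
        out[role] = g.like(np.where(g.mask, dn, g.nodata))
    return stack.with_bands(out, value_kind="digital_number", provenance="forward_model")
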