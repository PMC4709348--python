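# Methods

This note documents the models, parameter choices and known limitations of
the phenocrop pipeline, stage by stage in the order the method runs.

## Phenology model and compositing

The mapping principle is the spring/summer greenness contrast of winter
cereals: sown in autumn, green through spring, harvested around June, dry
stubble afterwards.  The per-period signal is

    ΔNDVI = max over spring scenes (NDVI) − median over summer scenes (NDVI)

computed per cell.  The maximum on the pre-harvest side deliberately
prefers each pixel's greenest observation across the period's years: a
field fallow in one year but cultivated in another still registers, and
cloud/haze-depressed observations lose to clear ones.  The median on the
post-harvest side rejects both residual green vegetation (a maximum would
keep it) and contaminated low outliers (a minimum would keep those).  The
even-count median is the midpoint of the central pair — standard and
deterministic.  Composites are computed on NDVI directly, not on
reflectance composited first.  Cells flagged in a scene's quality mask
(cloud/snow/haze) enter compositing as nodata for that scene; a difference
cell is valid only where at least one valid spring and one valid summer
observation exist, and per-cell contribution counts are written out for
QA.

## Radiometric correction

Raw digital-number scenes are converted to radiance (L = gain·DN + bias)
and corrected to surface reflectance by dark-object subtraction with
Rayleigh transmittances (the DOS3 formulation): the dark-object radiance
is the 1 % quantile of positive in-scene radiances — a quantile rather
than a minimum so single-pixel outliers cannot define the haze level —
assumed to image targets of 1 % reflectance; the path radiance is the
excess above that floor.  Downwelling diffuse irradiance is set to zero
(Rayleigh-only), the usual simplification of the method.  Corrected
reflectance is clipped to [0, 1] and clip counts are logged.  Scenes
delivered as surface reflectance (LEDAPS-style products) bypass correction
entirely.  Note that correction does not uniformly darken an image
relative to TOA reflectance: the two-way transmittance division raises
values wherever the path-radiance subtraction is smaller than the
transmittance loss, so the corrected product is below TOA only under
genuine haze.

## Segmentation

Objects come from the standard multiresolution region-merging formulation
(the published settings scale = 100, shape = 0.1, compactness = 0.1 of the
commercial tool parameterize exactly this family; the proprietary
implementation itself is unpublished).  Starting from single-cell objects,
adjacent objects merge under local mutual best fitting; the fusion cost
combines the increase in spectral heterogeneity Σ_b w_b·n·σ_b and in shape
heterogeneity w_cmpct·(l/√n) + (1 − w_cmpct)·(l/b); a merge requires
f < scale².  Determinism: objects are scanned in ascending id order (ids
row-major, a merged object keeps the smaller id) and cost ties break to
the lowest (id₁, id₂) pair; the seed argument is reserved for a randomized
start ordering and unused by default.  Bands are green/red/NIR with equal
weights; blue is excluded because spring haze loads it most.

The scale parameter lives in band-value units: 100 suits 8-bit DN
imagery, whereas [0, 1] reflectance scenes (including all synthetic
scenes) use scale 2 — with ~0.02 within-cover band noise and field-scale
objects of ~64 cells, admissible within-cover fusion costs stay well
below 4 while cross-cover merges at field size cost an order of magnitude
more.

Polygons follow cell edges (4-connectivity); the centroid used by the
water mask is the polygon *area* centroid, which may lie outside the
polygon — so a C-shaped shoreline segment whose centroid falls in the
lake is masked even though its cells are on land.  This literal centroid
rule is intentional.

## Thresholds and classification

T_ndvi = mean − 2.3·sd of the cropland training points' ΔNDVI (2.3 sd
keeps ≈99 % of a normal cropland population); T_slope = mean + 2·sd of
their slope.  Standard deviations are sample (ddof = 1).  The ΔNDVI
boundary is inclusive (≥), the slope boundary exclusive (segments at or
above the cut are filtered) — both conventions are load-bearing and
tested.  The Duhok study's printed decision values, T_ndvi = 0.30291 and
T_slope = 7.625°, are the pipeline defaults for stated-threshold runs.
The printed derivation "0.5713 − 2.3 × 0.113" actually evaluates to
0.3114; the two printed numbers are mutually inconsistent and we do not
guess which is the typo — the decision value 0.30291 is honored as the
default while `derive_thresholds` implements the rule faithfully for
fresh data.

Slope uses the Horn 3×3 operator (the DEM standard; the source analysis
does not name one), with edge-replicated neighborhoods at the grid
border.  The DEM is resampled to the imagery grid by nearest neighbor
when geometries differ only by sampling.

## Overlay

Change accounting happens on the common raster grid, not by polygon
intersection: per-period segmentations are independent, so cross-period
reasoning starts after rasterization.  Each cell gets a 4-bit presence
code (bit order A B C D); areas are tabulated for all 16 codes so their
sum — including the never-cropland code — equals the study area exactly.
Named categories: stable (1111), reclaimed from B on (0111), all-but-B
(1011), new-in-D (0001).  The minimum-area filter (default 100 km²)
limits only which combinations are flagged for a map product; totals are
never filtered.

## Accuracy and area estimation

The stratified estimator treats the two mapped classes as strata with
weights W_i from the classification itself.  User's accuracy is
row-conditional and therefore identical with and without area weighting;
producer's and overall accuracy differ once weighted, which is why
published producer's/overall figures cannot be reproduced from counts
alone without the (unpublished) W_i — an inversion utility recovers W
from a published adjusted estimate instead.  z = 1.96 exactly for the
95 % level.  Degenerate rows/columns yield NaN, never silent zeros.
Report rounding: areas to km², percentages to one decimal, kappa to three
decimals.

The interval estimator is Wald-type per stratum: it is well calibrated at
moderate error rates but under-covers when a stratum's conditional
accuracy approaches 1 (the binomial variance term collapses).  The
Monte-Carlo calibration check therefore draws the reference layer from a
confusion process at the accuracy level of the real validation (~0.8
user's accuracy for mapped crop) rather than from the nearly error-free
synthetic map, and requires ≥90 % empirical coverage of the nominal 95 %
interval over 500 stratified draws.

## Synthetic study generator

The generator emulates the study conditions end to end on a scaled-down
scene (default 96×96 cells of 30 m, ≈8.3 km²):

- **Terrain** — a gently tilted plain with smoothed random bumps (sd 4 m)
  and a mountain belt (600 m relief) along the northern edge, giving both
  low-slope cropland terrain and steep grassland/shrub/woodland terrain.
- **Fields** — 8×8-cell blocks on sub-5° terrain; 45 % of usable blocks
  are crop fields.  Per-period activity profiles mirror the study's
  change story: 45 % stable, 10 % reclaimed from B on, 12 % abandoned
  only in B, 8 % first cultivated in D, the rest random with per-period
  activity (A 0.9, B 0.35, C 0.55, D 0.75), reproducing a decline after
  period A and recovery through C and D.  Within a period, an active
  field is cultivated in each year with probability 0.75 (at least one
  year), so single scenes miss fallow fields but multi-year composites
  recover them.  A field inactive for a whole period reverts to
  grassland; a field fallow in a single year shows a bright stubble
  signature distinct from natural bare soil.
- **Spectra** — per-cover seasonal NDVI Gaussians; bands are synthesised
  from NDVI v and a per-cover brightness sum s as NIR = s(1+v)/2,
  Red = s(1−v)/2 (green/blue tied to red), truncated to [0, 1].  Active
  cropland's ΔNDVI is drawn with mean 0.5713 and total sd 0.113 — the
  training statistics the threshold rule is built from — split into a
  between-field (sd 0.05) and a within-field (sd 0.1013) component; the
  split is a free choice made so that field-count sampling noise does not
  dominate scene-level moments at the default size.  All other covers
  keep mean ΔNDVI well below the 0.30291 threshold; water NDVI is
  truncated negative in both seasons.
- **Contamination** — each spring scene carries, with probability 0.4, a
  haze patch (10–20 cells a side): additive blue/green offset, NDVI
  depression, and a set quality flag.  Summer scenes are clean, matching
  the seasonal asymmetry of archive availability.
- **Sampling** — 333 stratified training points of which 51 cropland
  (the study's training set), and 240 validation points placed at equal
  intervals along a serpentine road on the plain, offset half a cell to
  the right-hand side of the direction of travel; the same locations are
  labeled per period from each period's truth map.  On the scaled-down
  scene the transect spacing is road-length/240 (≈90 m) rather than the
  1 km of a governorate-scale survey.

What passing tests on this generator do **not** show: performance under
real atmospheric variability, georegistration error, mixed pixels at
field boundaries smaller than the cell size, crop-type spectral
diversity, or inter-annual precipitation effects on grassland phenology —
the confusers here are statistically clean Gaussians.  The end-to-end
recovery bound (≤15 % per period) is a property of this controlled
setting, not a field-accuracy claim.

## Problem sizes and numerical choices

Default test/acceptance sizes: 96×96 cells, 3 spring + 2 summer scenes
per period, 4 periods (20 scenes); segmentation of four scenes takes a
few seconds; the coverage simulation uses 500 replicates of 240 points.
Exact-oracle segmentation checks run on ≤5×5 instances against a
from-scratch brute-force simulator with identical decision rules.
Floating-point ties in fusion costs are resolved with a 1e-12
strict-improvement margin before the lexicographic tie-break.  Rasters
round-trip bit-exactly for integer grids and to 10 significant digits for
floats.

## Known limitations

- No aerosol inversion, topographic illumination correction, or LEDAPS
  port; DOS3 with Rayleigh-only transmittance is the only built-in
  correction.
- No hierarchical multi-level segmentation; the merge loop is quadratic
  in the worst case and intended for scenes up to a few hundred cells a
  side, not full Landsat tiles.
- Two-class accuracy workflow only (cropland vs other), as the estimator
  types permit but do not exercise more classes.
- No crop-type discrimination, irrigation detection, or spatially
  explicit error mapping.
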