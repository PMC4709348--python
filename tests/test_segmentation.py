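"""Region-merging segmentation: exact small-instance oracle, invariants,
zonal statistics and the water-centroid rule."""

import datetime
import math

import numpy as np
import pytest
from shapely.geometry import Polygon, box

from phenocrop.grid import RasterGrid
from phenocrop.io_pipeline import BandStack
from phenocrop.segmentation import (SegmentationParams, layer_from_labels,
                                    mask_water, multiresolution_segment,
                                    zonal_attributes)

ND = -9999.0


def stack_of(*band_arrays, roles=("red",)):
    bands = {r: RasterGrid(np.asarray(a, dtype=float), nodata=ND)
             for r, a in zip(roles, band_arrays)}
    return BandStack(bands=bands, acquisition_date=datetime.date(2000, 4, 1),
                     season="spring", period="A",
                     value_kind="surface_reflectance")


def partition_of(labels: np.ndarray) -> set[frozenset]:
    out = {}
    for r, c in zip(*np.nonzero(labels >= 0)):
        out.setdefault(labels[r, c], set()).add((int(r), int(c)))
    return {frozenset(v) for v in out.values()}


# ---------------------------------------------------------------------------
# Independent brute-force simulator: recomputes every statistic from raw
# cell sets at every step (no incremental bookkeeping), same decision rules.


def oracle_segment(cube: np.ndarray, scale: float, w_shape: float = 0.1,
                   w_cmpct: float = 0.1) -> set[frozenset]:
    nb, nrows, ncols = cube.shape
    regions: dict[int, set[tuple[int, int]]] = {}
    ids = {}
    k = 0
    for r in range(nrows):
        for c in range(ncols):
            regions[k] = {(r, c)}
            ids[(r, c)] = k
            k += 1

    def perimeter(cells):
        p = 0
        for r, c in cells:
            for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                if (r + dr, c + dc) not in cells:
                    p += 1
        return float(p)

    def h(cells):
        n = len(cells)
        h_color = 0.0
        for b in range(nb):
            vals = [cube[b, r, c] for r, c in cells]
            mu = sum(vals) / n
            var = sum(v * v for v in vals) / n - mu * mu
            if var > 0:
                h_color += n * math.sqrt(var)
        rs = [r for r, _ in cells]
        cs = [c for _, c in cells]
        bb = 2.0 * ((max(rs) - min(rs) + 1) + (max(cs) - min(cs) + 1))
        l = perimeter(cells)
        h_shape = w_cmpct * l / math.sqrt(n) + (1 - w_cmpct) * l / bb
        return h_color, h_shape

    def cost(i, j):
        hci, hsi = h(regions[i])
        hcj, hsj = h(regions[j])
        hcm, hsm = h(regions[i] | regions[j])
        return w_shape * (hsm - hsi - hsj) + (1 - w_shape) * (hcm - hci - hcj)

    def neighbors(i):
        out = set()
        for r, c in regions[i]:
            for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                q = (r + dr, c + dc)
                if q in ids and ids[q] != i:
                    out.add(ids[q])
        return out

    def best(i):
        bj, bf = -1, math.inf
        for j in sorted(neighbors(i)):
            f = cost(i, j)
            if f < bf - 1e-12:
                bj, bf = j, f
        return (None if bj < 0 else (bj, bf))

    threshold = scale * scale
    while True:
        merged = False
        for i in sorted(regions):
            if i not in regions:
                continue
            b = best(i)
            if b is None or b[1] >= threshold:
                continue
            j = b[0]
            back = best(j)
            if back is None or back[0] != i:
                continue
            a, z = min(i, j), max(i, j)
            regions[a] = regions[a] | regions[z]
            for cell in regions[z]:
                ids[cell] = a
            del regions[z]
            merged = True
        if not merged:
            return {frozenset(v) for v in regions.values()}


class TestMergeEngine:
    def test_uniform_image_collapses_to_one_segment(self):
        layer = multiresolution_segment(
            stack_of(np.full((6, 6), 0.4)),
            SegmentationParams(scale=1.0, band_weights={"red": 1.0}))
        assert layer.n_segments == 1
        assert layer.segments[0].n_cells == 36

    def test_two_colored_halves_give_two_segments(self):
        img = np.array([[0.1, 0.9], [0.1, 0.9]])
        layer = multiresolution_segment(
            stack_of(img), SegmentationParams(scale=1.0,
                                              band_weights={"red": 1.0}),
            polygonize=False)
        assert partition_of(layer.labels.values) == {
            frozenset({(0, 0), (1, 0)}), frozenset({(0, 1), (1, 1)})}

    @pytest.mark.parametrize("shape", [(3, 3), (4, 5), (5, 5)])
    def test_matches_brute_force_oracle_on_small_instances(self, shape):
        rng = np.random.default_rng(sum(shape))
        params = SegmentationParams(scale=0.8, band_weights={"red": 1.0})
        for trial in range(6):
            img = np.round(rng.random(shape), 2)
            layer = multiresolution_segment(stack_of(img), params,
                                            polygonize=False)
            expected = oracle_segment(img[None, :, :], scale=0.8)
            assert partition_of(layer.labels.values) == expected

    def test_scale_monotonicity_on_random_fixtures(self):
        rng = np.random.default_rng(42)
        params_lo = SegmentationParams(scale=0.5, band_weights={"red": 1.0})
        params_hi = SegmentationParams(scale=1.5, band_weights={"red": 1.0})
        for _ in range(50):
            img = rng.random((6, 6))
            n_lo = multiresolution_segment(stack_of(img), params_lo,
                                           polygonize=False).n_segments
            n_hi = multiresolution_segment(stack_of(img), params_hi,
                                           polygonize=False).n_segments
            assert n_lo >= n_hi

    def test_partition_property_on_synthetic_scene(self, layers):
        for layer in layers.values():
            labels = layer.labels.values
            assert (labels >= 0).all()
            counts = layer.cell_counts()
            assert counts == {i: s.n_cells for i, s in layer.segments.items()}
            assert sum(counts.values()) == labels.size

    def test_identical_halves_get_identical_statistics(self):
        rng = np.random.default_rng(9)
        half = rng.random((4, 2))
        img = np.hstack([half, np.full((4, 1), 9.0), half])
        layer = multiresolution_segment(
            stack_of(img), SegmentationParams(scale=1.0,
                                              band_weights={"red": 1.0}),
            polygonize=False)
        parts = partition_of(layer.labels.values)
        left = {part for part in parts if all(c <= 1 for _, c in part)}
        right_shifted = {frozenset({(r, c - 3) for r, c in part})
                         for part in parts
                         if all(c >= 3 for _, c in part)}
        assert left == right_shifted

    def test_nonfinite_input_rejected(self):
        img = np.full((2, 2), np.nan)
        with pytest.raises(ValueError, match="non-finite"):
            multiresolution_segment(
                stack_of(img),
                SegmentationParams(scale=1.0, band_weights={"red": 1.0}))

    def test_param_validation(self):
        with pytest.raises(ValueError):
            SegmentationParams(scale=0)
        with pytest.raises(ValueError):
            SegmentationParams(shape_weight=1.0)
        with pytest.raises(ValueError):
            SegmentationParams(band_weights={"red": 0.0})


class TestZonalAttributes:
    def make_layer(self):
        labels = RasterGrid(np.array([[0, 0, 1], [0, 1, 1]]), nodata=-1)
        return layer_from_labels(labels)

    def test_simple_mean(self):
        layer = self.make_layer()
        grid = RasterGrid(np.array([[0.2, 0.4, 0.6], [0.3, 0.5, 0.7]]),
                          nodata=ND)
        zonal_attributes(layer, {"ndvi_diff": grid})
        assert layer.segments[0].mean_ndvi_diff == pytest.approx(0.3)
        assert layer.segments[1].mean_ndvi_diff == pytest.approx(0.6)

    def test_constant_field(self):
        layer = self.make_layer()
        grid = RasterGrid(np.full((2, 3), 0.42), nodata=ND)
        zonal_attributes(layer, {"slope": grid})
        for seg in layer.segments.values():
            assert seg.mean_slope == pytest.approx(0.42)

    def test_matches_brute_force_on_random_grid(self, layers, composites):
        layer = layers["B"]
        grid = composites["B"].difference
        labels = layer.labels.values
        for i, seg in layer.segments.items():
            cells = grid.values[(labels == i) & grid.mask]
            assert seg.mean_ndvi_diff == pytest.approx(cells.mean(), rel=1e-9)

    def test_no_valid_cells_gives_nan(self):
        layer = self.make_layer()
        grid = RasterGrid(np.array([[ND, ND, 0.5], [ND, 0.5, 0.5]]), nodata=ND)
        zonal_attributes(layer, {"ndvi_diff": grid})
        assert math.isnan(layer.segments[0].mean_ndvi_diff)
        assert layer.segments[1].mean_ndvi_diff == pytest.approx(0.5)


class TestWaterMask:
    def test_empty_water_set_masks_nothing(self, layers):
        import copy
        layer = layer_from_labels(layers["A"].labels)
        mask_water(layer, [])
        assert not any(s.masked for s in layer.segments.values())

    def test_segment_inside_lake_is_masked(self):
        labels = RasterGrid(np.array([[0, 1], [0, 1]]), nodata=-1,
                            cell_size=1.0, origin=(0.0, 2.0))
        layer = layer_from_labels(labels, polygonize=True)
        lake = box(0.0, 0.0, 1.0, 2.0)   # covers column 0 exactly
        mask_water(layer, [lake])
        assert layer.segments[0].masked
        assert not layer.segments[1].masked

    def test_c_shape_masked_by_centroid_rule(self):
        """A C-shaped segment whose area centroid falls inside a small lake
        in its notch is masked even though every cell is on land."""
        lab = -np.ones((5, 5), dtype=np.int64)
        lab[:, 0] = 0
        lab[0, :] = 0
        lab[4, :] = 0
        labels = RasterGrid(lab, nodata=-1, cell_size=1.0, origin=(0.0, 5.0))
        layer = layer_from_labels(labels, polygonize=True)
        cx, cy = layer.segments[0].centroid
        lake = box(cx - 0.3, cy - 0.3, cx + 0.3, cy + 0.3)
        # the lake sits in the notch: no segment cell overlaps it
        assert layer.segments[0].polygon.intersection(lake).area == pytest.approx(0.0)
        mask_water(layer, [lake])
        assert layer.segments[0].masked

    def test_invalid_water_polygon_rejected(self):
        labels = RasterGrid(np.zeros((2, 2), dtype=np.int64), nodata=-1)
        layer = layer_from_labels(labels, polygonize=True)
        bowtie = Polygon([(0, 0), (1, 1), (1, 0), (0, 1)])
        with pytest.raises(ValueError, match="invalid"):
            mask_water(layer, [bowtie])
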