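"""Threshold derivation, slope computation, classification rule and overlay."""

import math

import numpy as np
import pytest

from phenocrop import classification_change as cch
from phenocrop.classification_change import (CROP, OTHER, TrainingStats,
                                             classify_period,
                                             derive_thresholds,
                                             overlay_periods, slope_grid)
from phenocrop.grid import RasterGrid
from phenocrop.io_pipeline import SamplePoint
from phenocrop.segmentation import Segment, SegmentLayer


def points_on_grid(grid, values_labels):
    """Place training points on distinct cells carrying given diff values."""
    pts = []
    vals = grid.values
    k = 0
    for v, label in values_labels:
        r, c = divmod(k, grid.shape[1])
        vals[r, c] = v
        x, y = grid.cell_center(r, c)
        pts.append(SamplePoint(x, y, label, "training"))
        k += 1
    return pts


class TestDeriveThresholds:
    def test_zero_variance_gives_threshold_at_mean(self):
        diff = RasterGrid(np.zeros((3, 3)))
        slope = RasterGrid(np.zeros((3, 3)))
        pts = points_on_grid(diff, [(0.5, "cropland")] * 4)
        stats = derive_thresholds(pts, diff, slope, k_ndvi=2.3)
        assert stats.t_ndvi == pytest.approx(0.5)

    def test_rule_arithmetic_matches_direct_computation(self):
        diff = RasterGrid(np.zeros((4, 4)))
        slope = RasterGrid(np.zeros((4, 4)))
        crop_vals = [0.45, 0.52, 0.58, 0.63, 0.70]
        slope_vals = [1.0, 2.0, 1.5, 2.5, 3.0]
        pts = points_on_grid(diff, [(v, "cropland") for v in crop_vals])
        for p, s in zip(pts, slope_vals):
            r, c = diff.index_of(p.x, p.y)
            slope.values[r, c] = s
        stats = derive_thresholds(pts, diff, slope, k_ndvi=2.3, k_slope=2.0)
        assert stats.t_ndvi == pytest.approx(
            np.mean(crop_vals) - 2.3 * np.std(crop_vals, ddof=1))
        assert stats.t_slope == pytest.approx(
            np.mean(slope_vals) + 2.0 * np.std(slope_vals, ddof=1))

    def test_sampling_recovery_with_known_population(self):
        rng = np.random.default_rng(6)
        mu, sd, n = 0.5713, 0.113, 51
        vals = rng.normal(mu, sd, n)
        side = int(np.ceil(np.sqrt(n)))
        diff = RasterGrid(np.zeros((side, side)))
        slope = RasterGrid(np.zeros((side, side)))
        pts = points_on_grid(diff, [(v, "cropland") for v in vals])
        stats = derive_thresholds(pts, diff, slope, k_ndvi=2.3)
        assert abs(stats.t_ndvi - (mu - 2.3 * sd)) < 3 * sd / math.sqrt(n) * 3

    def test_per_cover_table(self):
        diff = RasterGrid(np.zeros((3, 3)))
        slope = RasterGrid(np.zeros((3, 3)))
        pts = points_on_grid(diff, [(0.5, "cropland"), (0.6, "cropland"),
                                    (0.1, "grassland"), (0.2, "grassland"),
                                    (0.05, "bare soil")])
        stats = derive_thresholds(pts, diff, slope)
        assert stats.per_cover["grassland"]["median"] == pytest.approx(0.15)
        assert stats.per_cover["bare soil"]["n"] == 1

    def test_too_few_cropland_points(self):
        diff = RasterGrid(np.zeros((2, 2)))
        pts = points_on_grid(diff, [(0.5, "cropland"), (0.1, "grassland")])
        with pytest.raises(ValueError, match="at least 2 cropland"):
            derive_thresholds(pts, diff, RasterGrid(np.zeros((2, 2))))


class TestSlopeGrid:
    def test_flat_dem_is_zero(self):
        out = slope_grid(RasterGrid(np.full((5, 5), 321.0), cell_size=30.0))
        np.testing.assert_allclose(out.values, 0.0, atol=1e-12)

    def test_unit_plane_gives_45_degrees_interior(self):
        cols = np.arange(8, dtype=float)
        dem = RasterGrid(np.tile(cols, (6, 1)), cell_size=1.0)
        out = slope_grid(dem).values
        np.testing.assert_allclose(out[1:-1, 1:-1], 45.0, atol=1e-9)

    def test_matches_direct_horn_oracle(self):
        rng = np.random.default_rng(3)
        dem = RasterGrid(rng.uniform(100, 900, (12, 10)), cell_size=30.0)
        out = slope_grid(dem).values
        z = np.pad(dem.values, 1, mode="edge")
        for r in range(12):
            for c in range(10):
                w = z[r:r + 3, c:c + 3]
                dzdx = ((w[0, 2] + 2 * w[1, 2] + w[2, 2])
                        - (w[0, 0] + 2 * w[1, 0] + w[2, 0])) / (8 * 30.0)
                dzdy = ((w[2, 0] + 2 * w[2, 1] + w[2, 2])
                        - (w[0, 0] + 2 * w[0, 1] + w[0, 2])) / (8 * 30.0)
                expected = math.degrees(math.atan(math.hypot(dzdx, dzdy)))
                assert out[r, c] == pytest.approx(expected, abs=1e-9)

    def test_degenerate_dem_rejected(self):
        with pytest.raises(ValueError):
            slope_grid(RasterGrid(np.zeros((1, 5))))


def layer_with(segments_spec):
    """SegmentLayer from (diff, slope, n_cells[, masked]) tuples; labels
    raster is a single row with one run of cells per segment."""
    total = sum(s[2] for s in segments_spec)
    lab = np.empty((1, total), dtype=np.int64)
    segs = {}
    pos = 0
    for i, spec in enumerate(segments_spec):
        diff, slope, n = spec[:3]
        masked = bool(spec[3]) if len(spec) > 3 else False
        lab[0, pos:pos + n] = i
        pos += n
        segs[i] = Segment(id=i, n_cells=n, perimeter_m=0.0, band_mean={},
                          band_sd={}, mean_ndvi_diff=diff, mean_slope=slope,
                          masked=masked, area_km2=n * 9e-4)
    return SegmentLayer(labels=RasterGrid(lab, nodata=-1), segments=segs)


def stated_stats():
    return TrainingStats.from_defaults()


class TestClassifyPeriod:
    def test_ndvi_boundary_is_inclusive(self):
        layer = layer_with([(0.30291, 0.0, 4), (0.30290, 0.0, 4)])
        cl = classify_period(layer, stated_stats())
        assert layer.segments[0].class_label == CROP
        assert layer.segments[1].class_label == OTHER

    def test_slope_boundary_is_exclusive(self):
        layer = layer_with([(0.9, 7.625, 4), (0.9, 7.624, 4)])
        cl = classify_period(layer, stated_stats())
        assert layer.segments[0].class_label == OTHER
        assert layer.segments[1].class_label == CROP

    def test_all_below_threshold_yields_null_map(self):
        layer = layer_with([(0.1, 0.0, 5), (0.2, 1.0, 5)])
        cl = classify_period(layer, stated_stats())
        assert cl.crop_area_km2 == 0.0
        assert cl.proportions[OTHER] == pytest.approx(1.0)

    def test_masked_segments_excluded_from_proportions(self):
        layer = layer_with([(0.9, 0.0, 5), (0.9, 0.0, 5, True)])
        cl = classify_period(layer, stated_stats())
        assert cl.proportions[CROP] == pytest.approx(1.0)
        assert layer.segments[1].class_label is None

    def test_monotone_in_thresholds(self):
        rng = np.random.default_rng(12)
        spec = [(rng.uniform(0, 0.8), rng.uniform(0, 12), 2)
                for _ in range(40)]
        layer = layer_with(spec)

        def crop_set(t_ndvi, t_slope):
            s = stated_stats()
            s.t_ndvi, s.t_slope = t_ndvi, t_slope
            classify_period(layer, s)
            return {i for i, sg in layer.segments.items()
                    if sg.class_label == CROP}

        assert crop_set(0.4, 7.625) <= crop_set(0.3, 7.625)
        assert crop_set(0.3, 5.0) <= crop_set(0.3, 9.0)

    def test_missing_attributes_rejected(self):
        layer = layer_with([(float("nan"), 0.0, 3)])
        with pytest.raises(ValueError, match="zonal_attributes"):
            classify_period(layer, stated_stats())


def classification_from_mask(period, mask, cell_size=30.0):
    grid = RasterGrid(mask.astype(np.int8), cell_size=cell_size, nodata=-1)
    layer = SegmentLayer(labels=RasterGrid(
        np.zeros(mask.shape, dtype=np.int64), cell_size=cell_size, nodata=-1),
        segments={})
    area = float(mask.sum()) * grid.cell_area_km2()
    return cch.PeriodClassification(
        period=period, layer=layer, crop_area_km2=area,
        proportions={CROP: 0.0, OTHER: 1.0}, crop_mask=grid)


class TestOverlay:
    def test_identity_overlay(self):
        mask = np.zeros((10, 10), dtype=bool)
        mask[2:5, 2:7] = True
        cls = {p: classification_from_mask(p, mask) for p in "ABCD"}
        out = overlay_periods(cls)
        cell = cls["A"].crop_mask.cell_area_km2()
        assert out.categories["stable_all_periods"] == pytest.approx(15 * cell)
        assert out.union_area_km2 == pytest.approx(15 * cell)
        for code, area in out.area_by_code.items():
            if code not in (0, 0b1111):
                assert area == 0.0

    def test_disjoint_periods(self):
        masks = {}
        for k, p in enumerate("ABCD"):
            m = np.zeros((8, 8), dtype=bool)
            m[k * 2:k * 2 + 2, :] = True
            masks[p] = m
        cls = {p: classification_from_mask(p, m) for p, m in masks.items()}
        out = overlay_periods(cls)
        cell = cls["A"].crop_mask.cell_area_km2()
        assert out.categories["stable_all_periods"] == 0.0
        assert out.union_area_km2 == pytest.approx(64 * cell)
        assert out.categories["new_in_D"] == pytest.approx(16 * cell)

    def test_random_layers_match_brute_force_tabulation(self):
        rng = np.random.default_rng(5)
        masks = {p: rng.random((20, 20)) < 0.4 for p in "ABCD"}
        cls = {p: classification_from_mask(p, m) for p, m in masks.items()}
        out = overlay_periods(cls)
        cell = cls["A"].crop_mask.cell_area_km2()
        for code in range(16):
            want = np.ones((20, 20), dtype=bool)
            for bit, p in zip((3, 2, 1, 0), "ABCD"):
                present = bool(code >> bit & 1)
                want &= masks[p] == present
            assert out.area_by_code[code] == pytest.approx(want.sum() * cell)

    def test_area_conservation(self):
        rng = np.random.default_rng(8)
        masks = {p: rng.random((15, 17)) < 0.5 for p in "ABCD"}
        cls = {p: classification_from_mask(p, m) for p, m in masks.items()}
        out = overlay_periods(cls)
        total = sum(out.area_by_code.values())
        cell = cls["A"].crop_mask.cell_area_km2()
        assert total == pytest.approx(15 * 17 * cell)

    def test_report_filter_never_drops_totals(self):
        rng = np.random.default_rng(9)
        masks = {p: rng.random((10, 10)) < 0.5 for p in "ABCD"}
        cls = {p: classification_from_mask(p, m) for p, m in masks.items()}
        small = overlay_periods(cls, min_report_area_km2=1e9)
        assert small.reported_codes == []
        assert sum(small.area_by_code.values()) == pytest.approx(
            100 * cls["A"].crop_mask.cell_area_km2())

    def test_missing_period_rejected(self):
        mask = np.zeros((4, 4), dtype=bool)
        cls = {p: classification_from_mask(p, mask) for p in "ABC"}
        with pytest.raises(ValueError, match="missing"):
            overlay_periods(cls)
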