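"""Shared fixtures: one synthetic study (seed 1) processed end to end.

Session-scoped so the generator and the four segmentations run once for
the whole suite.
"""

import numpy as np
import pytest

from phenocrop import accuracy as acc
from phenocrop import classification_change as cch
from phenocrop import compositing, segmentation
from phenocrop import synthetic_scene as synth

PERIODS = ("A", "B", "C", "D")


@pytest.fixture(scope="session")
def bundle():
    return synth.generate_scene_collection(synth.SceneTemplate(seed=1))


@pytest.fixture(scope="session")
def composites(bundle):
    return {p: compositing.build_period_composite(p, bundle.scenes_of(p))
            for p in PERIODS}


@pytest.fixture(scope="session")
def slope(bundle):
    return cch.slope_grid(bundle.dem)


@pytest.fixture(scope="session")
def seg_params():
    return segmentation.SegmentationParams(scale=segmentation.REFLECTANCE_SCALE)


@pytest.fixture(scope="session")
def layers(bundle, composites, slope, seg_params):
    out = {}
    for p in PERIODS:
        layer = segmentation.multiresolution_segment(
            bundle.segmentation_scene(p), seg_params, seed=1)
        segmentation.zonal_attributes(
            layer, {"ndvi_diff": composites[p].difference, "slope": slope})
        segmentation.mask_water(layer, bundle.water)
        out[p] = layer
    return out


@pytest.fixture(scope="session")
def training_stats(bundle, composites, slope):
    return cch.derive_thresholds(bundle.training, composites["D"].difference,
                                 slope)


@pytest.fixture(scope="session")
def classifications(layers, training_stats):
    return {p: cch.classify_period(layers[p], training_stats, period=p)
            for p in PERIODS}
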