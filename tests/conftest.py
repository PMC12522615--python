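import numpy as np
import pytest

from periopano import synth_pano
from periopano.annotations_io import AnnotationScene, PolygonContour


@pytest.fixture
def rectangle_tooth() -> PolygonContour:
    """A 20x100 vertical rectangle centered at x=50 (unambiguous axis)."""
    return PolygonContour("31", [(40.0, 0.0), (60.0, 0.0), (60.0, 100.0), (40.0, 100.0)])


@pytest.fixture
def simple_scene() -> AnnotationScene:
    """A hand-built one-tooth mandibular scene with known landmarks.

    Tooth 31 spans y in [40, 240]; CEJ band [100, 102]; the bone contour's
    upper boundary crosses the axis at y=120 -> D1=20, D2=100, RBL=20%.
    """
    tooth = PolygonContour("31", [(40.0, 40.0), (60.0, 40.0), (60.0, 240.0), (40.0, 240.0)])
    cej = PolygonContour("cej_lower", [(0.0, 100.0), (100.0, 100.0), (100.0, 102.0), (0.0, 102.0)])
    bone = PolygonContour("bone", [(0.0, 120.0), (100.0, 120.0), (100.0, 300.0), (0.0, 300.0)])
    return AnnotationScene(
        image_width=100, image_height=300,
        teeth={31: tooth}, cej={"mandibular": cej}, bone=bone,
    )


@pytest.fixture
def synthetic_truth():
    """One default synthetic scene (seeded) with its ground truth."""
    image, truth = synth_pano.generate_scene(synth_pano.SyntheticSceneConfig(seed=11))
    return image, truth


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
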