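import numpy as np
import pytest

from plantwatch.fuzzy import default_engine
from plantwatch.imaging import CropRect
from plantwatch.synthetic import SceneSpec, SpotSpec, make_leaf_scene, scene_crop


@pytest.fixture(scope="session")
def engine():
    return default_engine()


@pytest.fixture(scope="session")
def intensity_set(engine):
    return engine.inputs_by_name["Intensity"]


@pytest.fixture(scope="session")
def area_set(engine):
    return engine.inputs_by_name["Area"]


@pytest.fixture(scope="session")
def output_set(engine):
    return engine.output_set


@pytest.fixture
def simple_scene():
    """A gradient-free scene with one clear defect and one faint noise spot."""
    spec = SceneSpec(
        defects=(SpotSpec(row=230.0, col=300.0, radius=33.0, intensity=30.0),),
        noise=(SpotSpec(row=300.0, col=400.0, radius=20.0, intensity=185.0),),
        pixel_noise_sigma=1.0,
        seed=7,
    )
    frame, truth = make_leaf_scene(spec)
    return spec, frame, truth, scene_crop(spec)
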