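import numpy as np
import pandas as pd
import pytest

from acornsight import (
    SceneParams,
    extract_features,
    generate_dataset,
    generate_scene,
    normalise,
)
from acornsight.segmentation import override_circle


def small_scene_params(**overrides) -> SceneParams:
    """A compact scene geometry that keeps unit tests fast."""
    defaults = dict(
        image_width=220, image_height=180, patch_size=40,
        circle_centre=(130.0, 100.0), circle_radius=60.0,
        noise_sd=0.0, seed=0,
    )
    defaults.update(overrides)
    return SceneParams(**defaults)


@pytest.fixture
def small_params() -> SceneParams:
    return small_scene_params()


@pytest.fixture
def small_scene(small_params):
    return generate_scene(small_params)


def features_table(dataset, manifest, normalised: bool) -> pd.DataFrame:
    """Feature table for a generated dataset, using ground-truth masks."""
    rows = []
    for (scene, _), (_, m) in zip(dataset, manifest.iterrows()):
        mask = override_circle(scene.pixels.shape[:2],
                               (m["circle_x"], m["circle_y"]), m["radius"])
        pixels = normalise(scene).pixels if normalised else scene.pixels
        fv = extract_features(pixels, mask, sequence_id=scene.sequence_id)
        rows.append(fv.as_dict() | {"label": int(m["germinating"])})
    return pd.DataFrame(rows)


@pytest.fixture(scope="session")
def study_dataset():
    """The full-size synthetic study: 400 scenes, 183 germinating, with
    step illumination drift — shared across tests that need it."""
    return generate_dataset(400, 183.0 / 400.0, "step", seed=11)


@pytest.fixture(scope="session")
def study_features(study_dataset):
    """Raw and normalised feature tables for the 400-scene study set."""
    dataset, manifest = study_dataset
    return (features_table(dataset, manifest, normalised=False),
            features_table(dataset, manifest, normalised=True))
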