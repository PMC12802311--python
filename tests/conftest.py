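import warnings

import numpy as np
import pytest
from hypothesis import settings

import swarmetrics as sw

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("ci")

warnings.filterwarnings("ignore", category=FutureWarning)


@pytest.fixture(scope="session")
def small_scene():
    """A 51.2 µm square scene with 60 cells, 10 debris and a fluorescence channel."""
    cfg = sw.SceneConfig(
        image_size=(512, 512),
        n_cells=60,
        n_debris=10,
        seed=3,
        fluorescence_model=sw.FluorescenceModel(),
    )
    return sw.generate_scene(cfg)


@pytest.fixture(scope="session")
def sparse_scene():
    """A low-density, low-noise scene (mostly isolated cells)."""
    cfg = sw.SceneConfig(
        image_size=(600, 600),
        n_cells=15,
        n_debris=0,
        filament_density=0.0,
        noise_sd=0.01,
        seed=5,
    )
    return sw.generate_scene(cfg)


@pytest.fixture(scope="session")
def trained_classifier():
    """Classifier trained on two annotated mid-density frames."""
    scenes = []
    for hour, seed in ((2, 101), (6, 102)):
        cfg = sw.timecourse_presets(hour)
        cfg.image_size = (600, 600)
        cfg.n_cells = 160
        cfg.seed = seed
        scenes.append(sw.generate_scene(cfg))
    anns = [
        sw.annotations_from_truth(truth, n_per_class=3000, seed=7 + i)
        for i, (_, _, truth) in enumerate(scenes)
    ]
    return sw.train_classifier([s[0] for s in scenes], anns, seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
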