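import numpy as np
import pytest

from denseleaf.boxes import BoundingBox, ScoredBox
from denseleaf.model import MiniDetector, ModelConfig
from denseleaf.scenes import SceneSpec, generate_scenes


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def random_box(rng, span=100.0, min_side=2.0, max_side=40.0) -> BoundingBox:
    x0 = rng.uniform(0, span - max_side)
    y0 = rng.uniform(0, span - max_side)
    w = rng.uniform(min_side, max_side)
    h = rng.uniform(min_side, max_side)
    return BoundingBox(x0, y0, x0 + w, y0 + h)


def random_scored(rng, n, **kw) -> list[ScoredBox]:
    return [ScoredBox(random_box(rng, **kw), float(rng.uniform(0, 1))) for _ in range(n)]


@pytest.fixture
def tiny_model_config():
    """A desk-scale detector configuration used across model tests."""
    return ModelConfig(channels=16, num_levels=2, num_queries=40,
                       num_extra_queries=40, decoder_layers=1, seed=11)


@pytest.fixture
def tiny_model(tiny_model_config):
    return MiniDetector(tiny_model_config)


@pytest.fixture(scope="session")
def small_scenes():
    """Twenty 64x64 scenes at mean density 10, shared across tests."""
    spec = SceneSpec(width=64, height=64, mean_instances=10.0,
                     semi_major_range=(8.0, 14.0), semi_minor_range=(5.0, 9.0),
                     seed=101)
    return generate_scenes(spec, 20)
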