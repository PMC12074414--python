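import numpy as np
import pytest

from crownseg.architecture import LayerSpec, ModelSpec


@pytest.fixture
def rng():
    return np.random.Generator(np.random.PCG64(1234))


@pytest.fixture
def tiny_spec() -> ModelSpec:
    """A miniature encoder-decoder with one skip, for fast end-to-end tests."""
    spec = ModelSpec(
        [
            LayerSpec("c1", "conv3x3", 3, 4, 1, activation="relu"),
            LayerSpec("p1", "maxpool2", 4, 4, 2),
            LayerSpec("c2", "conv3x3", 4, 6, 2, activation="relu"),
            LayerSpec("u1", "upsample2x", 6, 6, 1),
            LayerSpec("k1", "concat_skip", 6, 10, 1, skip_source="c1"),
            LayerSpec("c3", "conv3x3", 10, 4, 1, activation="relu"),
            LayerSpec("h", "conv1x1", 4, 3, 1),
        ],
        name="tiny",
    )
    spec.validate()
    return spec
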