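import numpy as np
import pytest

import plateqc as pq


@pytest.fixture(scope="session")
def neuro_scene():
    """One reference three-channel scene (40 cells, all neurons, 25% TH+)."""
    image, truth = pq.gen_neuro_scene(256, 256, 40, neuron_fraction=1.0,
                                      th_fraction_of_neurons=0.25, seed=1)
    return image, truth


@pytest.fixture(scope="session")
def segmented_scene(neuro_scene):
    image, truth = neuro_scene
    result = pq.segment_scene(image.channel(1), image.channel(2), image.channel(0))
    return result, truth


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
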