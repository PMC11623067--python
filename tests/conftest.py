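import numpy as np
import pytest

from hierbanet import SynthConfig, TensorShape, build_hierbanet, generate_dataset
from hierbanet.data import ArrayDataset
from hierbanet.training import init_weights


@pytest.fixture(scope="session")
def tiny_graph():
    """Desk-scale variant: 32x32 input, base width 4, 2 blocks, 3 classes."""
    return build_hierbanet(TensorShape(32, 32, 3), num_classes=3, num_blocks=2, base_width=4)


@pytest.fixture(scope="session")
def tiny_params(tiny_graph):
    return init_weights(tiny_graph, seed=11)


@pytest.fixture(scope="session")
def synth_index(tmp_path_factory):
    """Small synthetic dataset shared across tests: 30 images/class at 32x32."""
    out = tmp_path_factory.mktemp("synth32")
    cfg = SynthConfig(n_per_class=30, image_size=32, noise_sd=10.0, seed=7)
    return generate_dataset(cfg, out)


@pytest.fixture(scope="session")
def synth_data(synth_index):
    return ArrayDataset.load(synth_index, size=32)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
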