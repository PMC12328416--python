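import numpy as np
import pytest

from sonoseg import ModelConfig
from sonoseg.synthetic import generate_dataset
from sonoseg.cli import load_pair_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_cfg():
    """Desk-scale model: 4x4 token grid, width 48, 2+1 layers."""
    return ModelConfig(patch_size=14, image_size=56, embed_dim=48,
                       encoder_layers=2, mae_decoder_layers=2,
                       seg_decoder_layers=1, heads=3)


@pytest.fixture(scope="session")
def small_corpus(tmp_path_factory):
    """Eight 56x56 phantom image/mask pairs shared across tests."""
    root = tmp_path_factory.mktemp("corpus")
    generate_dataset(8, 56, seed=7, out_dir=root)
    pairs, stems = load_pair_dataset(root)
    return {"dir": root, "pairs": pairs, "stems": stems}
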