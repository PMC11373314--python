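import numpy as np
import pytest

from fraglink.decoder import DecoderConfig, init_decoder_params
from fraglink.encoder import EncoderConfig, init_encoder_params
from fraglink.fixtures import ToyDatasetConfig, generate_toy_dataset
from fraglink.molgraph import parse_smiles


@pytest.fixture(scope="session")
def toy_dataset():
    """Small shared dataset for unit tests."""
    return generate_toy_dataset(ToyDatasetConfig(n_examples=40, seed=7))


@pytest.fixture(scope="session")
def enc_cfg():
    return EncoderConfig()


@pytest.fixture(scope="session")
def dec_cfg():
    return DecoderConfig()


@pytest.fixture(scope="session")
def random_params(enc_cfg, dec_cfg):
    """Untrained (random) model parameters, gcn backbone."""
    rng = np.random.default_rng(12345)
    return {**init_encoder_params(enc_cfg, rng),
            **init_decoder_params(enc_cfg, dec_cfg, rng)}


@pytest.fixture(scope="session")
def censnet_cfg():
    return EncoderConfig(backbone="censnet")


@pytest.fixture(scope="session")
def censnet_params(censnet_cfg, dec_cfg):
    rng = np.random.default_rng(54321)
    return {**init_encoder_params(censnet_cfg, rng),
            **init_decoder_params(censnet_cfg, dec_cfg, rng)}


@pytest.fixture
def fragment_pair():
    return parse_smiles("CC(C)*"), parse_smiles("OC*")
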