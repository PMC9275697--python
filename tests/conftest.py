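import numpy as np
import pytest
from hypothesis import settings

from revhom.encoding import AA_INDEX
from revhom.model import EncoderConfig, ReverseHomologyModel

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def tiny_config():
    """Small encoder used in fast unit tests."""
    return EncoderConfig(L_std=32, branch_kernels=(1, 3), branch_filters=4,
                         conv2_kernel=3, conv2_filters=6,
                         conv3_kernel=3, conv3_filters=8, fc_dims=(12, 12))


@pytest.fixture
def tiny_model(tiny_config):
    return ReverseHomologyModel(tiny_config, seed=0)


def build_rrxs_detector(L_std: int = 48) -> ReverseHomologyModel:
    """Single-channel model hard-wired to detect the pattern R-R-x-S.

    conv1 (kernel 5) scores +1 for R, R and S at window offsets 0, 1 and 3
    with bias -2.5, so after the rectifier the activation is 0.5 exactly at
    full matches; conv2/conv3 are 1x1 pass-throughs scaled so the final
    activation is 1.0 at a match and 0 elsewhere.  Receptive field = 5.
    """
    cfg = EncoderConfig(L_std=L_std, branch_kernels=(5,), branch_filters=1,
                        conv2_kernel=1, conv2_filters=1,
                        conv3_kernel=1, conv3_filters=1, fc_dims=(2, 2))
    model = ReverseHomologyModel(cfg, seed=0)
    for enc in (model.g1, model.g2):
        b = enc.branches[0]
        b.params["W"][...] = 0.0
        b.params["W"][0, AA_INDEX["R"], 0] = 1.0
        b.params["W"][1, AA_INDEX["R"], 0] = 1.0
        b.params["W"][3, AA_INDEX["S"], 0] = 1.0
        b.params["b"][...] = -2.5
        enc.conv2.params["W"][...] = 2.0
        enc.conv2.params["b"][...] = 0.0
        enc.conv3.params["W"][...] = 1.0
        enc.conv3.params["b"][...] = 0.0
    return model


@pytest.fixture
def rrxs_detector():
    return build_rrxs_detector()
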