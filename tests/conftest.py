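import numpy as np
import pytest

from sdasnet import DWTModuleConfig, ModelConfig, build_model


def zero_shift_params(module):
    """Zero every additive parameter (conv biases, normalisation betas)."""
    for name, p in module.named_parameters():
        if name.rsplit(".", 1)[-1] in ("bias", "beta"):
            p.data[...] = 0.0
    return module


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def tiny_config():
    """64x64 input, base width 8, unstried wavelet front end, 4x4 token grid."""
    return ModelConfig(
        base_width=8, input_size=(64, 64),
        dwt=DWTModuleConfig(out_channels=8, mid_channels=4, final_stride=1))


@pytest.fixture
def tiny_model(tiny_config):
    return build_model(tiny_config, seed=7)
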