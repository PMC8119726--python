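import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_net_config():
    """A very small but structurally complete network configuration."""
    from cmmnet.architecture import NetworkConfig
    return NetworkConfig(input_height=32, input_width=32,
                         encoder_channels=[4, 8, 12, 16],
                         ppm_bottleneck_channels=4, ppm_max_scale=16)
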