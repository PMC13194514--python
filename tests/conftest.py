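import numpy as np
import pytest

from mceegnet.model import BranchConfig, MCEEGNetConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_branch():
    """A branch small enough for finite-difference and shape tests."""
    return BranchConfig(n_channels=3, n_samples=40, f1=2, temporal_kernel=7,
                        depth_multiplier=2, sep_kernel=5, pool1=2, pool2=2,
                        dropout_p=0.0)


@pytest.fixture
def tiny_cfg(tiny_branch):
    return MCEEGNetConfig(branch=tiny_branch, mode="classify")
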