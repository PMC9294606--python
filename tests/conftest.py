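import numpy as np
import pytest

from stpkit.signal_core import StimulusProtocol
from stpkit.synth import KernelParams


@pytest.fixture
def train_protocol() -> StimulusProtocol:
    """40 stimuli at 100 Hz, the standard depleting train."""
    return StimulusProtocol.train(40, 100.0)


@pytest.fixture
def wt_kernel() -> KernelParams:
    """Wild-type-like mIPSC kinetics (biexponential decay)."""
    return KernelParams(tau_rise=1.3, tau_fast=6.25, tau_slow=13.4, fast_fraction=0.6)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
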