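import dataclasses

import numpy as np
import pytest

from startlekit.paradigm import build_startle_protocol
from startlekit.synth import SimConfig


@pytest.fixture
def startle_protocol():
    return build_startle_protocol(0)


@pytest.fixture
def quiet_sim():
    """Noiseless, jitter-free simulator config: everything is exact."""
    return SimConfig(seed=0, baseline_noise_sd=0.0, peak_jitter_cv=0.0,
                     motion_noise_sd=0.0, response_prob=1.0)


def replace(cfg: SimConfig, **kw) -> SimConfig:
    return dataclasses.replace(cfg, **kw)
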