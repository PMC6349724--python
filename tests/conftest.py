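import numpy as np
import pytest

import ripplemap as rm
from ripplemap.synth import SynthConfig, UnitSpec, lesion_config


@pytest.fixture(scope="session")
def lesion_recording():
    """One 15 s lesion-like recording with an SWD and burst HFO packets."""
    cfg = lesion_config(seed=11, duration=15.0)
    rec, gt = rm.make_recording(cfg)
    return cfg, rec, gt


@pytest.fixture(scope="session")
def single_channel_lesion():
    """Single-channel lesion recording for detector tests (full gain)."""
    cfg = lesion_config(
        seed=21, duration=30.0, n_channels=1, ripple_amp_profile=[1.0],
        n_swd=0, hfo_rate=0.8, hfo_amp_sd=6.0,
    )
    rec, gt = rm.make_recording(cfg)
    return cfg, rec, gt


@pytest.fixture(scope="session")
def units_recording():
    """Recording carrying one EXC and one INH unit on channel 0."""
    cfg = SynthConfig(
        n_channels=1, duration=20.0, ripple_amp_profile=[1.0], n_swd=0,
        burst_rate=0.3, hfo_rate=0.0, seed=5,
        unit_specs=[
            UnitSpec(channel=0, cell_class="EXC", rate_burst=15, amplitude=120),
            UnitSpec(channel=0, cell_class="INH", rate_burst=15, amplitude=120),
        ],
    )
    rec, gt = rm.make_recording(cfg)
    return cfg, rec, gt


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
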