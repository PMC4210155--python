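import numpy as np
import pytest

from reflexgait import preprocessing as pp
from reflexgait import synthetic as syn


@pytest.fixture(scope="session")
def small_setup():
    """A modest synthetic recording shared by read-only tests."""
    cfg = syn.SynthConfig(seed=5, envelope_snr=50.0)
    profile = syn.generate_speed_sequence(
        6, (0.9, 1.4), repeats=1, seed=5, strides_per_setting=8, config=cfg
    )
    rec, events, kernels = syn.generate_recording(profile, cfg)
    return {"config": cfg, "profile": profile, "rec": rec, "events": events, "kernels": kernels}


@pytest.fixture(scope="session")
def small_segmentation(small_setup):
    events = small_setup["events"]
    return pp.segment_strides(events, "left")
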