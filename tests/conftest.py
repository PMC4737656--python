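import numpy as np
import pytest
from hypothesis import settings

import whiskcode as wc

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_session():
    """120 s simulated recording under the default study conditions."""
    return wc.simulate_session(wc.SimConfig(duration=120.0, seed=1))


@pytest.fixture(scope="session")
def default_epochs(default_session):
    return wc.segment_epochs(default_session.kin)


@pytest.fixture(scope="session")
def rhythmic_session():
    """Near-continuous rhythmic whisking (for phase-tuning analyses)."""
    cfg = wc.SimConfig(
        duration=40.0, seed=2, gain=0.0, bout_dur_mean=60.0, quiet_dur_mean=0.5,
        twitch_rate=0.0, phase_mod_depth=0.0, locomotion_fraction=0.0,
    )
    s = wc.simulate_session(cfg)
    ep = wc.segment_epochs(s.kin)
    rhy, elig = wc.rhythmic_epochs(s.kin, ep)
    return s, ep, rhy, elig


def make_rhythmic(seed, depth, duration=35.0, **kw):
    """Helper used by phase/Kuiper tests: mostly-whisking session."""
    cfg = wc.SimConfig(
        duration=duration, seed=seed, gain=0.0, bout_dur_mean=60.0,
        quiet_dur_mean=0.5, twitch_rate=0.0, phase_mod_depth=depth,
        locomotion_fraction=0.0, **kw,
    )
    s = wc.simulate_session(cfg)
    ep = wc.segment_epochs(s.kin)
    rhy, elig = wc.rhythmic_epochs(s.kin, ep)
    return s, rhy, elig
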