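import numpy as np
import pytest

from ppgfatigue.synth import SubjectProfile, SynthConfig, simulate_record


@pytest.fixture
def quiet_config():
    """Noise-free 60 s recording config at the default 100 Hz rate."""
    return SynthConfig(
        duration_s=60.0, baseline_amp=0.0, powerline_amp=0.0, white_sd=0.0, seed=0
    )


@pytest.fixture
def steady_profile():
    """Constant 0.8 s inter-beat interval, prominent dicrotic wave."""
    return SubjectProfile(
        subject_id="S01",
        condition="non_fatigue",
        kss=3,
        pvt_ms=356.0,
        mean_ibi_s=0.8,
        ibi_sd_s=0.0,
        dicrotic_amp_rel=0.35,
    )


@pytest.fixture
def steady_record(steady_profile, quiet_config):
    return simulate_record(steady_profile, quiet_config)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
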