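import numpy as np
import pytest

from cica_rppg.ingest import TraceMatrix
from cica_rppg.synthdata import mix_to_rgb, scenario_preset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_traces(rng):
    """Small random 3x60 trace matrix at 30 Hz."""
    return TraceMatrix(values=rng.standard_normal((3, 60)), fs=30.0)


@pytest.fixture(scope="session")
def clean_scene():
    """60 s clean synthetic scene at 72 bpm, 10 dB pulse SNR."""
    scen = scenario_preset("clean", duration_s=60.0, hr_bpm=72.0, seed=3,
                           pulse_snr_db=10.0)
    traces, truth = mix_to_rgb(scen)
    return scen, traces, truth


@pytest.fixture(scope="session")
def medium_scene():
    """60 s scene with a 3x-amplitude periodic motion distractor at 1.6 Hz."""
    scen = scenario_preset("medium", duration_s=60.0, hr_bpm=72.0, seed=7,
                           pulse_snr_db=10.0)
    traces, truth = mix_to_rgb(scen)
    return scen, traces, truth
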