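import numpy as np
import pytest

from ecgmff import NoiseConfig, SynthConfig, generate_record


@pytest.fixture(scope="session")
def clean_record():
    """Noise-free 10 s, 60 bpm, exactly periodic record."""
    cfg = SynthConfig(
        duration=10.0, heart_rate=60.0, rr_jitter=0.0,
        noise=NoiseConfig(baseline_amp=0, powerline_amp=0, broadband_sd=0),
        seed=7,
    )
    return generate_record(cfg)


@pytest.fixture(scope="session")
def noisy_record():
    """10 s, 70 bpm record with default wander/mains/broadband noise."""
    cfg = SynthConfig(duration=10.0, heart_rate=70.0, rr_jitter=0.05, seed=3)
    return generate_record(cfg)


@pytest.fixture(scope="session")
def clean_beats(clean_record):
    from ecgmff.preprocess import preprocess_record

    _, _, beats = preprocess_record(clean_record)
    return beats


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
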