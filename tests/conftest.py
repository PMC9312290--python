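import numpy as np
import pytest

from ecgfusion.fiducial import delineate_waves, detect_r_peaks
from ecgfusion.synthetic import RhythmSpec, default_spec, generate_record


@pytest.fixture(scope="session")
def normal_record():
    """Noise-free Normal rhythm, 60 bpm, zero RR jitter: RR is exactly 1 s."""
    spec = RhythmSpec("Normal", heart_rate_bpm=60.0, rr_jitter=0.0)
    return generate_record(spec, duration_s=10.0, fs=500.0, noise_sd=0.0, seed=1)


@pytest.fixture(scope="session")
def normal_jittered_record():
    """Noise-free Normal rhythm with the default physiologic RR jitter."""
    return generate_record(default_spec("Normal", 60.0), 10.0, 500.0, 0.0, seed=1)


@pytest.fixture(scope="session")
def af_record():
    return generate_record(default_spec("AF", 60.0), 30.0, 500.0, 0.02, seed=7)


@pytest.fixture(scope="session")
def normal_fiducials(normal_record):
    sig = normal_record.lead("II")
    r = detect_r_peaks(sig, normal_record.fs)
    return delineate_waves(sig, normal_record.fs, r)
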