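import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from laborhrv.synthetic import TachogramSpec, generate_rri_ipfm, synthesize_ecg


@pytest.fixture(scope="session")
def modulated_rri():
    """A 5-min RR series with LF and HF tones, plus its ground truth."""
    spec = TachogramSpec(
        mean_rr=800.0, modulations=[(0.1, 0.03), (0.25, 0.04)],
        duration=310.0, seed=7,
    )
    beat_times, rri, truth = generate_rri_ipfm(spec)
    return beat_times, rri, truth


@pytest.fixture(scope="session")
def clean_ecg(modulated_rri):
    """Noise-free synthetic ECG for the modulated RR series."""
    beat_times, _, _ = modulated_rri
    rec, wtruth = synthesize_ecg(beat_times, fs=1000.0, noise_sd=0.0)
    return rec, wtruth


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
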