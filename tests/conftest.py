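import pytest
from hypothesis import settings

from vitalband import train_intensity_classifier
from vitalband.synthetic import AccelSpec, PPGSpec, generate_accel, generate_ppg

settings.register_profile("deterministic", derandomize=True, max_examples=50)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def ppg_8052():
    """Noiseless 40-s dual-wavelength PPG at 80.52 bpm (1.342 Hz pulse)."""
    return generate_ppg(
        PPGSpec(heart_rate_bpm=80.52, duration_s=40.0, noise_sd=0.0, seed=0)
    )


@pytest.fixture(scope="session")
def accel_corpus():
    """50 labeled accelerometry windows: 10 per intensity level, 2% jitter."""
    return [
        generate_accel(AccelSpec(level=level, jitter_frac=0.02, seed=level * 100 + i))
        for level in range(1, 6)
        for i in range(10)
    ]


@pytest.fixture(scope="session")
def trained_classifier(accel_corpus):
    """Intensity SVM trained on the 50-window corpus, with its report."""
    return train_intensity_classifier(accel_corpus, seed=0)
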