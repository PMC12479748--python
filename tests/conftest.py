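import numpy as np
import pytest

from ecgfusion.synthetic import (SyntheticECGSpec, generate_waveform,
                                 make_dataset, render_image)


@pytest.fixture(scope="session")
def clean_record():
    """Noise-free 5-beat record at 60 bpm / 250 Hz with its annotations."""
    spec = SyntheticECGSpec(heart_rate=60, sampling_rate=250, duration=5,
                            noise_sd=0.0, seed=3)
    return generate_waveform(spec)


@pytest.fixture(scope="session")
def clean_image(clean_record):
    trace, _ = clean_record
    return render_image(trace)


@pytest.fixture(scope="session")
def small_dataset():
    """10 records per class at the default noisy study conditions."""
    return make_dataset(10, seed=7)


@pytest.fixture
def rng():
    return np.random.default_rng(11)
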