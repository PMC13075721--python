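import numpy as np
import pytest

from hagwo import Signal, SignalSpec, TableSpec, make_feature_table, make_signal


@pytest.fixture
def sine_signal():
    """Pure 5 Hz sine, 4 s at 128 Hz."""
    clean, _ = make_signal(SignalSpec(duration=4, sampling_rate=128,
                                      tones=((5.0, 1.0),), noise_sd=0.0))
    return clean


@pytest.fixture
def duo_tone_signal():
    """2 Hz + 20 Hz mixture, 4 s at 128 Hz."""
    clean, _ = make_signal(SignalSpec(duration=4, sampling_rate=128,
                                      tones=((2.0, 1.0), (20.0, 1.0)), noise_sd=0.0))
    return clean


@pytest.fixture
def small_table():
    """n=200, N=12, 3 informative at d=1.5, seed 0."""
    return make_feature_table(TableSpec(n_samples=200, n_features=12,
                                        n_informative=3, effect_size=1.5, seed=0))


def snr_db(x: np.ndarray, reference: np.ndarray) -> float:
    noise = x - reference
    return 10 * np.log10(np.sum(reference ** 2) / np.sum(noise ** 2))
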