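import numpy as np
import pytest

from decompcast.series import SlidingWindowDataset


@pytest.fixture
def two_tone():
    """1000-sample signal with tones at 0.002 and 0.024 cycles/sample."""
    n = np.arange(1000)
    return np.cos(2 * np.pi * 0.002 * n) + np.cos(2 * np.pi * 0.024 * n)


@pytest.fixture
def linear_dataset():
    """100 scaled samples whose target is an exact linear map of the inputs."""
    rng = np.random.default_rng(0)
    X = rng.uniform(0.0, 1.0, size=(100, 4))
    y = 0.5 * X.mean(axis=1) + 0.2
    return SlidingWindowDataset(inputs=X, targets=y, lag=4)


def spectral_peak(mode: np.ndarray) -> float:
    """Frequency (cycles/sample) of the largest non-DC spectral line."""
    amp = np.abs(np.fft.rfft(mode))
    freqs = np.fft.rfftfreq(len(mode))
    return float(freqs[1:][np.argmax(amp[1:])])


def spectral_bandwidth(mode: np.ndarray) -> float:
    """Power-weighted spectral standard deviation around the mean frequency."""
    power = np.abs(np.fft.rfft(mode)) ** 2
    freqs = np.fft.rfftfreq(len(mode))
    total = power.sum()
    mean = (freqs * power).sum() / total
    return float(np.sqrt(((freqs - mean) ** 2 * power).sum() / total))
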