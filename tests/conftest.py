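import numpy as np
import pytest

from ducksex import AudioSignal, FrameMatrix


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def tone_signal():
    """0.5 s of a 2500 Hz tone at 44100 Hz."""
    fs = 44100
    t = np.arange(int(0.5 * fs)) / fs
    return AudioSignal(samples=0.5 * np.sin(2 * np.pi * 2500.0 * t), sample_rate=fs)


@pytest.fixture()
def toy_separable(rng):
    """200 linearly separable 36-dim frames, 100 per class."""
    x = np.vstack([rng.normal(-2.0, 1.0, (100, 36)),
                   rng.normal(2.0, 1.0, (100, 36))]).astype(np.float32)
    y = np.repeat([0, 1], 100)
    return x, y


def make_frames(array_2d, hop=441, fs=44100, windowed=False):
    return FrameMatrix(frames=np.asarray(array_2d, dtype=float), hop_length=hop,
                       sample_rate=fs, windowed=windowed)
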