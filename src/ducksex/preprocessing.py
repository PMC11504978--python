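"""Pre-emphasis, framing and Hamming windowing of duckling vocalizations.

A duck call is quasi-stationary over 10-30 ms, so the signal is cut into
25 ms frames with a 10 ms hop.  Before framing, a first-order pre-emphasis
filter y(n) = x(n) - alpha*x(n-1) compensates the high-frequency roll-off of
the propagation path; each frame is then tapered with a Hamming window to
limit spectral leakage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np

from .audio_io import AudioSignal
from .errors import ParameterError, StateError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FrameParams:
    """Framing configuration.

    frame_length_ms : analysis window length (default 25 ms).
    hop_length_ms : stride between consecutive frames (default 10 ms).
    pre_emphasis_alpha : coefficient of the pre-emphasis filter (default 0.95).
    window_kind : taper applied before spectral analysis ("hamming" only).
    """

    frame_length_ms: float = 25.0
    hop_length_ms: float = 10.0
    pre_emphasis_alpha: float = 0.95
    window_kind: str = "hamming"

    def __post_init__(self) -> None:
        if not (0 < self.hop_length_ms <= self.frame_length_ms):
            raise ParameterError(
                f"need 0 < hop ({self.hop_length_ms} ms) <= frame length "
                f"({self.frame_length_ms} ms)"
            )
        if not (0 <= self.pre_emphasis_alpha < 1):
            raise ParameterError(
                f"pre-emphasis alpha must lie in [0, 1), got {self.pre_emphasis_alpha}"
            )
        if self.window_kind != "hamming":
            raise ParameterError(f"unsupported window kind {self.window_kind!r}")

    def frame_length_samples(self, sample_rate: int) -> int:
        # 25 ms at 44100 Hz is 1102.5 samples; floor keeps it deterministic.
        return int(self.frame_length_ms * sample_rate / 1000.0)

    def hop_length_samples(self, sample_rate: int) -> int:
        return int(self.hop_length_ms * sample_rate / 1000.0)


@dataclass
class FrameMatrix:
    """Short-time frames of one signal: shape (num_frames, frame_length)."""

    frames: np.ndarray
    hop_length: int
    sample_rate: int
    windowed: bool = False

    def __post_init__(self) -> None:
        self.frames = np.atleast_2d(np.asarray(self.frames, dtype=np.float64))

    @property
    def num_frames(self) -> int:
        return 0 if self.frames.size == 0 else self.frames.shape[0]

    @property
    def frame_length(self) -> int:
        return self.frames.shape[1]

    def frame_to_sample(self, frame_index: int) -> int:
        """Sample index where ``frame_index`` starts."""
        return frame_index * self.hop_length


def pre_emphasize(signal: AudioSignal, alpha: float = 0.95) -> AudioSignal:
    """Apply the first-order high-pass filter y(n) = x(n) - alpha*x(n-1).

    The first output sample is passed through unchanged (no history before
    the recording exists).  Length is preserved and the operation is linear.
    """
    if not (0 <= alpha < 1):
        raise ParameterError(f"pre-emphasis alpha must lie in [0, 1), got {alpha}")
    x = signal.samples
    y = np.empty_like(x)
    y[0] = x[0]
    y[1:] = x[1:] - alpha * x[:-1]
    return AudioSignal(samples=y, sample_rate=signal.sample_rate,
                       source_id=signal.source_id)


def hamming_window(n: int) -> np.ndarray:
    """Hamming taper w(k) = 0.54 - 0.46*cos(2*pi*k/(n-1)) for k = 0..n-1."""
    if n < 2:
        raise ParameterError(f"window length must be >= 2, got {n}")
    k = np.arange(n)
    return 0.54 - 0.46 * np.cos(2.0 * np.pi * k / (n - 1))


def frame_signal(signal: AudioSignal, params: FrameParams | None = None) -> FrameMatrix:
    """Slice a signal into overlapping frames (no window applied yet).

    Trailing samples that do not fill a complete frame are dropped, giving
    num_frames = 1 + floor((len(signal) - L) / hop).  A signal shorter than
    one frame yields an empty FrameMatrix with a logged warning.
    """
    params = params or FrameParams()
    fs = signal.sample_rate
    length = params.frame_length_samples(fs)
    hop = params.hop_length_samples(fs)
    x = signal.samples
    if x.size < length:
        logger.warning("signal %s shorter than one frame (%d < %d samples)",
                       signal.source_id, x.size, length)
        return FrameMatrix(frames=np.empty((0, length)), hop_length=hop,
                           sample_rate=fs, windowed=False)
    num = 1 + (x.size - length) // hop
    view = np.lib.stride_tricks.sliding_window_view(x, length)[::hop][:num]
    return FrameMatrix(frames=view.copy(), hop_length=hop, sample_rate=fs,
                       windowed=False)


def apply_window(frames: FrameMatrix) -> FrameMatrix:
    """Multiply each frame elementwise by the Hamming window."""
    if frames.windowed:
        raise StateError("frames are already windowed")
    w = hamming_window(frames.frame_length)
    return replace(frames, frames=frames.frames * w[None, :], windowed=True)
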