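"""Mel-frequency cepstral features: 12 MFCC + 12 delta + 12 delta-delta.

The frame-wise pipeline is: zero-pad to n_fft and FFT; spectral line
energies E(i,k) = |X(i,k)|^2; triangular Mel filterbank energies
S(i,m) = sum_k E(i,k) H_m(k); log and discrete cosine transform

    mfcc(i,n) = sqrt(2/M) * sum_{m=0}^{M-1} log S(i,m) * cos(pi*n*(2m+c)/(2M))

keeping n = 1..12 (the 0th coefficient, overall log-energy, is dropped by
default).  The cosine phase offset c is +1 in the standard DCT-II
convention and -1 in an alternate printed convention; both are supported
and pinned by brute-force oracle tests.  Temporal dynamics are appended as
first- and second-order regression deltas of the 12 static coefficients,
giving a 36-dimensional vector per frame.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .audio_io import AudioSignal
from .errors import ParameterError, ShapeError, StateError
from .preprocessing import FrameMatrix, FrameParams, apply_window, frame_signal, hamming_window

logger = logging.getLogger(__name__)

#: Feature layout: 12 static cepstra, then their first and second deltas.
FEATURE_DIM = 36


@dataclass(frozen=True)
class MfccParams:
    """MFCC extraction configuration.

    n_fft : FFT size (zero-padded; default 2048, next power of two above the
        1102-sample frame at 44100 Hz).
    n_filters : number M of triangular Mel filters (default 26).
    n_coeffs : cepstral coefficients kept (default 12, excluding c0).
    fmin, fmax : filterbank frequency range in Hz (fmax None = Nyquist).
    delta_width : half-width of the delta regression window (frames).
    energy_floor : floor applied to filterbank energies before the log.
    include_c0 : keep the 0th (log-energy) coefficient as well.
    dct_convention : "standard" for the (2m+1) DCT-II phase, "printed" for
        the alternate (2m-1) phase.
    """

    n_fft: int = 2048
    n_filters: int = 26
    n_coeffs: int = 12
    fmin: float = 0.0
    fmax: float | None = None
    delta_width: int = 2
    energy_floor: float = 1e-10
    include_c0: bool = False
    dct_convention: str = "standard"

    def __post_init__(self) -> None:
        if self.n_fft < 2 or (self.n_fft & (self.n_fft - 1)) != 0:
            raise ParameterError(f"n_fft must be a power of two >= 2, got {self.n_fft}")
        if self.n_filters < 2:
            raise ParameterError(f"need at least 2 Mel filters, got {self.n_filters}")
        if not (1 <= self.n_coeffs <= self.n_filters):
            raise ParameterError(
                f"n_coeffs ({self.n_coeffs}) must lie in [1, n_filters={self.n_filters}]"
            )
        if self.delta_width < 1:
            raise ParameterError(f"delta_width must be >= 1, got {self.delta_width}")
        if self.dct_convention not in ("standard", "printed"):
            raise ParameterError(f"unknown dct_convention {self.dct_convention!r}")


@dataclass
class MelFilterBank:
    """Triangular filters on the Mel scale, as a weight matrix over FFT bins."""

    weights: np.ndarray          # (M, n_fft // 2 + 1)
    boundary_bins: np.ndarray    # (M + 2,) FFT bin index of each filter edge/peak
    n_fft: int
    sample_rate: int
    fmin: float
    fmax: float

    @property
    def n_filters(self) -> int:
        return self.weights.shape[0]


@dataclass
class FeatureMatrix:
    """Per-frame feature vectors, shape (num_frames, 36).

    Column layout is [c1..c12, d1..d12, dd1..dd12].  ``normalization`` is
    "raw" until :func:`normalize_features` converts it to "zscored", at
    which point the training-set ``mean``/``std`` used are stored.
    """

    values: np.ndarray
    normalization: str = "raw"
    mean: np.ndarray | None = None
    std: np.ndarray | None = None
    duck_id: str | None = None

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=np.float64))
        if not np.all(np.isfinite(self.values)):
            raise ShapeError("feature matrix contains non-finite values")

    @property
    def num_frames(self) -> int:
        return self.values.shape[0]

    @property
    def dim(self) -> int:
        return self.values.shape[1]


def hz_to_mel(f):
    """Perceptual Mel warping mel(f) = 2595 log10(1 + f/700)."""
    return 2595.0 * np.log10(1.0 + np.asarray(f, dtype=np.float64) / 700.0)


def mel_to_hz(m):
    return 700.0 * (10.0 ** (np.asarray(m, dtype=np.float64) / 2595.0) - 1.0)


def power_spectrum(frames: FrameMatrix, n_fft: int = 2048) -> np.ndarray:
    """Spectral line energies E(i,k) = |FFT(x_i)|^2 for k = 0..n_fft/2."""
    if not frames.windowed:
        raise StateError("frames must be windowed before spectral analysis")
    if n_fft < frames.frame_length:
        raise ParameterError(
            f"n_fft ({n_fft}) must be >= frame length ({frames.frame_length})"
        )
    spectrum = np.fft.rfft(frames.frames, n=n_fft, axis=1)
    return np.abs(spectrum) ** 2


def build_mel_filterbank(sample_rate: int = 44100, n_fft: int = 2048,
                         n_filters: int = 26, fmin: float = 0.0,
                         fmax: float | None = None) -> MelFilterBank:
    """Place M triangular filters with edges equally spaced on the Mel scale.

    The M+2 boundary frequencies between fmin and fmax are an arithmetic
    progression in Mel, converted to FFT bin indices; filter m rises
    linearly from bin f(m-1) to a peak of 1 at bin f(m) and falls to zero at
    bin f(m+1).
    """
    nyquist = sample_rate / 2.0
    fmax = nyquist if fmax is None else float(fmax)
    if not (0 <= fmin < fmax):
        raise ParameterError(f"need 0 <= fmin ({fmin}) < fmax ({fmax})")
    if fmax > nyquist:
        raise ParameterError(f"fmax ({fmax}) exceeds Nyquist ({nyquist})")
    if n_filters < 2:
        raise ParameterError(f"need at least 2 filters, got {n_filters}")
    mel_pts = np.linspace(hz_to_mel(fmin), hz_to_mel(fmax), n_filters + 2)
    hz_pts = mel_to_hz(mel_pts)
    bins = np.floor((n_fft + 1) * hz_pts / sample_rate).astype(int)
    bins = np.minimum(bins, n_fft // 2)
    n_bins = n_fft // 2 + 1
    weights = np.zeros((n_filters, n_bins))
    for m in range(1, n_filters + 1):
        left, center, right = bins[m - 1], bins[m], bins[m + 1]
        for k in range(left, center + 1):
            if center > left:
                weights[m - 1, k] = (k - left) / (center - left)
        for k in range(center + 1, right + 1):
            if right > center:
                weights[m - 1, k] = (right - k) / (right - center)
        weights[m - 1, center] = 1.0  # peak exactly 1 even for degenerate edges
    return MelFilterBank(weights=weights, boundary_bins=bins, n_fft=n_fft,
                         sample_rate=sample_rate, fmin=fmin, fmax=fmax)


def filterbank_energies(spectral_energies: np.ndarray, bank: MelFilterBank,
                        floor: float = 1e-10) -> np.ndarray:
    """S(i,m) = sum_k E(i,k) H_m(k), floored at ``floor`` for the log step."""
    e = np.atleast_2d(np.asarray(spectral_energies, dtype=np.float64))
    if e.shape[1] != bank.weights.shape[1]:
        raise ShapeError(
            f"spectral grid has {e.shape[1]} bins, filterbank expects "
            f"{bank.weights.shape[1]}"
        )
    return np.maximum(e @ bank.weights.T, floor)


def mfcc(filter_energies: np.ndarray, n_coeffs: int = 12,
         convention: str = "standard", include_c0: bool = False) -> np.ndarray:
    """Log + DCT of Mel filterbank energies.

    mfcc(i,n) = sqrt(2/M) * sum_m log S(i,m) * cos(pi*n*(2m+c)/(2M)) with
    c = +1 ("standard" DCT-II phase) or c = -1 ("printed" alternate).
    Coefficients n = 1..n_coeffs are returned; n = 0 is prepended when
    ``include_c0`` is set.
    """
    s = np.atleast_2d(np.asarray(filter_energies, dtype=np.float64))
    if np.any(s <= 0):
        raise ParameterError("filterbank energies must be positive (apply the floor)")
    m_filters = s.shape[1]
    if not (1 <= n_coeffs <= m_filters):
        raise ParameterError(f"n_coeffs ({n_coeffs}) must lie in [1, {m_filters}]")
    offset = {"standard": 1.0, "printed": -1.0}[convention]
    n = np.arange(0 if include_c0 else 1, n_coeffs + 1)
    m = np.arange(m_filters)
    basis = np.cos(np.pi * np.outer(n, 2.0 * m + offset) / (2.0 * m_filters))
    return np.sqrt(2.0 / m_filters) * (np.log(s) @ basis.T)


def delta(features: np.ndarray, width: int = 2) -> np.ndarray:
    """First-order regression delta over a +-width frame window.

    d_t = sum_{tau=1..width} tau * (c_{t+tau} - c_{t-tau}) / (2 * sum tau^2),
    with edge frames replicated.  Apply twice for the second-order delta.
    """
    if width < 1:
        raise ParameterError(f"delta width must be >= 1, got {width}")
    c = np.atleast_2d(np.asarray(features, dtype=np.float64))
    if c.shape[0] < 2 * width + 1:
        logger.warning("delta window (2*%d+1) exceeds %d frames; edges replicated",
                       width, c.shape[0])
    padded = np.pad(c, ((width, width), (0, 0)), mode="edge")
    denom = 2.0 * sum(tau * tau for tau in range(1, width + 1))
    out = np.zeros_like(c)
    for tau in range(1, width + 1):
        out += tau * (padded[width + tau: padded.shape[0] - width + tau or None]
                      - padded[width - tau: -width - tau])
    return out / denom


def assemble_features(frames: FrameMatrix, params: MfccParams | None = None,
                      bank: MelFilterBank | None = None,
                      duck_id: str | None = None) -> FeatureMatrix:
    """Windowed frames -> [12 MFCC | 12 delta | 12 delta-delta] per frame."""
    params = params or MfccParams()
    if bank is None:
        bank = build_mel_filterbank(frames.sample_rate, params.n_fft,
                                    params.n_filters, params.fmin, params.fmax)
    spec = power_spectrum(frames, params.n_fft)
    s = filterbank_energies(spec, bank, params.energy_floor)
    c = mfcc(s, params.n_coeffs, params.dct_convention, params.include_c0)
    d1 = delta(c, params.delta_width)
    d2 = delta(d1, params.delta_width)
    return FeatureMatrix(values=np.hstack([c, d1, d2]), duck_id=duck_id)


def normalize_features(train: FeatureMatrix, *others: FeatureMatrix,
                       std_floor: float = 1e-8):
    """Z-score all matrices per column using *training-set* statistics.

    The mean and standard deviation are computed on ``train`` only and
    applied unchanged to every other matrix, so no statistic leaks from
    validation or test data.  Columns with (near-)zero variance map to zero.
    Returns the transformed matrices in input order, followed by the
    (mean, std) pair.
    """
    if train.num_frames == 0:
        raise ParameterError("training feature matrix is empty")
    mean = train.values.mean(axis=0)
    std = np.maximum(train.values.std(axis=0), std_floor)

    def transform(fm: FeatureMatrix) -> FeatureMatrix:
        return FeatureMatrix(values=(fm.values - mean) / std, normalization="zscored",
                             mean=mean, std=std, duck_id=fm.duck_id)

    out = [transform(train)] + [transform(fm) for fm in others]
    return (*out, (mean, std))


def spectrogram(signal: AudioSignal, frame_params: FrameParams | None = None,
                n_fft: int = 2048, log_floor: float = 1e-10):
    """Log-magnitude STFT for diagnostics.

    Returns (frequencies_hz, frame_times_s, logmag) where logmag has shape
    (n_fft//2 + 1, num_frames).
    """
    frame_params = frame_params or FrameParams()
    frames = apply_window(frame_signal(signal, frame_params))
    if frames.num_frames == 0:
        return (np.fft.rfftfreq(n_fft, 1.0 / signal.sample_rate), np.empty(0),
                np.empty((n_fft // 2 + 1, 0)))
    mag = np.abs(np.fft.rfft(frames.frames, n=n_fft, axis=1)).T
    freqs = np.fft.rfftfreq(n_fft, 1.0 / signal.sample_rate)
    times = (np.arange(frames.num_frames) * frames.hop_length
             + frames.frame_length / 2.0) / signal.sample_rate
    return freqs, times, np.log10(np.maximum(mag, log_floor))
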