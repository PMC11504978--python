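"""Zero-product dual-threshold endpoint detection.

Call boundaries are found from two cheap per-frame statistics: the
short-term energy E(i) = sum_n x_i(n)^2 and the short-term zero-crossing
rate Z(i) = 1/2 * sum_n |sgn x_i(n) - sgn x_i(n-1)| (sgn x = 1 for x >= 0,
-1 otherwise).  Their product K(i) = Z(i) * E(i) is large only where a frame
is both loud and rich in high-frequency content -- i.e. inside a call -- and
a hysteresis (dual-threshold) pass over K marks segment start and end
points.  Detection runs on unwindowed pre-emphasized frames: the window
taper would suppress exactly the frame-edge crossings Z counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .audio_io import AudioSignal
from .errors import ParameterError, ShapeError
from .preprocessing import FrameMatrix, FrameParams, frame_signal, pre_emphasize

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class EndpointParams:
    """Detection knobs, all relative to the per-recording maximum of K.

    high_frac : seed threshold T_high = high_frac * max(K).
    low_frac : extension threshold T_low = low_frac * max(K).
    min_frames : segments shorter than this are discarded (clicks, steps).
    merge_gap : segments separated by <= this many frames are merged.
    subtract_median : subtract the per-recording median of K (the noise
        plateau) before thresholding; used by the recording-level pipeline.
    hangover_frames : frames appended to each segment end to keep the
        decaying release tail that falls below the extension threshold.
    """

    high_frac: float = 0.10
    low_frac: float = 0.02
    min_frames: int = 10
    merge_gap: int = 5
    subtract_median: bool = True
    hangover_frames: int = 1


@dataclass
class ActivitySeries:
    """Per-frame energy E, zero-crossing rate Z and their product K."""

    energy: np.ndarray
    zcr: np.ndarray
    zero_product: np.ndarray

    def __post_init__(self) -> None:
        if not (len(self.energy) == len(self.zcr) == len(self.zero_product)):
            raise ShapeError("E, Z and K must have equal lengths")


@dataclass(frozen=True)
class Segment:
    """Half-open, 0-based frame span of one detected call."""

    start_frame: int
    end_frame: int
    start_sample: int
    end_sample: int

    @property
    def num_frames(self) -> int:
        return self.end_frame - self.start_frame


def short_term_energy(frames: FrameMatrix) -> np.ndarray:
    """E(i) = sum of squared samples of frame i."""
    return np.sum(frames.frames ** 2, axis=1)


def zero_crossing_rate(frames: FrameMatrix) -> np.ndarray:
    """Z(i) = half the total sign-change magnitude within frame i.

    The sign convention maps 0 to +1 and the n = 0 boundary term compares a
    frame's first sample with itself (contributing zero); frames are treated
    as independent units.
    """
    s = np.where(frames.frames >= 0, 1.0, -1.0)
    return 0.5 * np.sum(np.abs(np.diff(s, axis=1)), axis=1)


def zero_product(energy: np.ndarray, zcr: np.ndarray) -> np.ndarray:
    """K(i) = Z(i) * E(i), the single detection statistic."""
    energy = np.asarray(energy, dtype=np.float64)
    zcr = np.asarray(zcr, dtype=np.float64)
    if energy.shape != zcr.shape:
        raise ShapeError(f"energy shape {energy.shape} != zcr shape {zcr.shape}")
    return energy * zcr


def activity_series(frames: FrameMatrix) -> ActivitySeries:
    e = short_term_energy(frames)
    z = zero_crossing_rate(frames)
    return ActivitySeries(energy=e, zcr=z, zero_product=zero_product(e, z))


def detect_endpoints(k: np.ndarray, high_frac: float = 0.10, low_frac: float = 0.02,
                     min_frames: int = 10, merge_gap: int = 5,
                     hop_length: int = 441, frame_length: int = 1102) -> list[Segment]:
    """Dual-threshold hysteresis segmentation of the zero-product series K.

    A candidate segment is seeded wherever K >= T_high = high_frac*max(K) and
    extended in both directions while K >= T_low = low_frac*max(K).  Abutting
    or overlapping candidates, and candidates separated by at most
    ``merge_gap`` frames, are merged; merged segments shorter than
    ``min_frames`` are dropped.  An all-zero K means no activity and returns
    an empty list.
    """
    k = np.asarray(k, dtype=np.float64)
    if k.size == 0:
        raise ParameterError("K series is empty")
    if not (0 < low_frac < high_frac <= 1):
        raise ParameterError(
            f"need 0 < low_frac ({low_frac}) < high_frac ({high_frac}) <= 1"
        )
    kmax = float(np.max(k))
    if kmax <= 0:
        return []
    t_high = high_frac * kmax
    t_low = low_frac * kmax

    above_low = k >= t_low
    # Runs of frames above T_low; keep those containing a seed above T_high.
    edges = np.flatnonzero(np.diff(np.concatenate(([0], above_low.view(np.int8), [0]))))
    runs = [(int(edges[i]), int(edges[i + 1])) for i in range(0, len(edges), 2)]
    runs = [r for r in runs if np.any(k[r[0]:r[1]] >= t_high)]

    merged: list[list[int]] = []
    for start, end in runs:
        if merged and start - merged[-1][1] <= merge_gap:
            merged[-1][1] = end
        else:
            merged.append([start, end])

    segments = []
    for start, end in merged:
        if end - start < min_frames:
            continue
        segments.append(Segment(
            start_frame=start, end_frame=end,
            start_sample=start * hop_length,
            end_sample=(end - 1) * hop_length + frame_length,
        ))
    return segments


def apply_hangover(segments: list[Segment], hangover: int, num_frames: int,
                   hop_length: int, frame_length: int) -> list[Segment]:
    """Extend each segment end by ``hangover`` frames, re-merging overlaps.

    Release-smoothing: a call's decay tail drops below the extension
    threshold about one frame before the call truly ends, so the hysteresis
    pass systematically clips segment ends short.
    """
    if hangover <= 0 or not segments:
        return segments
    merged: list[list[int]] = []
    for seg in segments:
        end = min(seg.end_frame + hangover, num_frames)
        if merged and seg.start_frame <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], end)
        else:
            merged.append([seg.start_frame, end])
    return [Segment(start_frame=s, end_frame=e, start_sample=s * hop_length,
                    end_sample=(e - 1) * hop_length + frame_length)
            for s, e in merged]


def find_call_segments(signal: AudioSignal, frame_params: FrameParams | None = None,
                       params: EndpointParams | None = None) -> list[Segment]:
    """Recording-level detection: pre-emphasis, framing, K statistic, hysteresis.

    When ``params.subtract_median`` is set (the default), the per-recording
    median of K -- the background-noise plateau whenever silence dominates
    the recording -- is subtracted before thresholding, so that the relative
    thresholds are measured against the call peaks rather than the noise
    floor.  ``params.hangover_frames`` frames are appended to each segment
    end to keep the decaying call tail.
    """
    frame_params = frame_params or FrameParams()
    params = params or EndpointParams()
    emphasized = pre_emphasize(signal, frame_params.pre_emphasis_alpha)
    frames = frame_signal(emphasized, frame_params)
    if frames.num_frames == 0:
        return []
    k = activity_series(frames).zero_product
    if params.subtract_median:
        k = np.maximum(k - np.median(k), 0.0)
    segments = detect_endpoints(
        k, high_frac=params.high_frac, low_frac=params.low_frac,
        min_frames=params.min_frames, merge_gap=params.merge_gap,
        hop_length=frames.hop_length, frame_length=frames.frame_length,
    )
    return apply_hangover(segments, params.hangover_frames, frames.num_frames,
                          frames.hop_length, frames.frame_length)


def extract_voiced(signal: AudioSignal, segments: list[Segment]) -> list[AudioSignal]:
    """Cut the samples covered by each segment out of the recording."""
    out = []
    n = len(signal)
    for i, seg in enumerate(segments):
        if not (0 <= seg.start_sample < seg.end_sample <= n):
            raise ParameterError(
                f"segment {i} [{seg.start_sample}, {seg.end_sample}) outside signal of "
                f"length {n}"
            )
        out.append(AudioSignal(
            samples=signal.samples[seg.start_sample:seg.end_sample].copy(),
            sample_rate=signal.sample_rate,
            source_id=f"{signal.source_id or 'signal'}#seg{i}",
        ))
    return out
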