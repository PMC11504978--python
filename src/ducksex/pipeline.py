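"""End-to-end feature extraction: recording in, 36-dim frame features out.

Stage order: pre-emphasis -> framing -> endpoint detection on the
unwindowed frames -> Hamming windowing of the voiced frames -> MFCC with
first- and second-order deltas.  Deltas are computed within each detected
call segment, so call boundaries never bleed into the dynamics columns.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .audio_io import AudioSignal, DatasetManifest, read_wav
from .endpoint_detection import (EndpointParams, Segment, activity_series,
                                 apply_hangover, detect_endpoints)
from .errors import ParameterError
from .mfcc_features import (FeatureMatrix, MfccParams, build_mel_filterbank, delta,
                            filterbank_energies, mfcc, power_spectrum)
from .preprocessing import FrameMatrix, FrameParams, apply_window, frame_signal, pre_emphasize

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PipelineParams:
    """Bundle of all stage parameters for one experiment."""

    frame: FrameParams = field(default_factory=FrameParams)
    endpoint: EndpointParams = field(default_factory=EndpointParams)
    mfcc: MfccParams = field(default_factory=MfccParams)


def extract_features(signal: AudioSignal, params: PipelineParams | None = None
                     ) -> tuple[FeatureMatrix, list[Segment]]:
    """Run the full front end on one recording.

    Returns the per-frame feature matrix (voiced frames only, concatenated
    across detected segments) and the detected segments.  A recording with
    no detected activity yields an empty (0, 36) matrix.
    """
    params = params or PipelineParams()
    emphasized = pre_emphasize(signal, params.frame.pre_emphasis_alpha)
    frames = frame_signal(emphasized, params.frame)
    dim = 3 * params.mfcc.n_coeffs + (3 if params.mfcc.include_c0 else 0)
    if frames.num_frames == 0:
        return FeatureMatrix(np.empty((0, dim)), duck_id=signal.source_id), []

    k = activity_series(frames).zero_product
    if params.endpoint.subtract_median:
        k = np.maximum(k - np.median(k), 0.0)
    segments = detect_endpoints(
        k, high_frac=params.endpoint.high_frac, low_frac=params.endpoint.low_frac,
        min_frames=params.endpoint.min_frames, merge_gap=params.endpoint.merge_gap,
        hop_length=frames.hop_length, frame_length=frames.frame_length)
    segments = apply_hangover(segments, params.endpoint.hangover_frames,
                              frames.num_frames, frames.hop_length,
                              frames.frame_length)
    if not segments:
        logger.warning("no voiced segments detected in %s", signal.source_id)
        return FeatureMatrix(np.empty((0, dim)), duck_id=signal.source_id), []

    bank = build_mel_filterbank(signal.sample_rate, params.mfcc.n_fft,
                                params.mfcc.n_filters, params.mfcc.fmin,
                                params.mfcc.fmax)
    blocks = []
    for seg in segments:
        voiced = FrameMatrix(frames.frames[seg.start_frame:seg.end_frame],
                             hop_length=frames.hop_length,
                             sample_rate=frames.sample_rate, windowed=False)
        windowed = apply_window(voiced)
        spec = power_spectrum(windowed, params.mfcc.n_fft)
        s = filterbank_energies(spec, bank, params.mfcc.energy_floor)
        c = mfcc(s, params.mfcc.n_coeffs, params.mfcc.dct_convention,
                 params.mfcc.include_c0)
        d1 = delta(c, params.mfcc.delta_width)
        d2 = delta(d1, params.mfcc.delta_width)
        blocks.append(np.hstack([c, d1, d2]))
    values = np.vstack(blocks)
    return FeatureMatrix(values, duck_id=signal.source_id), segments


def corpus_features(corpus, params: PipelineParams | None = None):
    """Extract features for an iterable of (duck_id, sex, signal, truth).

    Returns (features_per_duck, sex_per_duck); ducks with zero voiced
    frames are excluded with a warning.
    """
    params = params or PipelineParams()
    features: dict[str, FeatureMatrix] = {}
    sexes: dict[str, str] = {}
    for duck_id, sex, signal, _truth in corpus:
        fm, _segments = extract_features(signal, params)
        if fm.num_frames == 0:
            logger.warning("duck %s excluded: no voiced frames", duck_id)
            continue
        features[duck_id] = fm
        sexes[duck_id] = sex
    return features, sexes


def manifest_features(manifest: DatasetManifest, params: PipelineParams | None = None,
                      split: str | None = None):
    """Extract features for every WAV referenced by a manifest."""
    records = manifest.records if split is None else manifest.subset(split).records
    corpus = ((r.duck_id, r.sex, read_wav(r.wav_path), None) for r in records)
    return corpus_features(corpus, params)
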