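"""Reading, writing and validating mono PCM WAV audio and dataset manifests.

All downstream processing assumes a single-channel waveform normalized to
[-1, 1] at a fixed sampling rate (44100 Hz by default).  Stereo files and
files at other rates are rejected rather than silently converted, because an
undocumented downmix or resample changes the energy and spectral features
the classifier depends on.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import wavfile
from scipy.signal import resample_poly

from .errors import AudioFormatError, ManifestError

logger = logging.getLogger(__name__)

#: The sampling rate of the recording rig; all features are computed at this rate.
DEFAULT_SAMPLE_RATE = 44100

VALID_SEXES = ("male", "female")
VALID_SPLITS = ("train", "test", "unassigned")


@dataclass
class AudioSignal:
    """A mono waveform with its sampling rate.

    Parameters
    ----------
    samples : ndarray
        1-D float array of amplitudes in [-1, 1].
    sample_rate : int
        Sampling rate in Hz.
    source_id : str, optional
        Identifier of the originating recording (e.g. a duck id).
    """

    samples: np.ndarray
    sample_rate: int
    source_id: str | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1:
            raise AudioFormatError(
                f"expected a single-channel signal, got array of ndim {self.samples.ndim}"
            )
        if self.samples.size < 1:
            raise AudioFormatError("signal must contain at least one sample")
        if not np.all(np.isfinite(self.samples)):
            raise AudioFormatError("signal contains non-finite samples")
        if int(self.sample_rate) <= 0:
            raise AudioFormatError(f"sample rate must be positive, got {self.sample_rate}")
        self.sample_rate = int(self.sample_rate)

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.sample_rate

    def __len__(self) -> int:
        return self.samples.size


@dataclass
class ManifestRecord:
    wav_path: str
    duck_id: str
    sex: str
    split: str = "unassigned"


@dataclass
class DatasetManifest:
    """A validated roster of recordings: one WAV file per individual duck."""

    records: list[ManifestRecord] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def subset(self, split: str) -> "DatasetManifest":
        return DatasetManifest([r for r in self.records if r.split == split])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(r.wav_path, r.duck_id, r.sex, r.split) for r in self.records],
            columns=["wav_path", "duck_id", "sex", "split"],
        )

    def save(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def read_wav(path: str | Path, expect_rate: int = DEFAULT_SAMPLE_RATE,
             resample: bool = False) -> AudioSignal:
    """Read a 16-bit PCM mono WAV file into a normalized :class:`AudioSignal`.

    Integer PCM samples are scaled by 2**(bits-1) so that full scale maps to
    [-1, 1].  Stereo input raises :class:`AudioFormatError` (downmix policy
    would be arbitrary); a sampling rate other than ``expect_rate`` is
    rejected unless ``resample=True``, in which case the signal is resampled
    with a polyphase FIR filter.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"WAV file not found: {path}")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # scipy chunk warnings on odd writers
            rate, data = wavfile.read(path)
    except ValueError as exc:
        raise AudioFormatError(f"unsupported WAV encoding in {path}: {exc}") from exc
    if data.ndim > 1:
        raise AudioFormatError(
            f"{path} has {data.shape[1]} channels; only mono input is supported"
        )
    if np.issubdtype(data.dtype, np.integer):
        bits = data.dtype.itemsize * 8
        samples = data.astype(np.float64) / float(2 ** (bits - 1))
    elif np.issubdtype(data.dtype, np.floating):
        samples = data.astype(np.float64)
    else:
        raise AudioFormatError(f"unsupported sample dtype {data.dtype} in {path}")
    if expect_rate is not None and rate != expect_rate:
        if not resample:
            raise AudioFormatError(
                f"{path} sampled at {rate} Hz, expected {expect_rate} Hz "
                "(pass resample=True to convert)"
            )
        g = np.gcd(int(expect_rate), int(rate))
        samples = resample_poly(samples, expect_rate // g, rate // g)
        rate = expect_rate
    return AudioSignal(samples=samples, sample_rate=int(rate), source_id=path.stem)


def write_wav(signal: AudioSignal, path: str | Path) -> None:
    """Write an :class:`AudioSignal` as a 16-bit PCM mono WAV file.

    Samples outside [-1, 1] are clipped with a logged warning.
    """
    samples = signal.samples
    peak = np.max(np.abs(samples)) if samples.size else 0.0
    if peak > 1.0:
        logger.warning("clipping %d samples with |amplitude| > 1 (peak %.3f) in %s",
                       int(np.sum(np.abs(samples) > 1.0)), peak, path)
        samples = np.clip(samples, -1.0, 1.0)
    # scale by 2^15 (matching the read normalization) and clip the +1.0 edge
    pcm = np.clip(np.round(samples * 32768.0), -32768, 32767).astype(np.int16)
    wavfile.write(str(path), signal.sample_rate, pcm)


def load_manifest(path: str | Path) -> DatasetManifest:
    """Load and validate a dataset manifest CSV.

    The CSV must have header columns ``wav_path, duck_id, sex, split``.
    Sex tokens are lowercased and must be exactly ``male`` or ``female``;
    duck ids must be unique.  All offending values are listed in the error.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str).fillna("")
    required = {"wav_path", "duck_id", "sex", "split"}
    missing = required - set(df.columns)
    if missing:
        raise ManifestError(f"manifest {path} missing columns: {sorted(missing)}")
    problems: list[str] = []
    df["sex"] = df["sex"].str.strip().str.lower()
    df["split"] = df["split"].str.strip().str.lower().replace("", "unassigned")
    bad_sex = sorted(set(df.loc[~df["sex"].isin(VALID_SEXES), "sex"]))
    if bad_sex:
        problems.append(f"invalid sex tokens {bad_sex} (accepted: male/female)")
    bad_split = sorted(set(df.loc[~df["split"].isin(VALID_SPLITS), "split"]))
    if bad_split:
        problems.append(f"invalid split tokens {bad_split}")
    dupes = sorted(df.loc[df["duck_id"].duplicated(), "duck_id"].unique())
    if dupes:
        problems.append(f"duplicate duck_id values {dupes}")
    if problems:
        raise ManifestError(f"manifest {path} invalid: " + "; ".join(problems))
    records = [
        ManifestRecord(r.wav_path, r.duck_id, r.sex, r.split)
        for r in df.itertuples(index=False)
    ]
    return DatasetManifest(records)
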