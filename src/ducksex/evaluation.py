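"""Confusion-matrix metrics, per-duck vote aggregation, splits and k-fold CV.

The male class is positive throughout, so recall is the recognition
accuracy for male ducks and specificity the recognition accuracy for
female ducks.  A duck's sex is decided by majority vote over its per-frame
classifications; the fraction of frames voting male is recorded as the
per-duck vote fraction that individual-level reports plot.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .audio_io import DatasetManifest, ManifestRecord
from .classifiers import CLASSES, ModelSpec, TrainConfig, fit, predict_frames
from .errors import ParameterError, ShapeError
from .mfcc_features import FeatureMatrix, normalize_features

logger = logging.getLogger(__name__)

POSITIVE = "male"   # positive class convention
NEGATIVE = "female"


@dataclass(frozen=True)
class ConfusionCounts:
    """Binary confusion tally with male as the positive class."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ParameterError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class MetricSet:
    """Accuracy, recall, specificity, precision and F1, each in [0, 1]."""

    accuracy: float
    recall: float
    specificity: float
    precision: float
    f1: float

    def as_percent(self) -> dict[str, float]:
        """Metrics in percent, rounded to 2 decimals (table formatting)."""
        return {k: round(100.0 * v, 2) for k, v in self.__dict__.items()}


@dataclass
class DuckPrediction:
    """Frame votes and the resulting sex call for one duck."""

    duck_id: str
    true_sex: str
    frame_labels: np.ndarray       # 0 = female, 1 = male per frame
    frame_vote_fraction: float     # fraction of frames voting male
    predicted_sex: str


def _as_binary(labels) -> np.ndarray:
    arr = np.asarray(labels)
    if arr.dtype.kind in "UOS":
        out = np.empty(arr.shape, dtype=np.int64)
        for i, v in enumerate(arr.ravel()):
            s = str(v).lower()
            if s not in CLASSES:
                raise ParameterError(f"unknown sex label {v!r}")
            out.ravel()[i] = CLASSES.index(s)
        return out
    out = arr.astype(np.int64)
    if not np.all(np.isin(out, [0, 1])):
        raise ParameterError("labels must be binary (0=female, 1=male)")
    return out


def confusion(true_labels, predicted_labels) -> ConfusionCounts:
    """Tally TP/FP/FN/TN with male (label 1) as the positive class."""
    y = _as_binary(true_labels)
    p = _as_binary(predicted_labels)
    if y.shape != p.shape:
        raise ShapeError(f"label shapes differ: {y.shape} vs {p.shape}")
    return ConfusionCounts(
        tp=int(np.sum((y == 1) & (p == 1))),
        fp=int(np.sum((y == 0) & (p == 1))),
        fn=int(np.sum((y == 1) & (p == 0))),
        tn=int(np.sum((y == 0) & (p == 0))),
    )


def metrics(counts: ConfusionCounts) -> MetricSet:
    """Accuracy, recall, specificity, precision and F1 from the counts.

    A zero denominator yields 0 for that metric with a logged warning.
    """
    if counts.total == 0:
        raise ParameterError("cannot compute metrics on zero evaluated items")

    def ratio(num: int, den: int, name: str) -> float:
        if den == 0:
            logger.warning("%s undefined (zero denominator); reporting 0", name)
            return 0.0
        return num / den

    accuracy = (counts.tp + counts.tn) / counts.total
    recall = ratio(counts.tp, counts.tp + counts.fn, "recall")
    specificity = ratio(counts.tn, counts.fp + counts.tn, "specificity")
    precision = ratio(counts.tp, counts.tp + counts.fp, "precision")
    f1 = 0.0 if precision + recall == 0 else 2 * precision * recall / (precision + recall)
    if precision + recall == 0:
        logger.warning("f1 undefined (precision + recall = 0); reporting 0")
    return MetricSet(accuracy=accuracy, recall=recall, specificity=specificity,
                     precision=precision, f1=f1)


def aggregate_duck(frame_probabilities: np.ndarray, duck_id: str, true_sex: str,
                   method: str = "vote") -> DuckPrediction:
    """Collapse per-frame probabilities into one sex call for a duck.

    ``method="vote"`` takes the majority over frame argmaxes (a tie at
    exactly 0.5 goes to male, deterministically); ``method="mean_prob"``
    averages the male probability over frames instead and applies the same
    0.5 rule.  ``frame_vote_fraction`` is always the fraction of frames
    whose argmax is male.
    """
    p = np.atleast_2d(np.asarray(frame_probabilities, dtype=np.float64))
    if p.shape[0] == 0:
        raise ParameterError(f"duck {duck_id} has no frames to aggregate")
    if p.shape[1] != 2:
        raise ShapeError(f"expected (n, 2) probabilities, got {p.shape}")
    frame_labels = np.argmax(p, axis=1)
    vote_fraction = float(np.mean(frame_labels == 1))
    if method == "vote":
        score = vote_fraction
    elif method == "mean_prob":
        score = float(np.mean(p[:, 1]))
    else:
        raise ParameterError(f"unknown aggregation method {method!r}")
    predicted = POSITIVE if score >= 0.5 else NEGATIVE
    return DuckPrediction(duck_id=duck_id, true_sex=true_sex,
                          frame_labels=frame_labels,
                          frame_vote_fraction=vote_fraction,
                          predicted_sex=predicted)


def split_dataset(manifest: DatasetManifest, n_train_per_sex: int = 120,
                  n_test_per_sex: int = 30, seed: int = 0) -> DatasetManifest:
    """Seeded duck-level stratified split into train and test partitions.

    Sampling is at the duck level only -- frames from one duck never cross
    the partition boundary.
    """
    rng = np.random.default_rng(seed)
    out: list[ManifestRecord] = []
    for sex in ("male", "female"):
        ducks = [r for r in manifest.records if r.sex == sex]
        need = n_train_per_sex + n_test_per_sex
        if len(ducks) < need:
            raise ParameterError(
                f"need {need} {sex} ducks ({n_train_per_sex} train + "
                f"{n_test_per_sex} test), manifest has {len(ducks)}"
            )
        order = rng.permutation(len(ducks))
        for j, idx in enumerate(order[:need]):
            r = ducks[idx]
            split = "train" if j < n_train_per_sex else "test"
            out.append(ManifestRecord(r.wav_path, r.duck_id, r.sex, split))
    out.sort(key=lambda r: r.duck_id)
    return DatasetManifest(out)


def sample_frames(features_per_duck: dict[str, FeatureMatrix | np.ndarray],
                  sex_per_duck: dict[str, str], n_per_duck: int = 3000,
                  seed: int = 0):
    """Draw exactly ``n_per_duck`` frames from every duck to balance the set.

    Uniform subsampling without replacement when a duck has enough voiced
    frames; with replacement (and a logged warning) when it has fewer.
    Returns (X, y, duck_ids) where y is 0/1 (female/male) per frame.
    """
    rng = np.random.default_rng(seed)
    xs, ys, ids = [], [], []
    for duck_id in sorted(features_per_duck):
        fm = features_per_duck[duck_id]
        values = fm.values if isinstance(fm, FeatureMatrix) else np.asarray(fm)
        n = values.shape[0]
        if n == 0:
            raise ParameterError(f"duck {duck_id} has zero voiced frames")
        if n >= n_per_duck:
            idx = rng.choice(n, size=n_per_duck, replace=False)
        else:
            logger.warning("duck %s has %d < %d frames; sampling with replacement",
                           duck_id, n, n_per_duck)
            idx = rng.choice(n, size=n_per_duck, replace=True)
        xs.append(values[idx])
        ys.append(np.full(n_per_duck, CLASSES.index(sex_per_duck[duck_id])))
        ids.extend([duck_id] * n_per_duck)
    return np.vstack(xs), np.concatenate(ys), np.asarray(ids)


def evaluate_ducks(model, features_per_duck: dict[str, FeatureMatrix | np.ndarray],
                   sex_per_duck: dict[str, str], norm_stats=None,
                   method: str = "vote"):
    """Score every duck with a trained model; returns (predictions, counts).

    ``norm_stats`` (mean, std) from the training set are applied to each
    duck's raw features before prediction.
    """
    predictions: list[DuckPrediction] = []
    for duck_id in sorted(features_per_duck):
        fm = features_per_duck[duck_id]
        values = fm.values if isinstance(fm, FeatureMatrix) else np.asarray(fm)
        if norm_stats is not None:
            mean, std = norm_stats
            values = (values - mean) / std
        probs = predict_frames(model, values)
        predictions.append(aggregate_duck(probs, duck_id, sex_per_duck[duck_id],
                                          method=method))
    counts = confusion([p.true_sex for p in predictions],
                       [p.predicted_sex for p in predictions])
    return predictions, counts


def _stratified_folds(duck_ids: list[str], sexes: list[str], k: int,
                      rng: np.random.Generator) -> list[list[str]]:
    folds: list[list[str]] = [[] for _ in range(k)]
    for sex in ("male", "female"):
        ids = [d for d, s in zip(duck_ids, sexes) if s == sex]
        ids = [ids[i] for i in rng.permutation(len(ids))]
        for j, duck in enumerate(ids):
            folds[j % k].append(duck)
    return folds


def kfold_cv(features_per_duck: dict[str, FeatureMatrix | np.ndarray],
             sex_per_duck: dict[str, str], model_spec: ModelSpec,
             train_config: TrainConfig, k: int = 5, seed: int = 0,
             n_frames_per_duck: int = 3000, method: str = "vote"):
    """Duck-level stratified k-fold cross-validation.

    Every duck appears in exactly one test fold; folds are balanced per sex
    to within one duck.  Each fold trains a fresh model on the remaining
    ducks' frames (normalized with that fold's training statistics) and
    scores the held-out ducks by majority vote.  Returns a DataFrame with
    one row per fold plus ``mean`` and ``std`` rows.
    """
    if k < 2:
        raise ParameterError(f"k must be >= 2, got {k}")
    duck_ids = sorted(features_per_duck)
    sexes = [sex_per_duck[d] for d in duck_ids]
    for sex in ("male", "female"):
        if sexes.count(sex) < k:
            raise ParameterError(f"need at least {k} {sex} ducks for {k}-fold CV")
    rng = np.random.default_rng(seed)
    folds = _stratified_folds(duck_ids, sexes, k, rng)

    rows = []
    for fold_idx, test_ducks in enumerate(folds):
        train_ducks = [d for d in duck_ids if d not in set(test_ducks)]
        x_tr, y_tr, _ = sample_frames(
            {d: features_per_duck[d] for d in train_ducks},
            sex_per_duck, n_per_duck=n_frames_per_duck, seed=seed + fold_idx)
        fm_tr, (mean, std) = normalize_features(FeatureMatrix(x_tr))
        model = fit(model_spec, fm_tr.values, y_tr,
                    TrainConfig(**{**train_config.__dict__,
                                   "seed": train_config.seed + fold_idx}),
                    norm_stats=(mean, std))
        _, counts = evaluate_ducks(
            model, {d: features_per_duck[d] for d in test_ducks},
            sex_per_duck, norm_stats=(mean, std), method=method)
        rows.append({"fold": fold_idx, **metrics(counts).__dict__})
    df = pd.DataFrame(rows)
    summary = df.drop(columns="fold").agg(["mean", "std"])
    summary.insert(0, "fold", summary.index)
    return pd.concat([df, summary], ignore_index=True)
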