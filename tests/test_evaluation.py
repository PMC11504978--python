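import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ducksex import (ConfusionCounts, DatasetManifest, ModelSpec, TrainConfig,
                     aggregate_duck, confusion, kfold_cv, metrics, sample_frames,
                     split_dataset)
from ducksex.audio_io import ManifestRecord
from ducksex.errors import ParameterError, ShapeError


def roster(n_male, n_female):
    recs = [ManifestRecord(f"m{i}.wav", f"m{i:03d}", "male") for i in range(n_male)]
    recs += [ManifestRecord(f"f{i}.wav", f"f{i:03d}", "female") for i in range(n_female)]
    return DatasetManifest(recs)


class TestConfusion:
    def test_perfect_predictions(self):
        c = confusion(["male", "male", "female", "female"],
                      ["male", "male", "female", "female"])
        assert (c.tp, c.tn, c.fp, c.fn) == (2, 2, 0, 0)

    def test_all_male_predictor(self):
        c = confusion(["male", "female"], ["male", "male"])
        assert (c.tp, c.fp, c.fn, c.tn) == (1, 1, 0, 0)

    def test_printed_worked_counts(self):
        """30 male / 30 female ducks with 28 + 28 correct."""
        truth = ["male"] * 30 + ["female"] * 30
        pred = ["male"] * 28 + ["female"] * 2 + ["female"] * 28 + ["male"] * 2
        c = confusion(truth, pred)
        assert (c.tp, c.fn, c.tn, c.fp) == (28, 2, 28, 2)

    def test_agrees_with_sklearn(self, rng):
        from sklearn.metrics import confusion_matrix
        y = rng.integers(0, 2, 200)
        p = rng.integers(0, 2, 200)
        c = confusion(y, p)
        tn, fp, fn, tp = confusion_matrix(y, p, labels=[0, 1]).ravel()
        assert (c.tp, c.fp, c.fn, c.tn) == (tp, fp, fn, tn)

    def test_length_mismatch(self):
        with pytest.raises(ShapeError):
            confusion([1, 0], [1])


class TestMetrics:
    @pytest.mark.parametrize("counts,accuracy", [
        (ConfusionCounts(tp=28, fn=2, tn=28, fp=2), 93.33),   # 56 of 60
        (ConfusionCounts(tp=28, fn=2, tn=27, fp=3), 91.67),   # 55 of 60
        (ConfusionCounts(tp=29, fn=1, tn=28, fp=2), 95.00),   # 57 of 60
    ])
    def test_duck_level_worked_examples(self, counts, accuracy):
        assert metrics(counts).as_percent()["accuracy"] == accuracy

    def test_perfect_counts_all_ones(self):
        m = metrics(ConfusionCounts(tp=5, fp=0, fn=0, tn=5))
        assert m.accuracy == m.recall == m.specificity == m.precision == m.f1 == 1.0

    def test_zero_denominator_yields_zero_with_warning(self, caplog):
        with caplog.at_level("WARNING"):
            m = metrics(ConfusionCounts(tp=0, fp=0, fn=0, tn=10))
        assert m.recall == 0.0 and m.precision == 0.0 and m.f1 == 0.0
        assert "undefined" in caplog.text

    def test_all_zero_counts_error(self):
        with pytest.raises(ParameterError):
            metrics(ConfusionCounts(0, 0, 0, 0))

    @settings(deadline=None, derandomize=True)
    @given(st.integers(1, 50), st.integers(1, 50), st.integers(0, 50), st.integers(0, 50))
    def test_label_swap_identities(self, tp, tn, fp, fn):
        """Accuracy invariant under class swap; recall and specificity exchange."""
        m = metrics(ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=tn))
        swapped = metrics(ConfusionCounts(tp=tn, fp=fn, fn=fp, tn=tp))
        assert m.accuracy == pytest.approx(swapped.accuracy)
        assert m.recall == pytest.approx(swapped.specificity)
        assert m.specificity == pytest.approx(swapped.recall)

    @settings(deadline=None, derandomize=True)
    @given(st.lists(st.sampled_from(["male", "female"]), min_size=2, max_size=30))
    def test_self_agreement_is_perfect(self, labels):
        if len(set(labels)) < 2:
            labels = labels + ["male", "female"]
        m = metrics(confusion(labels, labels))
        assert m.accuracy == m.f1 == 1.0


class TestAggregateDuck:
    def test_vote_fraction_and_majority(self):
        probs = np.zeros((3000, 2))
        probs[:2400, 1] = 1.0   # 2400 frames vote male
        probs[2400:, 0] = 1.0
        p = aggregate_duck(probs, "m001", "male")
        assert p.frame_vote_fraction == pytest.approx(0.8)
        assert p.predicted_sex == "male"

    def test_exact_tie_goes_male(self):
        probs = np.array([[0.9, 0.1], [0.1, 0.9]])
        assert aggregate_duck(probs, "x", "female").predicted_sex == "male"

    def test_unanimous_female(self):
        probs = np.tile([0.8, 0.2], (10, 1))
        p = aggregate_duck(probs, "f001", "female")
        assert p.predicted_sex == "female" and p.frame_vote_fraction == 0.0

    def test_mean_prob_aggregation_option(self):
        probs = np.array([[0.0, 1.0], [0.6, 0.4], [0.6, 0.4]])
        assert aggregate_duck(probs, "x", "male", method="vote").predicted_sex == "female"
        assert aggregate_duck(probs, "x", "male", method="mean_prob").predicted_sex == "male"

    def test_empty_frames_error(self):
        with pytest.raises(ParameterError):
            aggregate_duck(np.empty((0, 2)), "x", "male")


class TestSplitDataset:
    def test_full_roster_split_counts(self):
        split = split_dataset(roster(150, 150), 120, 30, seed=0)
        df = split.to_frame()
        counts = df.groupby(["sex", "split"]).size()
        assert counts[("male", "train")] == counts[("female", "train")] == 120
        assert counts[("male", "test")] == counts[("female", "test")] == 30

    def test_seeded_and_disjoint(self):
        a = split_dataset(roster(10, 10), 6, 4, seed=5)
        b = split_dataset(roster(10, 10), 6, 4, seed=5)
        assert a.to_frame().equals(b.to_frame())
        train_ids = {r.duck_id for r in a.records if r.split == "train"}
        test_ids = {r.duck_id for r in a.records if r.split == "test"}
        assert train_ids & test_ids == set()

    def test_shortfall_reported(self):
        with pytest.raises(ParameterError, match="female"):
            split_dataset(roster(10, 3), 6, 4, seed=0)


class TestSampleFrames:
    def test_exact_count_without_replacement(self, rng):
        feats = {"d1": rng.normal(size=(5000, 36))}
        x, y, ids = sample_frames(feats, {"d1": "male"}, n_per_duck=3000, seed=0)
        assert x.shape == (3000, 36)
        assert len(np.unique(x[:, 0])) == 3000   # distinct rows drawn

    def test_with_replacement_when_short(self, rng, caplog):
        feats = {"d1": rng.normal(size=(100, 36))}
        with caplog.at_level("WARNING"):
            x, y, _ = sample_frames(feats, {"d1": "female"}, n_per_duck=300, seed=0)
        assert x.shape == (300, 36)
        assert np.all(y == 0)
        assert "replacement" in caplog.text

    def test_zero_frame_duck_error(self):
        with pytest.raises(ParameterError, match="d1"):
            sample_frames({"d1": np.empty((0, 36))}, {"d1": "male"}, 10)


class TestKFold:
    def make_ducks(self, n_per_sex=6, frames=40, sep=3.0, seed=0):
        rng = np.random.default_rng(seed)
        feats, sexes = {}, {}
        for sex, center in (("male", sep), ("female", -sep)):
            for i in range(n_per_sex):
                d = f"{sex[0]}{i:02d}"
                feats[d] = rng.normal(center, 1.0, size=(frames, 36))
                sexes[d] = sex
        return feats, sexes

    def test_fold_structure(self):
        feats, sexes = self.make_ducks()
        from ducksex.evaluation import _stratified_folds
        ducks = sorted(feats)
        folds = _stratified_folds(ducks, [sexes[d] for d in ducks], 5,
                                  np.random.default_rng(0))
        sizes = sorted(len(f) for f in folds)
        assert max(sizes) - min(sizes) <= 2   # <= 1 duck per sex
        seen = [d for f in folds for d in f]
        assert sorted(seen) == ducks   # every duck in exactly one test fold

    def test_cv_on_separable_ducks(self):
        feats, sexes = self.make_ducks()
        df = kfold_cv(feats, sexes, ModelSpec("bpnn"),
                      TrainConfig(epochs=20, seed=0), k=5, seed=0,
                      n_frames_per_duck=40)
        per_fold = df[df.fold.apply(lambda v: isinstance(v, (int, np.integer)))]
        assert len(per_fold) == 5
        mean_acc = df.loc[df.fold == "mean", "accuracy"].iloc[0]
        assert mean_acc >= 0.9   # trivially separable ducks

    def test_k_too_small(self):
        feats, sexes = self.make_ducks(2)
        with pytest.raises(ParameterError):
            kfold_cv(feats, sexes, ModelSpec("bpnn"), TrainConfig(epochs=1), k=1)
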