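"""Classifier contract, training protocol and evaluation metrics."""

import numpy as np
import pytest
from scipy.stats import mannwhitneyu

from nativecam.io_core import ParticipantRecord, Volume
from nativecam.model import (ClassifierSpec, PredictionRecord, TrainConfig,
                             age_bin, build_classifier, evaluate,
                             load_classifier, predict, save_classifier, train)


def _spec(shape=(8, 8, 8), **kw):
    return ClassifierSpec("tiny_3d", shape, width=2, norm="none", **kw)


class TestBuild:
    @pytest.mark.parametrize("arch", ["tiny_3d", "residual_3d", "dense_3d"])
    def test_forward_finite_and_probabilities_normalised(self, arch, rng):
        spec = ClassifierSpec(arch, (8, 8, 8), width=2)
        c = build_classifier(spec, seed=0)
        zeros = c.forward(np.zeros((8, 8, 8)))
        assert np.all(np.isfinite(zeros))
        probs = c.predict_proba(rng.normal(size=(8, 8, 8)))
        assert probs.sum() == pytest.approx(1.0, abs=1e-6)
        assert np.all(probs >= 0)

    def test_too_small_input_rejected(self):
        with pytest.raises(ValueError, match="too small"):
            build_classifier(ClassifierSpec("tiny_3d", (4, 4, 4)))

    def test_num_classes_fixed(self):
        with pytest.raises(ValueError):
            ClassifierSpec("tiny_3d", (8, 8, 8), num_classes=3)

    def test_checkpoint_round_trip(self, tmp_path, rng):
        c = build_classifier(_spec(), seed=4)
        save_classifier(c, None, tmp_path / "ckpt.npz")
        c2 = load_classifier(tmp_path / "ckpt.npz")
        x = rng.normal(size=(8, 8, 8))
        np.testing.assert_allclose(c.forward(x), c2.forward(x), atol=1e-12)


def _separable_dataset(rng, n=6, shape=(8, 8, 8)):
    """Class 1 volumes carry a bright corner block: trivially separable."""
    data = []
    for i in range(n):
        x = rng.normal(0, 0.1, size=shape)
        y = i % 2
        if y:
            x[:4, :4, :4] += 2.0
        data.append((Volume(x, np.eye(4), id=f"s{i}"), y))
    return data


class TestTrain:
    def test_eval_cadence(self, rng):
        data = _separable_dataset(rng)
        c = build_classifier(_spec(), seed=0)
        log = train(c, data, data, TrainConfig(max_epochs=4, eval_every=2, seed=0))
        assert [e["epoch"] for e in log.entries] == [2, 4]

    def test_same_seed_identical_logs(self, rng):
        data = _separable_dataset(rng)
        cfg = TrainConfig(max_epochs=4, eval_every=2, seed=3)
        logs = []
        for _ in range(2):
            c = build_classifier(_spec(), seed=9)
            logs.append(train(c, data, data, cfg))
        assert logs[0].entries == logs[1].entries

    def test_single_class_train_set_rejected(self, rng):
        data = [(Volume(rng.normal(size=(8, 8, 8)), np.eye(4)), 1) for _ in range(4)]
        c = build_classifier(_spec(), seed=0)
        with pytest.raises(ValueError, match="both classes"):
            train(c, data, data, TrainConfig(max_epochs=2, eval_every=2))

    def test_separable_data_learned(self, rng):
        """A large planted effect is learned to high validation accuracy in
        a few epochs (property over independent draws)."""
        wins = 0
        for seed in range(5):
            r = np.random.default_rng(seed)
            train_set = _separable_dataset(r, n=12)
            val_set = _separable_dataset(np.random.default_rng(seed + 50), n=8)
            c = build_classifier(ClassifierSpec("tiny_3d", (8, 8, 8), width=4), seed=seed)
            log = train(c, train_set, val_set,
                        TrainConfig(max_epochs=20, eval_every=2, batch_size=2, seed=seed))
            best = max(e["val_accuracy"] for e in log.entries)
            wins += best >= 0.9
        assert wins >= 4

    def test_best_checkpoint_earliest_tie(self, rng):
        data = _separable_dataset(rng, n=8)
        c = build_classifier(_spec(), seed=1)
        log = train(c, data, data, TrainConfig(max_epochs=8, eval_every=2, seed=1))
        accs = {e["epoch"]: e["val_accuracy"] for e in log.entries}
        best_acc = max(accs.values())
        assert log.best_epoch == min(ep for ep, a in accs.items() if a == best_acc)


class TestPredict:
    @pytest.mark.parametrize("prob,expected", [(0.5, 0), (0.51, 1), (0.49, 0)])
    def test_strict_threshold(self, prob, expected):
        rec = PredictionRecord(id="x", probability=prob, predicted=int(prob > 0.5))
        assert rec.predicted == expected

    def test_outcome_classes(self):
        assert PredictionRecord("a", 0.9, 1, true_label=1).outcome == "TP"
        assert PredictionRecord("b", 0.9, 1, true_label=0).outcome == "FP"
        assert PredictionRecord("c", 0.1, 0, true_label=0).outcome == "TN"
        assert PredictionRecord("d", 0.1, 0, true_label=1).outcome == "FN"

    def test_predict_fills_record(self, rng):
        c = build_classifier(_spec(), seed=0)
        v = Volume(rng.normal(size=(8, 8, 8)), np.eye(4), id="p1")
        rec = ParticipantRecord("p1", 1, "A", "female", 12.0, "test")
        p = predict(c, v, record=rec)
        assert p.site == "A" and p.true_label == 1
        assert p.predicted == int(p.probability > 0.5)

    def test_shape_mismatch(self, rng):
        c = build_classifier(_spec(), seed=0)
        with pytest.raises(ValueError, match="shape"):
            predict(c, Volume(rng.normal(size=(6, 6, 6)), np.eye(4)))


def _preds(pairs, **meta):
    return [PredictionRecord(id=f"s{i}", probability=p, predicted=int(p > 0.5),
                             true_label=y, **meta)
            for i, (p, y) in enumerate(pairs)]


class TestEvaluate:
    def test_perfect_predictions(self):
        preds = _preds([(0.9, 1)] * 5 + [(0.1, 0)] * 5)
        row = evaluate(preds).iloc[0]
        assert row["accuracy"] == 1.0 and row["auc"] == 1.0
        assert row["sensitivity"] == 1.0 and row["specificity"] == 1.0

    def test_contingency_arithmetic(self):
        pairs = [(0.9, 1)] * 4 + [(0.1, 1)] + [(0.1, 0)] * 4 + [(0.9, 0)]
        row = evaluate(_preds(pairs)).iloc[0]
        assert row["sensitivity"] == pytest.approx(0.8)
        assert row["specificity"] == pytest.approx(0.8)

    def test_constant_probabilities_auc_half(self):
        preds = _preds([(0.5, 1)] * 4 + [(0.5, 0)] * 4)
        assert evaluate(preds).iloc[0]["auc"] == pytest.approx(0.5)

    def test_single_class_group_flagged(self):
        preds = _preds([(0.7, 1), (0.4, 1)])
        row = evaluate(preds).iloc[0]
        assert not row["auc_defined"]
        assert np.isnan(row["auc"])

    def test_auc_equals_mann_whitney(self, rng):
        """Trapezoidal ROC AUC equals the Mann-Whitney U statistic divided
        by n1*n0 (oracle equivalence, random prediction sets)."""
        for trial in range(20):
            r = np.random.default_rng(trial)
            n = int(r.integers(4, 50))
            y = np.concatenate([np.zeros(2), np.ones(2),
                                r.integers(0, 2, size=n - 4)]).astype(int)
            prob = r.random(len(y))
            preds = _preds(list(zip(prob, y)))
            auc = evaluate(preds).iloc[0]["auc"]
            u = mannwhitneyu(prob[y == 1], prob[y == 0]).statistic
            assert auc == pytest.approx(u / ((y == 1).sum() * (y == 0).sum()), abs=1e-9)

    def test_group_by_site(self):
        preds = (_preds([(0.9, 1), (0.1, 0)], site="A")
                 + _preds([(0.2, 1), (0.8, 0)], site="B"))
        table = evaluate(preds, group_by="site").set_index("group")
        assert table.loc["A", "accuracy"] == 1.0
        assert table.loc["B", "accuracy"] == 0.0


class TestAgeBins:
    @pytest.mark.parametrize("age,bin_", [
        (10.0, "10-15"), (5.0, "5-10"), (15.0, "15-20"),
        (19.99, "15-20"), (20.0, "over-20"), (64.0, "over-20"), (3.0, "under-5")])
    def test_half_open_bins(self, age, bin_):
        assert age_bin(age) == bin_
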