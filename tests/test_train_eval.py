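"""Splitting, training schedules, inference path, and metrics."""

import numpy as np
import pytest

from clockapi.backbone import Backbone, BackboneSpec, extract_embedding
from clockapi.data_prep import standardize
from clockapi.train_eval import (ApiNetModel, ConventionalModel, MetricsReport,
                                 SplitSpec, TrainConfig, evaluate,
                                 repeated_runs, stratified_split, train,
                                 train_conventional)


class TestStratifiedSplit:
    def test_half_quarter_quarter_arithmetic(self, tiny_records):
        from clockapi import synthclock
        recs = synthclock.generate_records(8, seed=2)
        tr, va, te = stratified_split(recs, SplitSpec(seed=0))
        assert len(tr) == 12 and len(va) == 6 and len(te) == 6
        for split in (tr, va, te):
            labels = [r.label for r in split]
            assert labels.count(3) == labels.count(4) == labels.count(5)

    def test_partition_disjoint_cover(self, small_records):
        tr, va, te = stratified_split(small_records, SplitSpec(seed=1))
        ids = [r.id for r in tr] + [r.id for r in va] + [r.id for r in te]
        assert sorted(ids) == sorted(r.id for r in small_records)
        assert len(set(ids)) == len(ids)

    def test_same_seed_identical_split(self, small_records):
        a = stratified_split(small_records, SplitSpec(seed=4))
        b = stratified_split(small_records, SplitSpec(seed=4))
        for sa, sb in zip(a, b):
            assert [r.id for r in sa] == [r.id for r in sb]

    def test_bad_fractions_rejected(self):
        with pytest.raises(ValueError):
            SplitSpec(fractions=(0.5, 0.3, 0.3))


class TestFreezeContracts:
    def test_frozen_training_leaves_backbone_untouched(self, tiny_records):
        bb = Backbone(BackboneSpec(embedding_dim=16), seed=0)
        bb.set_trainable(False)
        before = bb.checksum()
        model = ApiNetModel(bb, seed=0)
        cfg = TrainConfig(epochs=2, per_class=2, lr=1e-3, seed=0)
        model, log = train(model, tiny_records, [], cfg)
        assert bb.checksum() == before
        assert (log["backbone_checksum"] == before).all()

    def test_gradual_first_changes_backbone_after_frozen_phase(self, tiny_records):
        bb = Backbone(BackboneSpec(embedding_dim=16), seed=1)
        model = ApiNetModel(bb, seed=1)
        start = bb.checksum()
        cfg = TrainConfig(epochs=3, per_class=2, lr=1e-3, seed=1,
                          freeze_mode="gradual", frozen_epochs=1)
        model, log = train(model, tiny_records, [], cfg)
        sums = log["backbone_checksum"].tolist()
        assert sums[0] == start          # epoch 1: still frozen
        assert sums[1] != start          # epoch 2 = frozen_epochs + 1: unfrozen
        assert sums[2] != sums[1]

    def test_set_trainable_toggle_round_trip(self):
        bb = Backbone(BackboneSpec(embedding_dim=8), seed=2)
        assert bb.spec.trainable
        bb.set_trainable(False).set_trainable(True)
        assert bb.spec.trainable
        assert all(p.trainable for p in bb.parameters())


class TestFinetune:
    def test_zero_epochs_is_noop(self, small_records):
        from clockapi.backbone import finetune_backbone
        bb = Backbone(BackboneSpec(embedding_dim=16), seed=3)
        before = bb.checksum()
        finetune_backbone(bb, [standardize(r) for r in small_records], epochs=0)
        assert bb.checksum() == before

    def test_loss_decreases_over_epochs(self, finetuned_small):
        log = finetuned_small.finetune_loss_log
        assert len(log) == 10
        assert log[-1] < log[0]

    def test_empty_training_set_rejected(self):
        from clockapi.backbone import finetune_backbone
        with pytest.raises(ValueError):
            finetune_backbone(Backbone(BackboneSpec(embedding_dim=8)), [])


class TestInference:
    def test_predict_equals_conventional_pipeline(self, finetuned_small,
                                                  small_records):
        """Single-image inference is exactly backbone -> shared classifier;
        the interaction block plays no part."""
        model = ApiNetModel(finetuned_small, seed=4)
        for rec in small_records[:5]:
            label, probs = model.predict(rec)
            emb = extract_embedding(finetuned_small, standardize(rec))
            logits = emb @ model.api.classifier.W.data + model.api.classifier.b.data
            ref = np.exp(logits - logits.max())
            ref /= ref.sum()
            np.testing.assert_array_equal(probs, model._probs_from_embeddings(emb[None])[0])
            assert label == model.classes[int(np.argmax(ref))]

    def test_probabilities_normalized_and_deterministic(self, finetuned_small,
                                                        small_records):
        model = ApiNetModel(finetuned_small, seed=5)
        l1, p1 = model.predict(small_records[0])
        l2, p2 = model.predict(small_records[0])
        assert l1 == l2
        np.testing.assert_array_equal(p1, p2)
        assert p1.sum() == pytest.approx(1.0, abs=1e-6)


class _StubModel:
    """Fixed-output classifier for metric arithmetic."""

    def __init__(self, outputs):
        self.outputs = list(outputs)
        self.classes = [3, 4, 5]

    def predict_batch(self, records):
        labels = np.array(self.outputs[: len(records)])
        return labels, None


class TestEvaluate:
    def _records(self, labels):
        from clockapi.data_prep import ImageRecord
        return [ImageRecord(f"r{i}", np.zeros((1, 1, 3), np.float32), l, label=l)
                for i, l in enumerate(labels)]

    def test_perfect_predictions_score_one(self):
        recs = self._records([3, 3, 4, 4, 5, 5])
        rep = evaluate(_StubModel([3, 3, 4, 4, 5, 5]), recs)
        assert rep.accuracy == rep.f1 == rep.precision == rep.recall == 1.0

    def test_constant_predictor_on_balanced_data(self):
        recs = self._records([3, 3, 4, 4, 5, 5])
        rep = evaluate(_StubModel([4] * 6), recs)
        assert rep.accuracy == pytest.approx(1 / 3)
        assert rep.recall == pytest.approx(1 / 3)

    def test_hand_computed_confusion_matrix(self):
        # truth:      3 3 3 4 4 5            predictions below
        recs = self._records([3, 3, 3, 4, 4, 5])
        rep = evaluate(_StubModel([3, 3, 4, 4, 5, 5]), recs)
        # accuracy = 4/6; per-class precision: 3 -> 2/2, 4 -> 1/2, 5 -> 1/2
        # weighted precision = (3*1 + 2*0.5 + 1*0.5)/6 = 0.75
        assert rep.accuracy == pytest.approx(4 / 6)
        assert rep.precision == pytest.approx(0.75)
        assert rep.per_class[3]["recall"] == pytest.approx(2 / 3)
        assert rep.per_class[5]["recall"] == pytest.approx(1.0)

    def test_weighted_recall_equals_accuracy(self):
        recs = self._records([3, 3, 4, 5, 5, 5])
        rep = evaluate(_StubModel([3, 4, 4, 5, 3, 5]), recs)
        assert rep.recall == pytest.approx(rep.accuracy)

    def test_empty_test_set_rejected(self):
        with pytest.raises(ValueError):
            evaluate(_StubModel([]), [])


class TestRepeatedRuns:
    @staticmethod
    def _pipeline(seed):
        rng = np.random.default_rng(seed)
        v = float(rng.uniform(0.5, 0.9))
        return MetricsReport(accuracy=v, f1=v, precision=v, recall=v, per_class={})

    def test_row_count_and_mean(self):
        df = repeated_runs(self._pipeline, n_runs=3, seeds=[1, 2, 3])
        assert len(df) == 5  # 3 runs + mean + sd
        runs = df.iloc[:3]["accuracy"].astype(float)
        assert df.iloc[3]["accuracy"] == pytest.approx(runs.mean())

    def test_identical_seeds_give_zero_sd(self):
        df = repeated_runs(self._pipeline, n_runs=2, seeds=[7, 7])
        assert df.iloc[-1]["accuracy"] == pytest.approx(0.0)

    def test_single_run_rejected(self):
        with pytest.raises(ValueError):
            repeated_runs(self._pipeline, n_runs=1)


def test_model_checkpoint_round_trip(tmp_path, finetuned_small, small_records):
    model = ApiNetModel(finetuned_small, seed=6)
    path = tmp_path / "model.npz"
    model.save(path)
    loaded = ApiNetModel.load(path)
    l1, p1 = model.predict(small_records[0])
    l2, p2 = loaded.predict(small_records[0])
    assert l1 == l2
    np.testing.assert_allclose(p1, p2, atol=1e-7)
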