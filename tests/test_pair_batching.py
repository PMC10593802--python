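"""Stratified batching and the three pair-mining strategies."""

import logging

import numpy as np
import pytest

from clockapi.pair_batching import (PairAssignment, PairedBatch, build_pairs,
                                    intra_inter_toggle,
                                    make_stratified_batches,
                                    pairwise_distances)
from conftest import brute_force_pairs


def records_stub(counts: dict[int, int]):
    """Lightweight labeled records (pair mining never touches pixels)."""
    from clockapi.data_prep import ImageRecord

    out = []
    for label, n in counts.items():
        for k in range(n):
            out.append(ImageRecord(id=f"c{label}_{k:02d}",
                                   pixels=np.zeros((1, 1, 3), np.float32),
                                   raw_score=label, label=label))
    return out


class TestStratifiedBatches:
    def test_sixty_images_twenty_per_class_is_one_batch(self):
        batches = make_stratified_batches(records_stub({3: 20, 4: 20, 5: 20}),
                                          per_class=20, seed=0)
        assert len(batches) == 1
        assert len(batches[0]) == 60
        assert batches[0].class_counts == {3: 20, 4: 20, 5: 20}

    def test_six_images_one_per_class_gives_two_batches_of_three(self):
        batches = make_stratified_batches(records_stub({3: 2, 4: 2, 5: 2}),
                                          per_class=1, seed=0)
        assert [len(b) for b in batches] == [3, 3]

    def test_same_seed_identical_partition(self):
        recs = records_stub({3: 8, 4: 8, 5: 8})
        a = make_stratified_batches(recs, per_class=4, seed=5)
        b = make_stratified_batches(recs, per_class=4, seed=5)
        assert [x.ids for x in a] == [x.ids for x in b]

    def test_partition_covers_each_image_once(self):
        recs = records_stub({3: 9, 4: 9, 5: 9})
        batches = make_stratified_batches(recs, per_class=3, seed=1)
        seen = [i for b in batches for i in b.ids]
        assert sorted(seen) == sorted(r.id for r in recs)

    def test_partial_batch_with_singleton_class_dropped(self, caplog):
        with caplog.at_level(logging.WARNING):
            batches = make_stratified_batches(records_stub({3: 5, 4: 5, 5: 5}),
                                              per_class=4, seed=0)
        assert len(batches) == 1  # 4/4/4 kept; 1/1/1 remainder dropped
        assert any("partial" in m for m in caplog.messages)

    def test_empty_class_rejected(self):
        with pytest.raises(ValueError):
            make_stratified_batches([], per_class=2, seed=0)


class TestDistances:
    def test_metric_identity_and_pythagoras(self):
        d = pairwise_distances(np.array([[0.0, 0.0], [3.0, 4.0]]))
        assert d[0, 0] == 0.0 and d[1, 1] == 0.0
        assert d[0, 1] == pytest.approx(5.0)

    def test_symmetry(self):
        rng = np.random.default_rng(0)
        d = pairwise_distances(rng.normal(size=(6, 3)))
        np.testing.assert_allclose(d, d.T)
        np.testing.assert_allclose(np.diag(d), 0.0)

    def test_ragged_input_rejected(self):
        with pytest.raises(ValueError):
            pairwise_distances([np.zeros(2), np.zeros(3)])


def _random_batch(rng, n_max=30, dim=4):
    n = int(rng.integers(6, n_max + 1))
    labels_arr = rng.choice([3, 4, 5], size=n)
    while len(set(labels_arr)) < 2:
        labels_arr = rng.choice([3, 4, 5], size=n)
    ids = [f"im{k:02d}" for k in range(n)]
    labels = dict(zip(ids, (int(l) for l in labels_arr)))
    feats = {i: rng.normal(size=dim) for i in ids}
    return PairedBatch(ids=ids, labels=labels), feats


class TestPairMining:
    def test_score4_anchor_yields_three_pairs(self):
        batch = PairedBatch(
            ids=["a3", "b3", "a4", "b4", "a5", "b5"],
            labels={"a3": 3, "b3": 3, "a4": 4, "b4": 4, "a5": 5, "b5": 5},
        )
        feats = {i: np.array([float(k)]) for k, i in enumerate(batch.ids)}
        paired = build_pairs(batch, feats, strategy="embedding")
        for anchor, expected in (("a4", 3), ("a3", 2), ("a5", 2)):
            got = [p for p in paired.pairs if p.anchor_id == anchor]
            assert len(got) == expected
        a4 = [p for p in paired.pairs if p.anchor_id == "a4"]
        assert sorted(p.kind for p in a4) == ["inter", "inter", "intra"]

    def test_matches_brute_force_oracle_on_50_random_batches(self):
        rng = np.random.default_rng(1234)
        for _ in range(50):
            batch, feats = _random_batch(rng)
            paired = build_pairs(batch, feats, strategy="embedding")
            got = sorted((p.anchor_id, p.partner_id, p.kind) for p in paired.pairs)
            ref = sorted(brute_force_pairs(batch.ids, batch.labels, feats))
            assert got == ref

    def test_inter_pairs_connect_adjacent_labels_only(self):
        rng = np.random.default_rng(99)
        for _ in range(20):
            batch, feats = _random_batch(rng)
            paired = build_pairs(batch, feats, strategy="raw")
            for p in paired.pairs:
                la, lp = batch.labels[p.anchor_id], batch.labels[p.partner_id]
                if p.kind == "inter":
                    assert abs(la - lp) == 1
                else:
                    assert la == lp

    def test_distance_ties_break_to_lowest_id(self):
        batch = PairedBatch(ids=["a", "b", "c", "d"],
                            labels={"a": 4, "b": 4, "c": 4, "d": 5})
        feats = {"a": np.zeros(2), "b": np.ones(2), "c": np.ones(2),
                 "d": np.zeros(2)}
        paired = build_pairs(batch, feats, strategy="embedding")
        intra_a = [p for p in paired.pairs
                   if p.anchor_id == "a" and p.kind == "intra"][0]
        assert intra_a.partner_id == "b"  # b and c tie at distance sqrt(2)

    def test_rigid_motion_of_feature_space_leaves_pairs_unchanged(self):
        rng = np.random.default_rng(5)
        batch, feats = _random_batch(rng, dim=3)
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        shift = rng.normal(size=3)
        moved = {i: q @ v + shift for i, v in feats.items()}
        a = build_pairs(batch, feats, strategy="embedding").pairs
        b = build_pairs(batch, moved, strategy="embedding").pairs
        assert a == b

    def test_singleton_class_skips_intra_with_warning(self, caplog):
        batch = PairedBatch(ids=["x4", "a5", "b5"],
                            labels={"x4": 4, "a5": 5, "b5": 5})
        feats = {i: np.array([float(k)]) for k, i in enumerate(batch.ids)}
        with caplog.at_level(logging.WARNING):
            paired = build_pairs(batch, feats, strategy="embedding")
        kinds = [p.kind for p in paired.pairs if p.anchor_id == "x4"]
        assert kinds == ["inter"]
        assert any("intra pair skipped" in m for m in caplog.messages)

    def test_random_strategy_pairs_every_anchor(self):
        rng = np.random.default_rng(6)
        batch, _ = _random_batch(rng)
        paired = build_pairs(batch, None, strategy="random", seed=3)
        assert len(paired.pairs) == len(batch.ids)
        again = build_pairs(batch, None, strategy="random", seed=3)
        assert paired.pairs == again.pairs
        for p in paired.pairs:
            assert p.anchor_id != p.partner_id

    def test_missing_features_rejected(self):
        batch = PairedBatch(ids=["a", "b"], labels={"a": 4, "b": 5})
        with pytest.raises(ValueError):
            build_pairs(batch, {"a": np.zeros(2)}, strategy="embedding")


class TestIntraInterToggle:
    def _paired(self):
        batch = PairedBatch(
            ids=["a3", "b3", "a4", "b4", "a5", "b5"],
            labels={"a3": 3, "b3": 3, "a4": 4, "b4": 4, "a5": 5, "b5": 5},
        )
        feats = {i: np.array([float(k)]) for k, i in enumerate(batch.ids)}
        return build_pairs(batch, feats, strategy="embedding")

    def test_include_is_identity(self):
        paired = self._paired()
        assert intra_inter_toggle(paired, True) is paired

    def test_exclude_removes_all_intra(self):
        filtered = intra_inter_toggle(self._paired(), False)
        assert all(p.kind == "inter" for p in filtered.pairs)
        a4 = [p for p in filtered.pairs if p.anchor_id == "a4"]
        assert len(a4) == 2


def test_pair_assignment_validation():
    with pytest.raises(ValueError):
        PairAssignment("a", "a", "intra")
    with pytest.raises(ValueError):
        PairAssignment("a", "b", "diagonal")
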