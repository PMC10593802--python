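"""Stratified batch partitioning and pair mining.

Training pairs are mined *within* stratified batches. For every image
(anchor) in a batch the embedding and raw-pixel strategies build

* one intra-class pair: the most *dissimilar* image of the same score
  (largest Euclidean distance), and
* one inter-class pair per adjacent score present in the batch: the most
  *similar* image of that score (smallest distance).

A score-4 anchor therefore yields three pairs (4 is adjacent to both 3 and
5); scores 3 and 5 yield two. Inter-class pairs never connect scores 3 and
5 directly — fine-grained contrast is only meaningful between neighbouring
scores. The random strategy pairs each anchor with a uniformly drawn batch
mate regardless of score (its pairs are labeled intra/inter by label
equality and may connect non-adjacent scores by construction).

Distance ties are broken toward the lexicographically smallest image id so
mining is deterministic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import squareform, pdist

from .data_prep import ImageRecord

logger = logging.getLogger(__name__)

__all__ = ["PairAssignment", "PairedBatch", "make_stratified_batches",
           "pairwise_distances", "build_pairs", "intra_inter_toggle"]


@dataclass(frozen=True)
class PairAssignment:
    anchor_id: str
    partner_id: str
    kind: str  # "intra" | "inter"

    def __post_init__(self):
        if self.kind not in ("intra", "inter"):
            raise ValueError(f"kind must be 'intra' or 'inter', got {self.kind!r}")
        if self.anchor_id == self.partner_id:
            raise ValueError("an image cannot be paired with itself")


@dataclass
class PairedBatch:
    """Image ids of one stratified batch plus the mined pair assignments."""

    ids: list[str]
    labels: dict[str, int]
    pairs: list[PairAssignment] = field(default_factory=list)

    @property
    def class_counts(self) -> dict[int, int]:
        counts: dict[int, int] = {}
        for i in self.ids:
            counts[self.labels[i]] = counts.get(self.labels[i], 0) + 1
        return counts

    def __len__(self) -> int:
        return len(self.ids)


def make_stratified_batches(records: list[ImageRecord], per_class: int,
                            seed: int = 0) -> list[PairedBatch]:
    """Randomly partition records into batches of ``per_class`` images per
    score class.

    Each image is used once per epoch. A trailing partial batch is kept
    only if every class it contains has at least two members (pair mining
    is ill-defined otherwise); else it is dropped with a warning.
    """
    if per_class < 1:
        raise ValueError("per_class must be >= 1")
    by_class: dict[int, list[str]] = {}
    labels = {}
    for r in records:
        if r.label is None:
            raise ValueError(f"record {r.id!r} has no label; relabel first")
        by_class.setdefault(r.label, []).append(r.id)
        labels[r.id] = r.label
    if any(len(v) == 0 for v in by_class.values()) or not by_class:
        raise ValueError("every class needs at least one image")
    rng = np.random.default_rng(seed)
    shuffled = {c: [ids[i] for i in rng.permutation(len(ids))]
                for c, ids in sorted(by_class.items())}
    n_batches = max(int(np.ceil(len(v) / per_class)) for v in shuffled.values())
    batches = []
    for k in range(n_batches):
        chunk = []
        counts = []
        for c, ids in shuffled.items():
            part = ids[k * per_class:(k + 1) * per_class]
            chunk.extend(part)
            counts.append(len(part))
        partial = any(c < per_class for c in counts)
        if partial and min(counts) < 2:
            if chunk:
                logger.warning("dropping partial batch of %d images "
                               "(a class has fewer than 2 members)", len(chunk))
            continue
        batches.append(PairedBatch(ids=chunk, labels={i: labels[i] for i in chunk}))
    return batches


def pairwise_distances(vectors: list[np.ndarray] | np.ndarray) -> np.ndarray:
    """Symmetric Euclidean distance matrix with a zero diagonal."""
    arr = np.asarray(vectors, dtype=float)
    if arr.ndim != 2:
        raise ValueError("vectors must all have the same length")
    if arr.shape[0] == 1:
        return np.zeros((1, 1))
    return squareform(pdist(arr, metric="euclidean"))


def _adjacent(label: int, present: set[int]) -> list[int]:
    return [l for l in (label - 1, label + 1) if l in present]


def build_pairs(batch: PairedBatch, features_by_id: dict[str, np.ndarray] | None,
                strategy: str = "embedding", seed: int = 0) -> PairedBatch:
    """Mine pair assignments for every anchor in the batch.

    ``strategy`` is ``"embedding"`` (distances between backbone embeddings),
    ``"raw"`` (distances between flattened pixels), or ``"random"``.
    Embedding and raw share the same mining rule and differ only in the
    feature space supplied through ``features_by_id``.
    """
    if strategy not in ("embedding", "raw", "random"):
        raise ValueError(f"unknown strategy {strategy!r}")
    ids = sorted(batch.ids)  # sorted order fixes deterministic tie-breaking
    labels = batch.labels
    pairs: list[PairAssignment] = []

    if strategy == "random":
        rng = np.random.default_rng(seed)
        for anchor in ids:
            others = [i for i in ids if i != anchor]
            partner = others[rng.integers(len(others))]
            kind = "intra" if labels[partner] == labels[anchor] else "inter"
            pairs.append(PairAssignment(anchor, partner, kind))
        return PairedBatch(ids=batch.ids, labels=labels, pairs=pairs)

    missing = [i for i in ids if i not in (features_by_id or {})]
    if missing:
        raise ValueError(f"features missing for ids: {missing[:5]}")
    feats = np.asarray([features_by_id[i] for i in ids], dtype=float)
    if feats.ndim != 2:
        raise ValueError("feature vectors must share one length")
    dist = pairwise_distances(feats)
    present = set(labels.values())

    for a, anchor in enumerate(ids):
        lab = labels[anchor]
        same = [b for b, i in enumerate(ids) if labels[i] == lab and i != anchor]
        if same:
            dmax = max(dist[a, b] for b in same)
            best = min(b for b in same if dist[a, b] == dmax)  # tie -> smallest id
            pairs.append(PairAssignment(anchor, ids[best], "intra"))
        else:
            logger.warning("anchor %s: single member of class %d in batch; "
                           "intra pair skipped", anchor, lab)
        for adj in _adjacent(lab, present):
            cand = [b for b, i in enumerate(ids) if labels[i] == adj]
            dmin = min(dist[a, b] for b in cand)
            best = min(b for b in cand if dist[a, b] == dmin)
            pairs.append(PairAssignment(anchor, ids[best], "inter"))
    return PairedBatch(ids=batch.ids, labels=labels, pairs=pairs)


def intra_inter_toggle(batch_pairs: PairedBatch, include_intra: bool) -> PairedBatch:
    """Optionally drop intra-class pairs (inter-only training variant)."""
    if include_intra:
        return batch_pairs
    kept = [p for p in batch_pairs.pairs if p.kind != "intra"]
    return PairedBatch(ids=batch_pairs.ids, labels=batch_pairs.labels, pairs=kept)
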