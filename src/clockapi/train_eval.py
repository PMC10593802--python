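"""Training schedules, inference, splitting, and evaluation metrics.

Two schedules are supported for training the pairwise-interaction scorer on
top of a finetuned backbone:

* ``frozen``  — the backbone stays fixed; only the interaction MLP and the
  shared classifier learn (100 epochs by default);
* ``gradual`` — the backbone stays fixed for ``frozen_epochs`` epochs while
  the interaction block and classifier settle, then all components train
  jointly for the remaining epochs.

Inference never uses the interaction block: a single image is embedded by
the backbone and classified directly by the shared classifier, exactly the
conventional CNN pipeline but with contrastively trained weights.

Records handed to :func:`train`, :func:`evaluate` and
:meth:`ApiNetModel.predict` are expected resized to 256x256 with pixels in
[0, 1] and relabeled; standardization (and optional augmentation of the
training split) happens inside.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.metrics import accuracy_score, precision_recall_fscore_support

from .api_core import ApiParams, forward_embeddings
from .backbone import Backbone
from .data_prep import AugmentConfig, ImageRecord, augment, standardize, to_nchw
from .losses import LabelInfo, LossConfig, total_loss
from .nn import Adam, Tensor
from .pair_batching import build_pairs, intra_inter_toggle, make_stratified_batches

logger = logging.getLogger(__name__)

__all__ = ["TrainConfig", "SplitSpec", "MetricsReport", "ApiNetModel",
           "stratified_split", "train", "train_conventional", "evaluate",
           "repeated_runs", "ConventionalModel", "warm_start_classifier"]


@dataclass
class TrainConfig:
    """Hyperparameters of the pairwise training stage.

    Defaults follow the operating point used throughout: Adam with
    lr 5e-5, 100 epochs, stratified batches of 20 images per class
    (batch size 60 for the three-class task), λ=1, ε=0.005.
    """

    lr: float = 5e-5
    epochs: int = 100
    per_class: int = 20
    freeze_mode: str = "frozen"  # "frozen" | "gradual"
    frozen_epochs: int = 10      # gradual only
    seed: int = 0
    loss: LossConfig = field(default_factory=LossConfig)
    strategy: str = "embedding"  # "embedding" | "raw" | "random"
    include_intra: bool = True
    augment: AugmentConfig | None = None

    def __post_init__(self):
        if self.freeze_mode not in ("frozen", "gradual"):
            raise ValueError("freeze_mode must be 'frozen' or 'gradual'")


@dataclass
class SplitSpec:
    fractions: tuple[float, float, float] = (0.50, 0.25, 0.25)
    seed: int = 0

    def __post_init__(self):
        if abs(sum(self.fractions) - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")
        if any(f < 0 for f in self.fractions):
            raise ValueError("split fractions must be non-negative")


@dataclass
class MetricsReport:
    accuracy: float
    f1: float
    precision: float
    recall: float
    per_class: dict[int, dict[str, float]]
    averaging: str = "weighted"

    def as_dict(self) -> dict[str, float]:
        return {"accuracy": self.accuracy, "f1": self.f1,
                "precision": self.precision, "recall": self.recall}


def stratified_split(records: list[ImageRecord], spec: SplitSpec
                     ) -> tuple[list[ImageRecord], list[ImageRecord], list[ImageRecord]]:
    """Per-class random partition into train/validation/test."""
    rng = np.random.default_rng(spec.seed)
    by_class: dict[int, list[ImageRecord]] = {}
    for r in records:
        key = r.label if r.label is not None else r.raw_score
        by_class.setdefault(key, []).append(r)
    train_r, val_r, test_r = [], [], []
    f_train, f_val, _ = spec.fractions
    for _, group in sorted(by_class.items()):
        group = sorted(group, key=lambda r: r.id)
        order = rng.permutation(len(group))
        n_train = int(round(f_train * len(group)))
        n_val = int(round(f_val * len(group)))
        for pos, idx in enumerate(order):
            if pos < n_train:
                train_r.append(group[idx])
            elif pos < n_train + n_val:
                val_r.append(group[idx])
            else:
                test_r.append(group[idx])
    return train_r, val_r, test_r


class ApiNetModel:
    """Backbone + interaction block + shared classifier."""

    def __init__(self, backbone: Backbone, num_classes: int = 3,
                 classes: tuple[int, ...] = (3, 4, 5), hidden: int | None = None,
                 dropout_rate: float = 0.5, symmetric: bool = False, seed: int = 0):
        if len(classes) != num_classes:
            raise ValueError("classes must list one score per class index")
        self.backbone = backbone
        self.classes = list(classes)
        self.api = ApiParams(backbone.spec.embedding_dim, num_classes=num_classes,
                             hidden=hidden, dropout_rate=dropout_rate,
                             symmetric=symmetric, seed=seed)

    def class_index(self, label: int) -> int:
        return self.classes.index(label)

    def _probs_from_embeddings(self, emb: np.ndarray) -> np.ndarray:
        W, b = self.api.classifier.W.data, self.api.classifier.b.data
        z = emb @ W + b
        z = z - z.max(axis=1, keepdims=True)
        e = np.exp(z)
        return e / e.sum(axis=1, keepdims=True)

    def predict_batch(self, records: list[ImageRecord]) -> tuple[np.ndarray, np.ndarray]:
        """Labels and probability rows for resized [0,1] records."""
        std = [standardize(r) for r in records]
        emb = self.backbone.embed_array(to_nchw(std))
        probs = self._probs_from_embeddings(emb)
        labels = np.array([self.classes[i] for i in probs.argmax(axis=1)])
        return labels, probs

    def predict(self, image: ImageRecord) -> tuple[int, np.ndarray]:
        """Single-image inference: backbone embedding -> shared classifier.

        The interaction block is not involved at test time.
        """
        labels, probs = self.predict_batch([image])
        return int(labels[0]), probs[0]

    def parameters(self):
        return self.backbone.parameters() + self.api.parameters()

    def state_arrays(self):
        return [p.data.copy() for p in self.parameters()]

    def load_state_arrays(self, arrays):
        for p, a in zip(self.parameters(), arrays, strict=True):
            p.data = a.copy()

    def save(self, path) -> None:
        np.savez(path, *[p.data for p in self.parameters()],
                 embedding_dim=self.backbone.spec.embedding_dim,
                 num_classes=self.api.num_classes,
                 classes=np.array(self.classes),
                 hidden=self.api.mlp1.W.data.shape[1],
                 dropout_rate=self.api.dropout.rate,
                 symmetric=self.api.symmetric)

    @classmethod
    def load(cls, path) -> "ApiNetModel":
        from .backbone import BackboneSpec
        with np.load(path) as z:
            model = cls(
                Backbone(BackboneSpec(embedding_dim=int(z["embedding_dim"]))),
                num_classes=int(z["num_classes"]),
                classes=tuple(int(c) for c in z["classes"]),
                hidden=int(z["hidden"]),
                dropout_rate=float(z["dropout_rate"]),
                symmetric=bool(z["symmetric"]),
            )
            arrays = [z[f"arr_{i}"] for i in range(len(model.parameters()))]
        model.load_state_arrays(arrays)
        return model


class ConventionalModel:
    """The non-contrastive baseline: backbone -> linear head -> softmax."""

    def __init__(self, backbone: Backbone, num_classes: int = 3,
                 classes: tuple[int, ...] = (3, 4, 5), seed: int = 0):
        from .nn import Linear
        self.backbone = backbone
        self.classes = list(classes)
        self.head = Linear(backbone.spec.embedding_dim, num_classes,
                           np.random.default_rng(seed))

    def _probs_from_embeddings(self, emb: np.ndarray) -> np.ndarray:
        z = emb @ self.head.W.data + self.head.b.data
        z = z - z.max(axis=1, keepdims=True)
        e = np.exp(z)
        return e / e.sum(axis=1, keepdims=True)

    def predict_batch(self, records):
        std = [standardize(r) for r in records]
        emb = self.backbone.embed_array(to_nchw(std))
        probs = self._probs_from_embeddings(emb)
        labels = np.array([self.classes[i] for i in probs.argmax(axis=1)])
        return labels, probs

    def predict(self, image):
        labels, probs = self.predict_batch([image])
        return int(labels[0]), probs[0]


def _epoch_views(records, cfg: TrainConfig, epoch: int):
    """This epoch's training views: optional online augmentation, then
    standardization. Returns (standardized records, raw [0,1] records)."""
    if cfg.augment is not None:
        base = cfg.augment
        views = [augment(r, replace(base, seed=base.seed + 7919 * epoch + k))
                 for k, r in enumerate(records)]
    else:
        views = records
    return [standardize(r) for r in views], views


class _ValCache:
    """Validation embeddings, reused across epochs while the backbone is
    frozen (they only change when backbone parameters move)."""

    def __init__(self, val_records):
        self.records = val_records
        self.truth = np.array([r.label for r in val_records]) if val_records else None
        self.std = [standardize(r) for r in val_records] if val_records else None
        self.emb = None

    def accuracy(self, model, backbone_may_have_moved: bool) -> float:
        if not self.records:
            return float("nan")
        if self.emb is None or backbone_may_have_moved:
            self.emb = model.backbone.embed_array(to_nchw(self.std))
        probs = model._probs_from_embeddings(self.emb)
        labels = np.array([model.classes[i] for i in probs.argmax(axis=1)])
        return float((labels == self.truth).mean())


def warm_start_classifier(model: ApiNetModel, train_records: list[ImageRecord],
                          steps: int = 200, lr: float = 3e-3,
                          seed: int = 0) -> ApiNetModel:
    """Fit the shared classifier on raw embeddings before pairwise training.

    Pairwise training only ever shows the classifier gate-scaled attentive
    features, while inference applies it to plain embeddings; anchoring the
    classifier on the raw embedding distribution first keeps the deployed
    path consistent. Full-batch Adam on the frozen-backbone embeddings.
    """
    std = [standardize(r) for r in train_records]
    emb = model.backbone.embed_array(to_nchw(std))
    y = np.array([model.class_index(r.label) for r in train_records])
    onehot = np.eye(model.api.num_classes)[y]
    opt = Adam(model.api.classifier_parameters(), lr=lr)
    for _ in range(steps):
        probs = model.api.classifier(Tensor(emb)).softmax(axis=1)
        loss = -(Tensor(onehot) * probs.log()).sum(axis=1).mean()
        opt.zero_grad()
        loss.backward()
        opt.step()
    return model


def train(model: ApiNetModel, train_records: list[ImageRecord],
          val_records: list[ImageRecord], cfg: TrainConfig
          ) -> tuple[ApiNetModel, pd.DataFrame]:
    """Pairwise contrastive training with the configured schedule.

    Per epoch: stratified batches are drawn, pairs are mined with the
    configured strategy (embeddings recomputed with the current backbone in
    evaluation mode), every assignment is pushed through the interaction
    block, and the combined cross-entropy + ranking loss is minimized with
    Adam. The best-validation-accuracy checkpoint is restored at the end.
    Returns the model and a log frame with per-epoch loss components,
    validation accuracy and a backbone parameter checksum.
    """
    if not train_records:
        raise ValueError("empty training split")
    if any(r.label is None for r in train_records):
        raise ValueError("training records must be relabeled first")

    rng = np.random.default_rng(cfg.seed)
    if cfg.freeze_mode == "gradual":
        model.backbone.set_trainable(False)

    opt = Adam(model.parameters(), lr=cfg.lr)
    log_rows = []
    best = (-np.inf, None)
    emb_cache: dict[str, np.ndarray] | None = None
    val_cache = _ValCache(val_records)

    for epoch in range(1, cfg.epochs + 1):
        if cfg.freeze_mode == "gradual" and epoch == cfg.frozen_epochs + 1:
            model.backbone.set_trainable(True)
        backbone_trainable = model.backbone.spec.trainable

        std_records, raw_records = _epoch_views(train_records, cfg, epoch)
        by_id = {r.id: r for r in std_records}
        raw_by_id = {r.id: r for r in raw_records}

        # embeddings serve both pair mining (embedding strategy) and, when the
        # backbone is frozen, the API forward inputs; cache them across epochs
        # whenever neither the backbone nor the images change. With a
        # trainable backbone they go stale after every step and are instead
        # recomputed per batch below.
        if not backbone_trainable and (cfg.augment is not None or emb_cache is None):
            emb = model.backbone.embed_array(to_nchw(std_records))
            emb_cache = {r.id: emb[i] for i, r in enumerate(std_records)}

        batches = make_stratified_batches(std_records, cfg.per_class,
                                          seed=int(rng.integers(2**31)))
        ep_L = ep_CE = ep_RK = 0.0
        n_pairs_total = 0
        for batch in batches:
            if cfg.strategy == "embedding":
                if emb_cache is not None:
                    feats = {i: emb_cache[i] for i in batch.ids}
                else:  # backbone moving: fresh eval-mode embeddings per batch
                    barr = model.backbone.embed_array(
                        to_nchw([by_id[i] for i in batch.ids]))
                    feats = {i: barr[k] for k, i in enumerate(batch.ids)}
            elif cfg.strategy == "raw":
                feats = {i: raw_by_id[i].pixels.ravel() for i in batch.ids}
            else:
                feats = None
            paired = build_pairs(batch, feats, strategy=cfg.strategy,
                                 seed=int(rng.integers(2**31)))
            paired = intra_inter_toggle(paired, cfg.include_intra)
            if not paired.pairs:
                continue

            pos = {rid: k for k, rid in enumerate(batch.ids)}
            a_idx = np.array([pos[p.anchor_id] for p in paired.pairs])
            b_idx = np.array([pos[p.partner_id] for p in paired.pairs])

            if backbone_trainable:
                x = Tensor(to_nchw([by_id[i] for i in batch.ids]))
                E = model.backbone.forward(x)
                n = len(batch.ids)
                S1 = np.zeros((len(a_idx), n), dtype=np.float32)
                S1[np.arange(len(a_idx)), a_idx] = 1.0
                S2 = np.zeros((len(b_idx), n), dtype=np.float32)
                S2[np.arange(len(b_idx)), b_idx] = 1.0
                e1, e2 = Tensor(S1) @ E, Tensor(S2) @ E
            else:
                if cfg.strategy == "embedding":
                    batch_emb = np.array([feats[i] for i in batch.ids])
                else:
                    batch_emb = np.array([emb_cache[i] for i in batch.ids])
                e1, e2 = Tensor(batch_emb[a_idx]), Tensor(batch_emb[b_idx])

            c1 = np.array([model.class_index(batch.labels[p.anchor_id])
                           for p in paired.pairs])
            c2 = np.array([model.class_index(batch.labels[p.partner_id])
                           for p in paired.pairs])
            labels = LabelInfo(c1, c2, num_classes=model.api.num_classes)
            preds = forward_embeddings(e1, e2, model.api, training=True, rng=rng)
            lb = total_loss(preds, labels, cfg.loss)
            opt.zero_grad()
            lb.L.backward()
            opt.step()
            if backbone_trainable:
                emb_cache = None  # parameters moved; cached embeddings stale
            L, CE, RK = lb.floats()
            ep_L += L * len(paired.pairs)
            ep_CE += CE * len(paired.pairs)
            ep_RK += RK * len(paired.pairs)
            n_pairs_total += len(paired.pairs)

        val_acc = val_cache.accuracy(model, backbone_may_have_moved=backbone_trainable)
        denom = max(n_pairs_total, 1)
        log_rows.append({
            "epoch": epoch, "L": ep_L / denom, "L_CE": ep_CE / denom,
            "L_RK": ep_RK / denom, "val_accuracy": val_acc,
            "n_pairs": n_pairs_total,
            "backbone_checksum": model.backbone.checksum(),
        })
        if val_records and val_acc > best[0]:
            best = (val_acc, model.state_arrays())

    if best[1] is not None:
        model.load_state_arrays(best[1])
    return model, pd.DataFrame(log_rows)


def train_conventional(model: ConventionalModel, train_records, val_records,
                       cfg: TrainConfig) -> tuple[ConventionalModel, pd.DataFrame]:
    """Standard supervised training of backbone+head on single images with
    plain cross-entropy — the non-contrastive comparator, run with the same
    optimizer, schedule and budget as :func:`train`."""
    if not train_records:
        raise ValueError("empty training split")
    rng = np.random.default_rng(cfg.seed)
    if cfg.freeze_mode == "gradual":
        model.backbone.set_trainable(False)
    params = model.backbone.parameters() + model.head.parameters()
    opt = Adam(params, lr=cfg.lr)
    classes = model.classes
    log_rows = []
    best = (-np.inf, None)
    emb_cache = None
    val_cache = _ValCache(val_records)
    batch_size = cfg.per_class * len(classes)

    for epoch in range(1, cfg.epochs + 1):
        if cfg.freeze_mode == "gradual" and epoch == cfg.frozen_epochs + 1:
            model.backbone.set_trainable(True)
        backbone_trainable = model.backbone.spec.trainable
        std_records, _ = _epoch_views(train_records, cfg, epoch)
        y = np.array([classes.index(r.label) for r in std_records])
        if not backbone_trainable:
            if emb_cache is None or cfg.augment is not None:
                emb_cache = model.backbone.embed_array(to_nchw(std_records))
            X = emb_cache
        order = rng.permutation(len(std_records))
        ep_loss, n_seen = 0.0, 0
        for start in range(0, len(order), batch_size):
            idx = order[start:start + batch_size]
            onehot = np.zeros((len(idx), len(classes)), dtype=np.float32)
            onehot[np.arange(len(idx)), y[idx]] = 1.0
            if backbone_trainable:
                xt = Tensor(to_nchw([std_records[i] for i in idx]))
                emb_t = model.backbone.forward(xt)
                emb_cache = None
            else:
                emb_t = Tensor(X[idx])
            probs = model.head(emb_t).softmax(axis=1)
            loss = -(Tensor(onehot) * probs.log()).sum(axis=1).mean()
            opt.zero_grad()
            loss.backward()
            opt.step()
            ep_loss += float(loss.data) * len(idx)
            n_seen += len(idx)
        val_acc = val_cache.accuracy(model, backbone_may_have_moved=backbone_trainable)
        log_rows.append({"epoch": epoch, "L": ep_loss / max(n_seen, 1),
                         "val_accuracy": val_acc,
                         "backbone_checksum": model.backbone.checksum()})
        if val_records and val_acc > best[0]:
            best = (val_acc, [p.data.copy() for p in params])
    if best[1] is not None:
        for p, a in zip(params, best[1], strict=True):
            p.data = a.copy()
    return model, pd.DataFrame(log_rows)


def evaluate(model, test_records: list[ImageRecord]) -> MetricsReport:
    """Accuracy plus weighted-average F1/precision/recall, with per-class
    breakdown. With weighted averaging, recall equals accuracy — kept as a
    self-check invariant."""
    if not test_records:
        raise ValueError("empty test set")
    pred_labels, _ = model.predict_batch(test_records)
    truth = np.array([r.label for r in test_records])
    acc = accuracy_score(truth, pred_labels)
    prec, rec, f1, _ = precision_recall_fscore_support(
        truth, pred_labels, average="weighted", zero_division=0)
    p_c, r_c, f_c, support = precision_recall_fscore_support(
        truth, pred_labels, labels=sorted(set(truth)), average=None, zero_division=0)
    per_class = {int(lab): {"precision": float(p), "recall": float(r),
                            "f1": float(f), "support": int(s)}
                 for lab, p, r, f, s in zip(sorted(set(truth)), p_c, r_c, f_c, support)}
    return MetricsReport(accuracy=float(acc), f1=float(f1), precision=float(prec),
                         recall=float(rec), per_class=per_class)


def repeated_runs(pipeline, n_runs: int, seeds: list[int] | None = None
                  ) -> pd.DataFrame:
    """Run ``pipeline(seed) -> MetricsReport`` repeatedly; return per-run
    rows plus mean and standard-deviation summary rows."""
    if n_runs < 2:
        raise ValueError("n_runs must be >= 2")
    seeds = list(seeds) if seeds is not None else list(range(n_runs))
    if len(seeds) != n_runs:
        raise ValueError("need one seed per run")
    rows = []
    for s in seeds:
        rep = pipeline(s)
        rows.append({"run_seed": s, **rep.as_dict()})
    df = pd.DataFrame(rows)
    metric_cols = ["accuracy", "f1", "precision", "recall"]
    summary = pd.DataFrame([
        {"run_seed": "mean", **df[metric_cols].mean().to_dict()},
        {"run_seed": "sd", **df[metric_cols].std(ddof=1).to_dict()},
    ])
    return pd.concat([df, summary], ignore_index=True)
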