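"""Desk-scale reference experiments on synthetic clock drawings.

These helpers wire the full pipeline together at a size a laptop CPU
handles in minutes: generate a stratified synthetic dataset, split it
50/25/25, finetune the tiny backbone, train the pairwise-interaction
scorer with the backbone frozen, and train the conventional comparator
(identical backbone start, plain cross-entropy on single images, same
optimizer budget).

The desk defaults — 50 images per class, 40 finetuning epochs, a
classifier warm-start on raw embeddings, then 300 frozen-backbone pairwise
epochs at lr 3e-3 — are sized for the from-scratch tiny CNN; see the
methods note for the reasoning.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import synthclock
from .backbone import Backbone, BackboneSpec, finetune_backbone
from .data_prep import standardize
from .train_eval import (ApiNetModel, ConventionalModel, MetricsReport,
                         SplitSpec, TrainConfig, evaluate, stratified_split,
                         train, train_conventional, warm_start_classifier)

__all__ = ["DeskRunResult", "desk_run", "comparative_runs"]


@dataclass
class DeskRunResult:
    model: ApiNetModel
    conventional: ConventionalModel
    train_accuracy: float
    api_report: MetricsReport
    conventional_report: MetricsReport
    train_records: list
    test_records: list


def desk_run(seed: int, n_per_class: int = 50, finetune_epochs: int = 40,
             finetune_lr: float = 3e-3, api_epochs: int = 300,
             api_lr: float = 3e-3, per_class: int = 20,
             embedding_dim: int = 64) -> DeskRunResult:
    """One complete synthetic-data experiment at the given seed."""
    records = synthclock.generate_records(n_per_class, seed=seed)
    tr, va, te = stratified_split(records, SplitSpec(seed=seed))
    std_tr = [standardize(r) for r in tr]

    bb = Backbone(BackboneSpec(embedding_dim=embedding_dim), seed=seed)
    finetune_backbone(bb, std_tr, epochs=finetune_epochs, lr=finetune_lr,
                      seed=seed, batch_size=15)
    finetuned = bb.state_arrays()
    bb.set_trainable(False)

    cfg = TrainConfig(epochs=api_epochs, per_class=per_class, lr=api_lr, seed=seed)
    model = ApiNetModel(bb, seed=seed)
    warm_start_classifier(model, tr, seed=seed)
    model, _ = train(model, tr, va, cfg)
    labels, _ = model.predict_batch(tr)
    train_acc = float((labels == np.array([r.label for r in tr])).mean())
    api_report = evaluate(model, te)

    bb2 = Backbone(BackboneSpec(embedding_dim=embedding_dim), seed=seed)
    bb2.load_state_arrays(finetuned)
    bb2.set_trainable(False)
    conv = ConventionalModel(bb2, seed=seed)
    conv, _ = train_conventional(conv, tr, va, cfg)
    conv_report = evaluate(conv, te)

    return DeskRunResult(model=model, conventional=conv,
                         train_accuracy=train_acc, api_report=api_report,
                         conventional_report=conv_report,
                         train_records=tr, test_records=te)


def comparative_runs(seeds: list[int], **kwargs) -> dict:
    """Mean test accuracy of the pairwise-trained scorer vs the
    conventional comparator over several seeds."""
    api_accs, conv_accs, train_accs = [], [], []
    for s in seeds:
        res = desk_run(s, **kwargs)
        api_accs.append(res.api_report.accuracy)
        conv_accs.append(res.conventional_report.accuracy)
        train_accs.append(res.train_accuracy)
    return {
        "api_mean_test_accuracy": float(np.mean(api_accs)),
        "conventional_mean_test_accuracy": float(np.mean(conv_accs)),
        "api_test_accuracies": api_accs,
        "conventional_test_accuracies": conv_accs,
        "train_accuracies": train_accs,
    }
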