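"""Attentive Pairwise Interaction (API) forward computation.

Given the embeddings x_1, x_2 of two visually similar clock drawings, the
block computes

* a mutual vector  x_m = MLP([x_1; x_2])  carrying contrastive cues,
* gate vectors     g_i = sigmoid(x_m ⊙ x_i),
* four attentive features via residual attention:
      x_i^self  = x_i + x_i ⊙ g_i
      x_1^other = x_1 + x_1 ⊙ g_2,   x_2^other = x_2 + x_2 ⊙ g_1,
* and four class-probability vectors p_i^j = softmax(W x_i^j + b) from a
  single shared classifier.

The mutual MLP is two affine maps with ReLU and dropout in between
(2d -> hidden -> d, hidden defaulting to d). Plain concatenation makes the
mutual map order-dependent; an optional symmetrized mode averages both
concatenation orders so that swapping the pair exactly swaps the outputs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .backbone import Backbone, eval_mode
from .data_prep import ImageRecord, to_nchw
from .nn import Dropout, Linear, Tensor, concat

__all__ = [
    "ApiParams", "PredictionQuad", "AttentiveQuad",
    "compute_mutual", "compute_gates", "compute_attentive", "classify",
    "forward_embeddings", "forward_pair",
]


@dataclass
class PredictionQuad:
    """The four class-probability vectors of one batch of pairs."""

    p_self_1: Tensor
    p_self_2: Tensor
    p_other_1: Tensor
    p_other_2: Tensor

    def numpy(self) -> dict[str, np.ndarray]:
        return {k: getattr(self, k).data for k in
                ("p_self_1", "p_self_2", "p_other_1", "p_other_2")}


@dataclass
class AttentiveQuad:
    x_self_1: Tensor
    x_self_2: Tensor
    x_other_1: Tensor
    x_other_2: Tensor


class ApiParams:
    """Parameters of the mutual MLP and the shared classifier."""

    def __init__(self, embedding_dim: int, num_classes: int = 3,
                 hidden: int | None = None, dropout_rate: float = 0.5,
                 symmetric: bool = False, seed: int = 0):
        rng = np.random.default_rng(seed)
        hidden = embedding_dim if hidden is None else hidden
        self.embedding_dim = embedding_dim
        self.num_classes = num_classes
        self.symmetric = symmetric
        self.mlp1 = Linear(2 * embedding_dim, hidden, rng)
        self.mlp2 = Linear(hidden, embedding_dim, rng)
        self.dropout = Dropout(dropout_rate)
        self.classifier = Linear(embedding_dim, num_classes, rng)

    def parameters(self):
        return (self.mlp1.parameters() + self.mlp2.parameters()
                + self.classifier.parameters())

    def api_parameters(self):
        return self.mlp1.parameters() + self.mlp2.parameters()

    def classifier_parameters(self):
        return self.classifier.parameters()


def _as_batch(x) -> Tensor:
    if isinstance(x, Tensor):
        return x if x.ndim == 2 else x.reshape(1, -1)
    a = np.asarray(x, dtype=np.float64)
    return Tensor(a if a.ndim == 2 else a[None, :])


def compute_mutual(x1, x2, params: ApiParams, training: bool = False,
                   rng: np.random.Generator | None = None) -> Tensor:
    """Mutual vector x_m = MLP([x1; x2]); dropout only when training."""
    x1, x2 = _as_batch(x1), _as_batch(x2)
    if x1.shape[1] != x2.shape[1]:
        raise ValueError(f"embedding lengths differ: {x1.shape[1]} vs {x2.shape[1]}")
    rng = rng or np.random.default_rng(0)

    def mlp(a: Tensor, b: Tensor) -> Tensor:
        h = params.mlp1(concat([a, b], axis=1)).relu()
        h = params.dropout(h, training, rng)
        return params.mlp2(h)

    if params.symmetric:
        return (mlp(x1, x2) + mlp(x2, x1)) * 0.5
    return mlp(x1, x2)


def compute_gates(x_m, x1, x2) -> tuple[Tensor, Tensor]:
    """g_i = sigmoid(x_m ⊙ x_i), elementwise; values strictly in (0, 1)."""
    x_m, x1, x2 = _as_batch(x_m), _as_batch(x1), _as_batch(x2)
    return (x_m * x1).sigmoid(), (x_m * x2).sigmoid()


def compute_attentive(x1, x2, g1, g2) -> AttentiveQuad:
    """Residual attention: each embedding enhanced by its own gate (self)
    and by the partner's gate (other)."""
    x1, x2, g1, g2 = map(_as_batch, (x1, x2, g1, g2))
    return AttentiveQuad(
        x_self_1=x1 + x1 * g1,
        x_self_2=x2 + x2 * g2,
        x_other_1=x1 + x1 * g2,
        x_other_2=x2 + x2 * g1,
    )


def classify(x, params: ApiParams) -> Tensor:
    """softmax(W x + b) with the single shared classifier."""
    return params.classifier(_as_batch(x)).softmax(axis=1)


def forward_embeddings(e1, e2, params: ApiParams, training: bool = False,
                       rng: np.random.Generator | None = None) -> PredictionQuad:
    """Full API block on a batch of embedding pairs."""
    e1, e2 = _as_batch(e1), _as_batch(e2)
    x_m = compute_mutual(e1, e2, params, training=training, rng=rng)
    g1, g2 = compute_gates(x_m, e1, e2)
    quad = compute_attentive(e1, e2, g1, g2)
    return PredictionQuad(
        p_self_1=classify(quad.x_self_1, params),
        p_self_2=classify(quad.x_self_2, params),
        p_other_1=classify(quad.x_other_1, params),
        p_other_2=classify(quad.x_other_2, params),
    )


def forward_pair(img1: ImageRecord, img2: ImageRecord, backbone: Backbone,
                 params: ApiParams, training: bool = False,
                 rng: np.random.Generator | None = None) -> PredictionQuad:
    """backbone -> API block -> classifier on one preprocessed image pair."""
    for img in (img1, img2):
        if img.pixels.shape != (256, 256, 3):
            raise ValueError(f"image {img.id!r} is not preprocessed to 256x256x3")
    if training:
        x = Tensor(to_nchw([img1, img2]))
        emb = backbone.forward(x)
        # keep the graph: select rows via constant selector matrices
        sel1 = Tensor(np.array([[1.0, 0.0]], dtype=np.float32))
        sel2 = Tensor(np.array([[0.0, 1.0]], dtype=np.float32))
        e1, e2 = sel1 @ emb, sel2 @ emb
    else:
        with eval_mode(backbone):
            arr = backbone.embed_array(to_nchw([img1, img2]))
        e1, e2 = Tensor(arr[0:1]), Tensor(arr[1:2])
    return forward_embeddings(e1, e2, params, training=training, rng=rng)
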