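"""CNN feature extractors for clock drawings.

A backbone is a convolutional network with its classification head removed:
it maps a preprocessed 256x256x3 image to a d-dimensional embedding (global
average pooling of the last convolutional feature map — the standard cut
point for all common architectures, and the form the pairwise interaction
block expects).

The built-in ``tinycnn`` needs no downloaded weights: an initial 4x average
pool takes 256 px to 64 px, followed by three stride-2 3x3 convolution
blocks and global average pooling. The registry accepts other architecture
names so externally provided feature extractors can be plugged in, but only
``tinycnn`` ships with the package.
"""

from __future__ import annotations

import logging
from contextlib import contextmanager
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .data_prep import ImageRecord, to_nchw
from .nn import Adam, Conv2d, Linear, Tensor, avg_pool2d, global_avg_pool

logger = logging.getLogger(__name__)

_EVAL_BATCH = 32  # embed in chunks to bound im2col scratch memory


@dataclass
class BackboneSpec:
    """Architecture choice and trainability state."""

    architecture_name: str = "tinycnn"
    embedding_dim: int = 64
    pretrained: bool = False
    trainable: bool = True


class TinyCNN:
    """4-block convolutional feature extractor, embedding dim configurable.

    A 2x average pool (256 -> 128 px) precedes four stride-2 3x3
    convolutions (16, 32, 64, d channels), leaving an 8x8 feature map that
    is globally average-pooled into the embedding. The light initial
    pooling keeps enough spatial resolution for the subtle score-4-vs-5
    cues (a few pixels of number jitter, a few degrees of hand angle)
    while staying CPU-affordable.
    """

    def __init__(self, embedding_dim: int, rng: np.random.Generator):
        widths = [16, 32, 64, embedding_dim]
        self.convs = []
        in_ch = 3
        for w in widths:
            self.convs.append(Conv2d(in_ch, w, rng, kernel=3, stride=2, pad=1))
            in_ch = w
        self.embedding_dim = embedding_dim

    def forward(self, x: Tensor, return_fmap: bool = False):
        h = avg_pool2d(x, 2)
        for conv in self.convs:
            h = conv(h).relu()
        pooled = global_avg_pool(h)
        return (pooled, h) if return_fmap else pooled

    def parameters(self):
        return [p for conv in self.convs for p in conv.parameters()]


class Backbone:
    """A feature-extractor with its trainability switch and parameter I/O."""

    def __init__(self, spec: BackboneSpec, seed: int = 0):
        if spec.architecture_name != "tinycnn":
            raise ValueError(
                f"architecture {spec.architecture_name!r} is not bundled with this "
                "package; construct a Backbone subclass around your own feature "
                "extractor, or use 'tinycnn'"
            )
        self.spec = spec
        self.net = TinyCNN(spec.embedding_dim, np.random.default_rng(seed))
        self.finetune_loss_log: list[float] = []
        self.set_trainable(spec.trainable)

    # -- forward paths --------------------------------------------------------
    def forward(self, x: Tensor, return_fmap: bool = False):
        return self.net.forward(x, return_fmap=return_fmap)

    def embed_array(self, images: np.ndarray) -> np.ndarray:
        """Evaluation-mode embeddings for an (N, 3, H, W) batch; no graph."""
        outs = []
        with eval_mode(self):
            for start in range(0, images.shape[0], _EVAL_BATCH):
                chunk = Tensor(images[start:start + _EVAL_BATCH])
                outs.append(self.net.forward(chunk).data)
        return np.concatenate(outs, axis=0)

    def parameters(self):
        return self.net.parameters()

    def set_trainable(self, trainable: bool) -> "Backbone":
        self.spec.trainable = trainable
        for p in self.parameters():
            p.trainable = trainable
            p.requires_grad = trainable
        return self

    def checksum(self) -> float:
        """Order-sensitive parameter fingerprint for freeze-contract checks."""
        return float(sum(float(np.sum(p.data * (i + 1))) for i, p in enumerate(self.parameters())))

    def state_arrays(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self.parameters()]

    def load_state_arrays(self, arrays: list[np.ndarray]) -> None:
        for p, a in zip(self.parameters(), arrays, strict=True):
            p.data = a.copy()

    def save(self, path: str | Path) -> None:
        np.savez(path, *[p.data for p in self.parameters()],
                 embedding_dim=self.spec.embedding_dim)

    @classmethod
    def load(cls, path: str | Path) -> "Backbone":
        with np.load(path) as z:
            dim = int(z["embedding_dim"])
            bb = cls(BackboneSpec(embedding_dim=dim))
            arrays = [z[f"arr_{i}"] for i in range(len(bb.parameters()))]
        bb.load_state_arrays(arrays)
        return bb


@contextmanager
def eval_mode(*modules):
    """Temporarily stop graph construction through the given modules'
    parameters (deterministic inference; dropout callers pass training=False
    separately)."""
    params = [p for m in modules for p in m.parameters()]
    saved = [p.requires_grad for p in params]
    for p in params:
        p.requires_grad = False
    try:
        yield
    finally:
        for p, s in zip(params, saved):
            p.requires_grad = s


def extract_embedding(backbone: Backbone, image: ImageRecord) -> np.ndarray:
    """Embed one preprocessed image (256x256x3, standardized) to a length-d
    vector; deterministic in evaluation mode."""
    if image.pixels.shape != (256, 256, 3):
        raise ValueError(
            f"image {image.id!r} has shape {image.pixels.shape}; expected "
            "(256, 256, 3) — run the preprocessing pipeline first"
        )
    return backbone.embed_array(to_nchw([image]))[0]


def finetune_backbone(backbone: Backbone, train_records: list[ImageRecord],
                      epochs: int = 40, lr: float = 1e-3, seed: int = 0,
                      batch_size: int = 30) -> Backbone:
    """Supervised finetuning of the backbone on labeled clock images.

    A temporary linear head (d -> n_classes) is attached, the composite is
    trained with cross-entropy and Adam, and the head is discarded. The
    per-epoch loss trace is kept in ``backbone.finetune_loss_log``. The
    default schedule is 40 epochs; the default rate suits a from-scratch
    tinycnn (pretrained plug-ins will usually want it lower).
    """
    if not train_records:
        raise ValueError("finetune_backbone needs a non-empty training set")
    if any(r.label is None for r in train_records):
        raise ValueError("train records must be relabeled to {3,4,5} first")
    backbone.finetune_loss_log = []
    if epochs == 0:
        return backbone
    rng = np.random.default_rng(seed)
    classes = sorted({r.label for r in train_records})
    head = Linear(backbone.spec.embedding_dim, len(classes), rng)
    was_trainable = backbone.spec.trainable
    backbone.set_trainable(True)
    opt = Adam(backbone.parameters() + head.parameters(), lr=lr)

    images = to_nchw(train_records)
    labels = np.array([classes.index(r.label) for r in train_records])
    n = len(train_records)
    for _ in range(epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, batch_size):
            idx = order[start:start + batch_size]
            x = Tensor(images[idx])
            onehot = np.zeros((len(idx), len(classes)), dtype=np.float32)
            onehot[np.arange(len(idx)), labels[idx]] = 1.0
            probs = head(backbone.forward(x)).softmax(axis=1)
            loss = -(Tensor(onehot) * probs.log()).sum(axis=1).mean()
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_loss += float(loss.data) * len(idx)
        backbone.finetune_loss_log.append(epoch_loss / n)
    backbone.set_trainable(was_trainable)
    return backbone


def set_trainable(backbone: Backbone, trainable: bool) -> Backbone:
    """Functional alias for :meth:`Backbone.set_trainable`."""
    return backbone.set_trainable(trainable)
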