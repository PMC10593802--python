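"""Score-CAM saliency maps for trained clock scorers.

Score-CAM is a gradient-free class-activation method: each channel of the
last convolutional feature map is upsampled to input size, min-max
normalized and used to mask the (standardized) input; the masked input is
forwarded through the model and the target-class score recorded. A softmax
over these scores weighs the upsampled maps, and the ReLU of the weighted
sum — min-max normalized to [0, 1] — is the saliency map.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image
from skimage.transform import resize as sk_resize

from .data_prep import ImageRecord, standardize, to_nchw

__all__ = ["SaliencyMap", "score_cam", "overlay"]

_CHUNK = 16  # masked-forward minibatch size


@dataclass
class SaliencyMap:
    values: np.ndarray  # HxW in [0, 1]
    target_class: int
    source_layer: str = "last_conv"


def _minmax(a: np.ndarray) -> np.ndarray:
    lo, hi = a.min(), a.max()
    if hi - lo < 1e-12:
        return np.zeros_like(a)
    return (a - lo) / (hi - lo)


def score_cam(model, image: ImageRecord, target_class: int) -> SaliencyMap:
    """Saliency of ``target_class`` for one resized [0,1] image.

    ``model`` is an :class:`~clockapi.train_eval.ApiNetModel` or
    :class:`~clockapi.train_eval.ConventionalModel`; inference runs through
    its single-image path (backbone -> classifier), so the map explains the
    scores the model actually reports.
    """
    std = standardize(image)
    x = to_nchw([std])
    cls_idx = model.classes.index(target_class)

    from .backbone import eval_mode
    from .nn import Tensor
    with eval_mode(model.backbone):
        _, fmap_t = model.backbone.forward(Tensor(x), return_fmap=True)
    fmap = fmap_t.data[0]  # (C, h, w)
    n_ch = fmap.shape[0]
    H, W = image.pixels.shape[:2]

    upsampled = np.stack([
        sk_resize(fmap[c], (H, W), order=1, preserve_range=True,
                  anti_aliasing=False)
        for c in range(n_ch)
    ])
    masks = np.stack([_minmax(u) for u in upsampled])

    scores = np.empty(n_ch)
    for start in range(0, n_ch, _CHUNK):
        m = masks[start:start + _CHUNK]
        batch = x[0][None] * m[:, None, :, :]  # mask the standardized input
        emb = model.backbone.embed_array(batch.astype(np.float32))
        logits = _logits(model, emb)
        scores[start:start + _CHUNK] = logits[:, cls_idx]

    z = scores - scores.max()
    weights = np.exp(z) / np.exp(z).sum()
    cam = np.maximum((weights[:, None, None] * upsampled).sum(axis=0), 0.0)
    return SaliencyMap(values=_minmax(cam), target_class=target_class)


def _logits(model, emb: np.ndarray) -> np.ndarray:
    if hasattr(model, "api"):
        return emb @ model.api.classifier.W.data + model.api.classifier.b.data
    return emb @ model.head.W.data + model.head.b.data


def overlay(sal: SaliencyMap, image: ImageRecord, out: str | Path,
            alpha: float = 0.5) -> Path:
    """Write a heatmap blend ``(1-alpha)*image + alpha*colormap(map)``."""
    from matplotlib import colormaps

    if sal.values.shape != image.pixels.shape[:2]:
        raise ValueError("saliency map and image sizes differ")
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must be in [0, 1]")
    heat = colormaps["jet"](sal.values)[:, :, :3]
    blended = (1.0 - alpha) * np.clip(image.pixels, 0, 1) + alpha * heat
    out = Path(out)
    Image.fromarray((np.clip(blended, 0, 1) * 255).astype(np.uint8)).save(out)
    return out
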