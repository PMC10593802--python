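"""Loading and preprocessing of clock-drawing images.

The preparation pipeline mirrors how scanned Clock Drawing Test (CDT)
images are fed to a convolutional scorer: resize to 256x256, optional
photometric/geometric augmentation that deliberately excludes rotations and
reflections (a rotated clock reads a different time, so those transforms
would corrupt the label), per-channel ImageNet standardization, and
collapsing of the rare severe scores (0-2) into score 3 to give a balanced
three-class task {3, 4, 5}.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from scipy import ndimage

logger = logging.getLogger(__name__)

#: canonical ImageNet channel statistics used by pretrained-backbone pipelines
IMAGENET_MEAN = np.array([0.485, 0.456, 0.406], dtype=np.float32)
IMAGENET_STD = np.array([0.229, 0.224, 0.225], dtype=np.float32)

TARGET_SIZE = 256


@dataclass
class ImageRecord:
    """One clock drawing flowing through the pipeline.

    ``pixels`` is an HxWx3 float grid in [0, 1] (grayscale inputs are
    replicated across channels); ``raw_score`` is the original Shulman
    score 0-5 and ``label`` the collapsed class in {3, 4, 5} once
    :func:`relabel_scores` has run.
    """

    id: str
    pixels: np.ndarray
    raw_score: int
    label: int | None = None


@dataclass
class AugmentConfig:
    """Ranges for the label-preserving augmentations.

    Brightness is additive, contrast multiplies deviations from mid-gray,
    shift is a translation as a fraction of the side length, and scale is an
    isotropic zoom about the image center. No rotation or reflection is ever
    applied. Shifted/zoomed-out borders are filled with white (1.0), the
    paper background of a scanned form.
    """

    brightness_delta: tuple[float, float] = (-0.2, 0.2)
    contrast_factor: tuple[float, float] = (0.8, 1.2)
    shift_frac: tuple[float, float] = (-0.1, 0.1)
    scale_factor: tuple[float, float] = (0.9, 1.1)
    seed: int = 0

    def __post_init__(self):
        for name in ("brightness_delta", "contrast_factor", "shift_frac", "scale_factor"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name}: lower bound {lo} exceeds upper bound {hi}")
        if self.scale_factor[0] <= 0:
            raise ValueError("scale_factor must stay positive")


def _to_rgb01(img: Image.Image) -> np.ndarray:
    arr = np.asarray(img.convert("RGB"), dtype=np.float32) / 255.0
    return arr


def load_images(image_dir: str | Path, label_table: str | Path) -> list[ImageRecord]:
    """Read a directory of PNG/JPEG clocks plus an ``id,score`` CSV.

    The ``id`` column names the image file (with or without extension).
    Records are returned sorted by id. A missing file or an out-of-range
    score is a hard error naming the offending id.
    """
    image_dir = Path(image_dir)
    table = pd.read_csv(label_table, dtype={"id": str})
    if not {"id", "score"}.issubset(table.columns):
        raise ValueError("label table must have columns 'id' and 'score'")
    if table.empty:
        logger.warning("label table %s is empty; returning no records", label_table)
        return []
    records = []
    for row in table.itertuples(index=False):
        rid = str(row.id)
        score = int(row.score)
        if not 0 <= score <= 5:
            raise ValueError(f"image {rid!r}: Shulman score {score} outside 0-5")
        path = image_dir / rid
        if not path.exists():
            for ext in (".png", ".jpg", ".jpeg"):
                cand = image_dir / (rid + ext)
                if cand.exists():
                    path = cand
                    break
            else:
                raise FileNotFoundError(f"no image file for id {rid!r} in {image_dir}")
        with Image.open(path) as img:
            pixels = _to_rgb01(img)
        records.append(ImageRecord(id=rid, pixels=pixels, raw_score=score))
    records.sort(key=lambda r: r.id)
    return records


def resize_256(record: ImageRecord) -> ImageRecord:
    """Bilinear resize to 256x256 (no aspect preservation; clocks sit in
    near-square crops so plain resampling keeps the geometry usable)."""
    h, w = record.pixels.shape[:2]
    if h == 0 or w == 0:
        raise ValueError(f"image {record.id!r} has zero size")
    if (h, w) == (TARGET_SIZE, TARGET_SIZE):
        return replace(record, pixels=record.pixels.copy())
    img = Image.fromarray((np.clip(record.pixels, 0, 1) * 255).astype(np.uint8))
    img = img.resize((TARGET_SIZE, TARGET_SIZE), Image.BILINEAR)
    return replace(record, pixels=_to_rgb01(img))


def augment(record: ImageRecord, cfg: AugmentConfig) -> ImageRecord:
    """Apply one random draw of brightness/contrast/shift/scale.

    Deterministic in ``cfg.seed``; never rotates or mirrors. Output pixels
    are clamped back to [0, 1].
    """
    rng = np.random.default_rng(cfg.seed)
    delta = rng.uniform(*cfg.brightness_delta)
    factor = rng.uniform(*cfg.contrast_factor)
    shift_y = rng.uniform(*cfg.shift_frac)
    shift_x = rng.uniform(*cfg.shift_frac)
    scale = rng.uniform(*cfg.scale_factor)

    x = record.pixels.astype(np.float64)
    h, w = x.shape[:2]
    if scale != 1.0 or shift_x != 0.0 or shift_y != 0.0:
        # affine map about the image center: output(o) = input(o/scale + offset)
        center = np.array([(h - 1) / 2.0, (w - 1) / 2.0])
        matrix = np.array([1.0 / scale, 1.0 / scale])
        offset = center - center / scale - np.array([shift_y * h, shift_x * w]) / scale
        out = np.empty_like(x)
        for c in range(x.shape[2]):
            out[:, :, c] = ndimage.affine_transform(
                x[:, :, c], matrix, offset=offset, order=1, mode="constant", cval=1.0
            )
        x = out
    x = (x - 0.5) * factor + 0.5 + delta
    return replace(record, pixels=np.clip(x, 0.0, 1.0).astype(np.float32))


def standardize(record: ImageRecord) -> ImageRecord:
    """Per-channel (x - mean)/std with the canonical ImageNet constants."""
    x = (record.pixels - IMAGENET_MEAN) / IMAGENET_STD
    return replace(record, pixels=x.astype(np.float32))


def relabel_scores(records: list[ImageRecord]) -> list[ImageRecord]:
    """Collapse Shulman scores <= 3 into class 3, keeping 4 and 5.

    Severe-deficit drawings are rare in clinic-collected CDT data; pooling
    them with score 3 yields the balanced {3, 4, 5} task.
    """
    out = []
    for r in records:
        if r.raw_score is None:
            raise ValueError(f"record {r.id!r} has no raw score")
        out.append(replace(r, label=3 if r.raw_score <= 3 else r.raw_score))
    return out


def preprocess(record: ImageRecord, augment_cfg: AugmentConfig | None = None) -> ImageRecord:
    """resize -> (optional augment) -> standardize; the full input pipeline."""
    r = resize_256(record)
    if augment_cfg is not None:
        r = augment(r, augment_cfg)
    return standardize(r)


def to_nchw(records: list[ImageRecord]) -> np.ndarray:
    """Stack records into an (N, 3, H, W) float32 batch for the backbone."""
    return np.stack([r.pixels.transpose(2, 0, 1) for r in records]).astype(np.float32)
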