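"""Procedural clock-drawing generator with graded visuospatial deficits.

Real Clock Drawing Test data are scanned hand drawings of a clock showing
11:10, scored 0-5 on the Shulman scale. This module fabricates the three
retained classes at desk scale:

* score 5 — a normal clock: circle, digits 1-12 at their true angular
  positions, hour and minute hands reading exactly 11:10;
* score 4 — minor visuospatial deficits: small positional jitter of the
  numbers and a small hand-angle error, no omissions;
* score 3 — an incorrect time representation: a gross hand-angle error
  (the drawn time is wrong) plus omitted numbers and wobblier strokes.

Every drawing also carries small seed-driven "handwriting" variability
(circle radius, hand lengths, digit size) that is independent of the
deficit magnitudes, so distinct seeds give distinct images in every class
while score-5 hands stay at the exact 11:10 geometry.

Digits are drawn as seven-segment stroke glyphs so no font files are
needed; the two digits of 10/11/12 are tied by a short connecting stroke so
each number is one connected ink component (convenient for counting
omissions in tests).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image, ImageDraw

from .data_prep import ImageRecord

__all__ = [
    "ClockSpec", "render_clock", "render_template", "default_spec_for",
    "generate_dataset", "HOUR_HAND_DEG", "MINUTE_HAND_DEG",
]

#: 11:10 geometry, degrees clockwise from 12 o'clock
MINUTE_HAND_DEG = 60.0          # minute hand on the 2
HOUR_HAND_DEG = 11 * 30.0 + (10 / 60) * 30.0  # 335: hour hand past the 11

#: deficit magnitudes per class (documented constants; monotone in severity)
_DEFAULT_DEFICITS = {
    5: dict(number_jitter_px=0.0, hand_angle_error_deg=0.0, omit_numbers=0, stroke_noise=0.0),
    4: dict(number_jitter_px=6.0, hand_angle_error_deg=8.0, omit_numbers=0, stroke_noise=0.6),
    3: dict(number_jitter_px=10.0, hand_angle_error_deg=60.0, omit_numbers=2, stroke_noise=1.2),
}

# seven-segment endpoints in a unit box, y growing downward
_SEG = {
    "t": ((0, 0), (1, 0)), "m": ((0, 0.5), (1, 0.5)), "b": ((0, 1), (1, 1)),
    "tl": ((0, 0), (0, 0.5)), "bl": ((0, 0.5), (0, 1)),
    "tr": ((1, 0), (1, 0.5)), "br": ((1, 0.5), (1, 1)),
}
_DIGIT_SEGS = {
    0: "t tl tr bl br b", 1: "tr br", 2: "t tr m bl b", 3: "t tr m br b",
    4: "tl m tr br", 5: "t tl m br b", 6: "t tl m bl br b", 7: "t tr br",
    8: "t m b tl bl tr br", 9: "t tl tr m br b",
}


@dataclass(frozen=True)
class ClockSpec:
    """Rendering recipe for one synthetic clock drawing."""

    target_label: int
    canvas_px: int = 256
    number_jitter_px: float = 0.0
    hand_angle_error_deg: float = 0.0
    omit_numbers: int = 0
    stroke_noise: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.target_label not in (3, 4, 5):
            raise ValueError(f"target_label must be in {{3,4,5}}, got {self.target_label}")
        if self.canvas_px < 64:
            raise ValueError("canvas_px must be at least 64")
        for name in ("number_jitter_px", "hand_angle_error_deg", "stroke_noise"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0 <= self.omit_numbers <= 11:
            raise ValueError("omit_numbers must be in 0..11")


def default_spec_for(label: int, seed: int) -> ClockSpec:
    """The documented deficit profile for a class; magnitudes shrink as the
    score rises (score 3 >> score 4 > score 5 = none)."""
    if label not in _DEFAULT_DEFICITS:
        raise ValueError(f"label must be in {{3,4,5}}, got {label}")
    return ClockSpec(target_label=label, seed=seed, **_DEFAULT_DEFICITS[label])


def _number_segments(n: int) -> list[tuple[tuple, tuple]]:
    """Stroke segments for the clock number `n` in a local unit frame
    centered at (0, 0) with digit height 1."""
    digits = [int(ch) for ch in str(n)]
    w, gap = 0.62, 0.22  # digit width and inter-digit gap, in digit heights
    total_w = len(digits) * w + (len(digits) - 1) * gap
    segs = []
    for k, d in enumerate(digits):
        x0 = -total_w / 2 + k * (w + gap)
        for key in _DIGIT_SEGS[d].split():
            (ax, ay), (bx, by) = _SEG[key]
            segs.append(((x0 + ax * w, ay - 0.5), (x0 + bx * w, by - 0.5)))
    if len(digits) == 2:
        # tie the digits so each number is one connected ink component
        segs.append(((-total_w / 2 + w / 2, 0.0), (total_w / 2, 0.0)))
    return segs


def _unit(theta_deg: float) -> np.ndarray:
    """Direction for an angle measured clockwise from 12 o'clock, in image
    coordinates (x right, y down)."""
    t = np.deg2rad(theta_deg)
    return np.array([np.sin(t), -np.cos(t)])


def _render(spec: ClockSpec, natural_variability: bool) -> np.ndarray:
    rng = np.random.default_rng(spec.seed)
    s = spec.canvas_px
    img = Image.new("RGB", (s, s), (255, 255, 255))
    draw = ImageDraw.Draw(img)
    ink = (20, 20, 20)
    lw = max(2, s // 128)

    if natural_variability:
        radius = s * rng.uniform(0.40, 0.44)
        center = s / 2 + rng.uniform(-0.012, 0.012, size=2) * s
        digit_h = s * 0.055 * rng.uniform(0.9, 1.1)
        hand_scale = rng.uniform(0.95, 1.05)
    else:
        radius = s * 0.42
        center = np.array([s / 2.0, s / 2.0])
        digit_h = s * 0.055
        hand_scale = 1.0

    def noisy(p: np.ndarray) -> tuple:
        if spec.stroke_noise > 0:
            p = p + rng.normal(0.0, spec.stroke_noise, size=2)
        return tuple(p)

    draw.ellipse(
        [center[0] - radius, center[1] - radius, center[0] + radius, center[1] + radius],
        outline=ink, width=lw,
    )

    omitted = set()
    if spec.omit_numbers:
        omitted = set(rng.choice(np.arange(1, 13), size=spec.omit_numbers, replace=False))
    number_r = radius * 0.78
    for n in range(1, 13):
        if n in omitted:
            continue
        pos = center + number_r * _unit(n * 30.0)
        if spec.number_jitter_px > 0:
            pos = pos + rng.uniform(-spec.number_jitter_px, spec.number_jitter_px, size=2)
        for a, b in _number_segments(n):
            pa = pos + np.array(a) * digit_h
            pb = pos + np.array(b) * digit_h
            draw.line([noisy(pa), noisy(pb)], fill=ink, width=max(1, lw - 1))

    def hand_angle(base: float) -> float:
        if spec.hand_angle_error_deg <= 0:
            return base
        # error magnitude in [1/2, 1] of the spec magnitude, random sign:
        # a score-3 magnitude of 60 deg always yields a wrong drawn time
        mag = rng.uniform(0.5, 1.0) * spec.hand_angle_error_deg
        return base + rng.choice([-1.0, 1.0]) * mag

    for base, frac in ((HOUR_HAND_DEG, 0.30), (MINUTE_HAND_DEG, 0.46)):
        tip = center + radius * frac * hand_scale * _unit(hand_angle(base))
        draw.line([noisy(center.copy()), noisy(tip)], fill=ink, width=lw)

    return np.asarray(img, dtype=np.float32) / 255.0


def render_clock(spec: ClockSpec) -> ImageRecord:
    """Render one clock; deterministic in ``spec.seed``."""
    pixels = _render(spec, natural_variability=True)
    return ImageRecord(
        id=f"synth_{spec.target_label}_{spec.seed}",
        pixels=pixels,
        raw_score=spec.target_label,
        label=spec.target_label,
    )


def render_template(canvas_px: int = 256) -> ImageRecord:
    """The canonical deficit-free clock with all variability suppressed;
    used as the reference image for pixel-difference statistics."""
    spec = ClockSpec(target_label=5, canvas_px=canvas_px, seed=0)
    return ImageRecord(id="template_5", pixels=_render(spec, natural_variability=False),
                       raw_score=5, label=5)


def generate_dataset(n_per_class: int, seed: int, out_dir: str | Path) -> Path:
    """Write ``3 * n_per_class`` PNGs plus a ``labels.csv`` (columns
    ``id,score``) compatible with :func:`clockapi.data_prep.load_images`.

    Returns the path of the label table. Exactly stratified and
    deterministic in ``seed``.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for label in (3, 4, 5):
        for i in range(n_per_class):
            child = int(np.random.SeedSequence([seed, label, i]).generate_state(1)[0] % (2**31))
            spec = default_spec_for(label, seed=child)
            rec = render_clock(spec)
            name = f"clock_{label}_{i:04d}.png"
            Image.fromarray((rec.pixels * 255).astype(np.uint8)).save(out_dir / name)
            rows.append({"id": name, "score": label})
    table = pd.DataFrame(rows)
    csv_path = out_dir / "labels.csv"
    table.to_csv(csv_path, index=False)
    return csv_path


def generate_records(n_per_class: int, seed: int, canvas_px: int = 256,
                     labels: tuple[int, ...] = (3, 4, 5)) -> list[ImageRecord]:
    """In-memory variant of :func:`generate_dataset` (no files written)."""
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    records = []
    for label in labels:
        for i in range(n_per_class):
            child = int(np.random.SeedSequence([seed, label, i]).generate_state(1)[0] % (2**31))
            spec = ClockSpec(target_label=label, canvas_px=canvas_px, seed=child,
                             **_DEFAULT_DEFICITS[label])
            rec = render_clock(spec)
            rec.id = f"clock_{label}_{i:04d}"
            records.append(rec)
    return records
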