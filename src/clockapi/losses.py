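"""Training objective: quad cross-entropy plus the score-ranking hinge.

For a pair (1, 2) with one-hot labels y_i and correct classes c_i,

    L     = L_CE + λ · L_RK
    L_CE  = − Σ_{i∈{1,2}} Σ_{j∈{self,other}} y_iᵀ log p_i^j          (4 terms)
    L_RK  = Σ_{i∈{1,2}} max(0, p_i^other(c_i) − p_i^self(c_i) + ε)

The ranking hinge asks the self-gated prediction of the true class to beat
the other-gated one by at least the margin ε; it vanishes once that holds.
Defaults λ=1, ε=0.005. Over a batch of pairs both terms are averaged
(mean reduction keeps learning-rate semantics independent of batch size).
Logs are clamped at 1e-12 so degenerate probabilities stay finite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .api_core import PredictionQuad
from .nn import Tensor

__all__ = ["LabelInfo", "LossConfig", "LossBreakdown",
           "cross_entropy_quad", "ranking_loss", "total_loss"]


@dataclass
class LossConfig:
    lam: float = 1.0       # λ, weight of the ranking term
    epsilon: float = 0.005  # ε, ranking margin

    def __post_init__(self):
        if self.lam < 0 or self.epsilon < 0:
            raise ValueError("lambda and epsilon must be non-negative")


class LabelInfo:
    """Correct classes and one-hot targets for a batch of pairs."""

    def __init__(self, c_1, c_2, num_classes: int):
        self.c_1 = np.atleast_1d(np.asarray(c_1, dtype=int))
        self.c_2 = np.atleast_1d(np.asarray(c_2, dtype=int))
        if self.c_1.shape != self.c_2.shape:
            raise ValueError("c_1 and c_2 must have equal length")
        if (self.c_1.min() < 0 or self.c_1.max() >= num_classes
                or self.c_2.min() < 0 or self.c_2.max() >= num_classes):
            raise ValueError("class indices out of range")
        self.num_classes = num_classes
        eye = np.eye(num_classes)
        self.y_1 = eye[self.c_1]
        self.y_2 = eye[self.c_2]


@dataclass
class LossBreakdown:
    L: float | Tensor
    L_CE: float | Tensor
    L_RK: float | Tensor
    lam: float
    epsilon: float

    def floats(self) -> tuple[float, float, float]:
        f = lambda v: float(v.data) if isinstance(v, Tensor) else float(v)
        return f(self.L), f(self.L_CE), f(self.L_RK)


def cross_entropy_quad(preds: PredictionQuad, labels: LabelInfo) -> Tensor:
    """Mean over pairs of the 4-term cross entropy (self and other views of
    both images)."""
    y1, y2 = Tensor(labels.y_1), Tensor(labels.y_2)
    per_pair = (
        -(y1 * preds.p_self_1.log()).sum(axis=1)
        - (y1 * preds.p_other_1.log()).sum(axis=1)
        - (y2 * preds.p_self_2.log()).sum(axis=1)
        - (y2 * preds.p_other_2.log()).sum(axis=1)
    )
    return per_pair.mean()


def ranking_loss(preds: PredictionQuad, labels: LabelInfo,
                 cfg: LossConfig | None = None) -> Tensor:
    """Mean over pairs of Σ_i max(0, p_i^other(c_i) − p_i^self(c_i) + ε)."""
    cfg = cfg or LossConfig()
    y1, y2 = Tensor(labels.y_1), Tensor(labels.y_2)
    h1 = ((preds.p_other_1 - preds.p_self_1) * y1).sum(axis=1) + cfg.epsilon
    h2 = ((preds.p_other_2 - preds.p_self_2) * y2).sum(axis=1) + cfg.epsilon
    return (h1.clip_min(0.0) + h2.clip_min(0.0)).mean()


def total_loss(preds: PredictionQuad, labels: LabelInfo,
               cfg: LossConfig | None = None) -> LossBreakdown:
    """L = L_CE + λ·L_RK; gradients flow through both terms."""
    cfg = cfg or LossConfig()
    l_ce = cross_entropy_quad(preds, labels)
    l_rk = ranking_loss(preds, labels, cfg)
    return LossBreakdown(L=l_ce + cfg.lam * l_rk, L_CE=l_ce, L_RK=l_rk,
                         lam=cfg.lam, epsilon=cfg.epsilon)
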