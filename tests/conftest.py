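import numpy as np
import pytest

from clockapi import synthclock
from clockapi.backbone import Backbone, BackboneSpec, finetune_backbone
from clockapi.data_prep import standardize


@pytest.fixture(scope="session")
def tiny_records():
    """Six synthetic clocks (two per class), resized and labeled."""
    return synthclock.generate_records(2, seed=7)


@pytest.fixture(scope="session")
def small_records():
    """Thirty synthetic clocks (ten per class)."""
    return synthclock.generate_records(10, seed=11)


@pytest.fixture(scope="session")
def fresh_backbone():
    return Backbone(BackboneSpec(), seed=3)


def loop_api_oracle(x1, x2, weights, num_classes):
    """Straight-line scalar re-implementation of the pairwise interaction
    equations (mutual MLP, gates, residual attention, shared softmax
    classifier), evaluation mode. Independent of the package's vectorized
    autodiff path: everything is explicit python loops over coordinates.

    ``weights`` carries W1 (2d,h), b1 (h,), W2 (h,d), b2 (d,), Wc (d,C),
    bc (C,).
    """
    import math

    W1, b1, W2, b2, Wc, bc = weights
    d = len(x1)
    cat = list(x1) + list(x2)
    h = []
    for j in range(W1.shape[1]):
        s = b1[j]
        for i in range(len(cat)):
            s += cat[i] * W1[i, j]
        h.append(max(s, 0.0))
    xm = []
    for j in range(W2.shape[1]):
        s = b2[j]
        for i in range(len(h)):
            s += h[i] * W2[i, j]
        xm.append(s)

    def sig(v):
        return 1.0 / (1.0 + math.exp(-v))

    g1 = [sig(xm[k] * x1[k]) for k in range(d)]
    g2 = [sig(xm[k] * x2[k]) for k in range(d)]
    x_self_1 = [x1[k] + x1[k] * g1[k] for k in range(d)]
    x_self_2 = [x2[k] + x2[k] * g2[k] for k in range(d)]
    x_other_1 = [x1[k] + x1[k] * g2[k] for k in range(d)]
    x_other_2 = [x2[k] + x2[k] * g1[k] for k in range(d)]

    def clf(v):
        z = []
        for c in range(num_classes):
            s = bc[c]
            for k in range(d):
                s += v[k] * Wc[k, c]
            z.append(s)
        m = max(z)
        e = [math.exp(t - m) for t in z]
        tot = sum(e)
        return [t / tot for t in e]

    return {
        "p_self_1": clf(x_self_1), "p_self_2": clf(x_self_2),
        "p_other_1": clf(x_other_1), "p_other_2": clf(x_other_2),
        "x_m": xm, "g1": g1, "g2": g2,
    }


def brute_force_pairs(ids, labels, features):
    """Exhaustive O(n^2) reference pair miner: per anchor, the same-class
    image at maximal distance and, per adjacent class, the image at minimal
    distance; ties toward the smallest id."""
    import math

    out = []
    present = set(labels.values())
    for anchor in sorted(ids):
        best_intra, best_d = None, -1.0
        for other in sorted(ids):
            if other == anchor or labels[other] != labels[anchor]:
                continue
            d = math.dist(features[anchor], features[other])
            if d > best_d:
                best_intra, best_d = other, d
        if best_intra is not None:
            out.append((anchor, best_intra, "intra"))
        for adj in (labels[anchor] - 1, labels[anchor] + 1):
            if adj not in present:
                continue
            best_inter, best_d = None, math.inf
            for other in sorted(ids):
                if labels[other] != adj:
                    continue
                d = math.dist(features[anchor], features[other])
                if d < best_d:
                    best_inter, best_d = other, d
            out.append((anchor, best_inter, "inter"))
    return out


@pytest.fixture(scope="session")
def finetuned_small(small_records):
    """A backbone briefly finetuned on the 30-clock set (shared across
    tests that need informative embeddings)."""
    bb = Backbone(BackboneSpec(), seed=5)
    finetune_backbone(bb, [standardize(r) for r in small_records],
                      epochs=10, lr=3e-3, seed=5, batch_size=10)
    return bb
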