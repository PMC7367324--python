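"""Task heads' loss algebra: softmax, cross-entropies, weighted joint loss.

Identification uses a softmax head with categorical cross-entropy (L2);
gender classification uses a single sigmoid logit with binary
cross-entropy (L1).  The multitask objective is the weighted sum

    L_joint = w1 * L1 + w2 * L2,   w1 + w2 = 1,

with w1 = w2 = 0.5 by default; ``grid_search_weights`` sweeps candidate
weightings against a validation metric (mean of the two task accuracies).
Predicted probabilities are clipped to [eps, 1-eps], eps = 1e-12, to keep
the losses finite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import softmax as _softmax

CLIP_EPS = 1e-12
DEFAULT_GRID = tuple(round(0.1 * k, 1) for k in range(1, 10))


@dataclass
class LossWeights:
    """Gender (w1) and identification (w2) loss weights; w1 + w2 = 1."""

    w1: float = 0.5
    w2: float = 0.5

    def __post_init__(self):
        if not (0.0 <= self.w1 <= 1.0 and 0.0 <= self.w2 <= 1.0):
            raise ValueError("loss weights must lie in [0, 1]")
        if abs(self.w1 + self.w2 - 1.0) > 1e-9:
            raise ValueError("loss weights must sum to 1")


def softmax(logits: np.ndarray) -> np.ndarray:
    """exp(y_i) / sum_j exp(y_j), computed with max-subtraction."""
    logits = np.asarray(logits, dtype=np.float64)
    if not np.all(np.isfinite(logits)):
        raise ValueError("logits must be finite")
    return _softmax(logits)


def categorical_cross_entropy(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    """L2 = -sum_i y_i log yhat_i for a one-hot label and probability vector."""
    y_true = np.asarray(y_true, dtype=np.float64)
    y_pred = np.asarray(y_pred, dtype=np.float64)
    if y_true.shape != y_pred.shape:
        raise ValueError("label and prediction shapes must match")
    p = np.clip(y_pred, CLIP_EPS, 1.0 - CLIP_EPS)
    return float(-np.sum(y_true * np.log(p)))


def binary_cross_entropy(y_true: float, y_pred: float) -> float:
    """L1 = -y log yhat - (1-y) log(1-yhat) for a {0,1} label."""
    if y_true not in (0, 1, 0.0, 1.0):
        raise ValueError("binary label must be 0 or 1")
    if not 0.0 <= y_pred <= 1.0:
        raise ValueError("prediction must lie in [0, 1]")
    p = min(max(y_pred, CLIP_EPS), 1.0 - CLIP_EPS)
    return float(-y_true * np.log(p) - (1.0 - y_true) * np.log(1.0 - p))


def joint_loss(l1: float, l2: float, weights: LossWeights | None = None) -> float:
    """L_joint = w1 * L1 + w2 * L2 (defaults w1 = w2 = 0.5)."""
    weights = weights or LossWeights()
    if l1 < 0 or l2 < 0:
        raise ValueError("losses must be non-negative")
    return weights.w1 * l1 + weights.w2 * l2


def grid_search_weights(grid, evaluate_fn, tie_value: float = 0.5) -> LossWeights:
    """Pick the (w1, 1-w1) grid point maximizing a validation metric.

    ``evaluate_fn(weights: LossWeights) -> float`` trains/evaluates under
    the candidate weighting and returns the validation metric (the mean
    of the two task accuracies in the standard harness).  Ties are broken
    toward w1 = ``tie_value``; evaluation order is deterministic.
    """
    grid = list(grid)
    if not grid:
        raise ValueError("empty weight grid")
    best: LossWeights | None = None
    best_score = -np.inf
    for w1 in grid:
        lw = LossWeights(round(float(w1), 12), round(float(1.0 - w1), 12))
        score = float(evaluate_fn(lw))
        better = score > best_score + 1e-12
        tie = abs(score - best_score) <= 1e-12 and best is not None and (
            abs(lw.w1 - tie_value) < abs(best.w1 - tie_value))
        if best is None or better or tie:
            best, best_score = lw, max(score, best_score)
    return best
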