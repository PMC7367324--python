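"""Modality fusion: feature-level concatenation and score-level rules.

Feature-level fusion batch-normalizes each modality's 300-d feature
(statistics over present samples only), zero-fills absent modalities and
concatenates in the fixed order (ecg, face, fingerprint) into a 900-d
vector.  Score-level fusion instead combines per-modality class
probabilities with a sum, product or max rule under non-negative
modality weights summing to one:

* sum:      p = sum_m w_m p_m              (a weighted arithmetic mean)
* product:  p ∝ prod_m p_m ** w_m          (a weighted geometric mean)
* max:      p ∝ elementwise max_m (w_m p_m)

Product and max outputs are renormalized to sum to one.  With equal
weights these reduce to the textbook combination rules, and the product
rule applied to identical inputs is the identity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .features import FEATURE_DIM, MODALITIES
from .nn import MaskedBatchNorm

FUSED_DIM = FEATURE_DIM * len(MODALITIES)
SCORE_RULES = ("sum", "product", "max")
_EPS = 1e-300  # floor inside the product rule's log, guards log(0)


@dataclass
class FusedFeature:
    """900-d concatenated feature + per-modality presence mask."""

    values: np.ndarray
    presence_mask: np.ndarray  # 3 booleans in (ecg, face, fingerprint) order

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        self.presence_mask = np.asarray(self.presence_mask, dtype=bool)
        if self.values.shape != (FUSED_DIM,):
            raise ValueError(f"fused feature must have length {FUSED_DIM}")
        if self.presence_mask.shape != (len(MODALITIES),):
            raise ValueError("presence mask must have one flag per modality")
        if not self.presence_mask.any():
            raise ValueError("at least one modality must be present")
        for i, present in enumerate(self.presence_mask):
            block = self.values[i * FEATURE_DIM : (i + 1) * FEATURE_DIM]
            if not present and np.any(block != 0):
                raise ValueError(f"absent modality {MODALITIES[i]!r} block must be zero")


@dataclass
class FusionSpec:
    """Fusion configuration: level, score rule, per-modality weights."""

    level: str = "feature"                       # "feature" | "score"
    rule: str = "sum"                            # score level only
    weights: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)

    def __post_init__(self):
        if self.level not in ("feature", "score"):
            raise ValueError(f"unknown fusion level {self.level!r}")
        if self.rule not in SCORE_RULES:
            raise ValueError(f"unknown score rule {self.rule!r}")
        w = np.asarray(self.weights, dtype=np.float64)
        if w.shape != (3,) or np.any(w < 0):
            raise ValueError("weights must be 3 non-negative reals")
        if abs(w.sum() - 1.0) > 1e-9:
            raise ValueError("weights must sum to 1")
        self.weights = tuple(float(x) for x in w)


def normalize_feature(batch: np.ndarray, bn: MaskedBatchNorm,
                      present: np.ndarray | None = None,
                      training: bool = True) -> np.ndarray:
    """Masked batch normalisation of one modality's feature batch.

    Rows flagged absent are excluded from the statistics (and from
    running-statistic updates) and come out exactly zero, implementing
    the missing-modality contract.
    """
    batch = np.atleast_2d(np.asarray(batch, dtype=np.float64))
    bn.set_mask(present)
    out = bn.forward(batch, training=training)
    bn.set_mask(None)
    return out


def fuse_features(features: dict[str, np.ndarray],
                  mask: dict[str, bool] | None = None) -> FusedFeature:
    """Concatenate per-modality 300-d features in (ecg, face, fingerprint) order.

    ``features`` maps modality name to its vector; missing keys (or keys
    masked False) produce zero-filled blocks.  At least one modality must
    be present.
    """
    mask = mask or {m: m in features for m in MODALITIES}
    unknown = set(features) - set(MODALITIES)
    if unknown:
        raise ValueError(f"unknown modalities: {sorted(unknown)}")
    presence = np.array([bool(mask.get(m, False)) for m in MODALITIES])
    if not presence.any():
        raise ValueError("all modalities absent")
    blocks = []
    for m, present in zip(MODALITIES, presence):
        if present:
            v = np.asarray(features[m], dtype=np.float64)
            if v.shape != (FEATURE_DIM,):
                raise ValueError(f"{m} feature must have length {FEATURE_DIM}")
            blocks.append(v)
        else:
            blocks.append(np.zeros(FEATURE_DIM))
    return FusedFeature(np.concatenate(blocks), presence)


def score_fuse(probs: list[np.ndarray], spec: FusionSpec,
               modalities: list[str] | None = None) -> np.ndarray:
    """Combine class-probability vectors under the spec's rule and weights.

    ``modalities`` names the source of each vector (defaults to the first
    ``len(probs)`` canonical modalities) and selects its weight; weights
    of supplied modalities are renormalized to sum to one when fewer than
    three vectors are given.  The output is always a probability vector.
    """
    if not probs:
        raise ValueError("need at least one probability vector")
    modalities = modalities or list(MODALITIES[: len(probs)])
    if len(modalities) != len(probs):
        raise ValueError("one modality name per probability vector")
    P = [np.asarray(p, dtype=np.float64) for p in probs]
    n_classes = P[0].shape[-1]
    for p in P:
        if p.shape[-1] != n_classes:
            raise ValueError("probability vectors must have the same class count")
        if np.any(p < 0) or np.any(np.abs(p.sum(axis=-1) - 1.0) > 1e-6):
            raise ValueError("inputs must be probability vectors")
    w = np.array([spec.weights[MODALITIES.index(m)] for m in modalities])
    w = w / w.sum()

    if spec.rule == "sum":
        out = sum(wi * p for wi, p in zip(w, P))
    elif spec.rule == "product":
        log_out = sum(wi * np.log(np.maximum(p, _EPS)) for wi, p in zip(w, P))
        log_out = log_out - log_out.max(axis=-1, keepdims=True)
        out = np.exp(log_out)
    else:  # max
        out = np.maximum.reduce([wi * p for wi, p in zip(w, P)])
    total = out.sum(axis=-1, keepdims=True)
    if np.any(total <= 0):
        # degenerate (e.g. product of disjoint one-hots): fall back to uniform
        out = np.where(total > 0, out, 1.0)
        total = out.sum(axis=-1, keepdims=True)
    return out / total
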