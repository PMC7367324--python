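"""The multimodal multitask network: branches -> masked BN -> trunk -> heads.

Architecture (feature-level fusion):

* per-modality feature branches (ECG 1-D conv + timestep max-pool; image
  backbones + affine projections), each emitting 300-d features;
* per-modality masked batch normalisation, absent modalities zero-filled,
  concatenated into a 900-d fused vector;
* a shared fully connected trunk (512, 256 rectified units);
* task heads: softmax over identity classes, and/or a single sigmoid
  logit for gender.

Training minimizes w1 * BCE(gender) + w2 * CCE(identity); single-task
configurations simply omit the other head from the graph (and from the
parameter count).  All parameters train jointly by backpropagation.
"""

from __future__ import annotations

import numpy as np

from . import nn
from .features import FEATURE_DIM, MODALITIES, EcgConvExtractor, SmallConvBackbone
from .losses import CLIP_EPS, LossWeights
from .noise import FACE_SHAPE, FINGERPRINT_SHAPE

TASKS = ("id", "gender")


class MultimodalNet:
    """Feature-level-fusion network over any subset of the three modalities."""

    def __init__(self, n_classes: int,
                 modalities: tuple[str, ...] = MODALITIES,
                 tasks: tuple[str, ...] = TASKS,
                 seed: int = 0,
                 ecg_kernel: int = 7,
                 face_pool: int = 10, finger_pool: int = 6,
                 n_filters: int = 6, embed_dim: int = 128,
                 trunk_sizes: tuple[int, int] = (512, 256)):
        if not modalities or any(m not in MODALITIES for m in modalities):
            raise ValueError(f"modalities must be a non-empty subset of {MODALITIES}")
        if not tasks or any(t not in TASKS for t in tasks):
            raise ValueError(f"tasks must be a non-empty subset of {TASKS}")
        rng = np.random.default_rng(seed)
        self.modalities = tuple(m for m in MODALITIES if m in modalities)
        self.tasks = tuple(t for t in TASKS if t in tasks)
        self.n_classes = n_classes

        self.branches: dict[str, object] = {}
        self.projections: dict[str, nn.Dense] = {}
        self.bns: dict[str, nn.MaskedBatchNorm] = {}
        for m in self.modalities:
            if m == "ecg":
                self.branches[m] = EcgConvExtractor(ecg_kernel, rng)
            else:
                shape = FACE_SHAPE if m == "face" else FINGERPRINT_SHAPE
                pool = face_pool if m == "face" else finger_pool
                self.branches[m] = SmallConvBackbone(shape, pool, n_filters,
                                                     embed_dim, rng, name=m)
                self.projections[m] = nn.Dense(embed_dim, FEATURE_DIM, rng)
            self.bns[m] = nn.MaskedBatchNorm(FEATURE_DIM)

        fused_dim = FEATURE_DIM * len(MODALITIES)
        h1, h2 = trunk_sizes
        self.trunk = nn.Sequential(
            nn.Dense(fused_dim, h1, rng), nn.ReLU(),
            nn.Dense(h1, h2, rng), nn.ReLU(),
        )
        self.id_head = nn.Dense(h2, n_classes, rng) if "id" in self.tasks else None
        self.gender_head = nn.Dense(h2, 1, rng) if "gender" in self.tasks else None

    # -- parameters --------------------------------------------------------

    def params(self) -> list[nn.Param]:
        out: list[nn.Param] = []
        for m in self.modalities:
            out.extend(self.branches[m].params())
            if m in self.projections:
                out.extend(self.projections[m].params())
            out.extend(self.bns[m].params())
        out.extend(self.trunk.params())
        if self.id_head is not None:
            out.extend(self.id_head.params())
        if self.gender_head is not None:
            out.extend(self.gender_head.params())
        return out

    @property
    def n_params(self) -> int:
        return sum(p.size for p in self.params())

    # -- forward / backward ------------------------------------------------

    def forward(self, batch: dict[str, np.ndarray], training: bool = False):
        """Compute (id_probs, gender_probs); absent modalities are zero blocks.

        ``batch`` maps modality name -> stacked array for the modalities
        this model uses.  Returns ``None`` for a head the model lacks.
        """
        B = len(next(iter(batch.values())))
        blocks = []
        self._present: dict[str, bool] = {}
        for m in MODALITIES:
            if m in self.modalities and m in batch:
                if m == "ecg":
                    feat = self.branches[m].features(batch[m], training=training)
                else:
                    emb = self.branches[m].embed(batch[m], training=training)
                    feat = self.projections[m].forward(emb, training=training)
                self.bns[m].set_mask(None)
                blocks.append(self.bns[m].forward(feat, training=training))
                self._present[m] = True
            else:
                blocks.append(np.zeros((B, FEATURE_DIM)))
                self._present[m] = False
        fused = np.concatenate(blocks, axis=1)
        self._fused_B = B
        h = self.trunk.forward(fused, training=training)
        id_probs = None
        gender_probs = None
        if self.id_head is not None:
            id_probs = nn.softmax(self.id_head.forward(h, training=training))
        if self.gender_head is not None:
            gender_probs = nn.sigmoid(
                self.gender_head.forward(h, training=training)[:, 0])
        self._id_probs = id_probs
        self._gender_probs = gender_probs
        return id_probs, gender_probs

    def backward(self, id_labels: np.ndarray | None,
                 gender_labels: np.ndarray | None,
                 weights: LossWeights) -> None:
        """Accumulate gradients of the (joint) loss for the last forward pass.

        Uses the fused softmax/sigmoid + cross-entropy gradients
        (p - y) / B, scaled by the task weights.  Single-task models pass
        ``None`` for the missing label set and use weight 1 implicitly.
        """
        B = self._fused_B
        multitask = self.id_head is not None and self.gender_head is not None
        w_id = weights.w2 if multitask else 1.0
        w_gender = weights.w1 if multitask else 1.0
        g_trunk = None
        if self.id_head is not None:
            Y = np.zeros((B, self.n_classes))
            Y[np.arange(B), id_labels] = 1.0
            g = w_id * (self._id_probs - Y) / B
            g_trunk = self.id_head.backward(g)
        if self.gender_head is not None:
            g = (w_gender * (self._gender_probs - gender_labels) / B)[:, None]
            gh = self.gender_head.backward(g)
            g_trunk = gh if g_trunk is None else g_trunk + gh
        g_fused = self.trunk.backward(g_trunk)
        for i, m in enumerate(MODALITIES):
            if not self._present[m]:
                continue
            g_block = g_fused[:, i * FEATURE_DIM : (i + 1) * FEATURE_DIM]
            g_feat = self.bns[m].backward(g_block)
            if m == "ecg":
                self.branches[m].backward(g_feat)
            else:
                g_emb = self.projections[m].backward(g_feat)
                self.branches[m].backward(g_emb)

    # -- losses / prediction ----------------------------------------------

    def batch_losses(self, id_labels, gender_labels) -> tuple[float, float]:
        """Mean per-sample (L1 gender BCE, L2 identity CCE) of the last forward."""
        l1 = 0.0
        l2 = 0.0
        if self._id_probs is not None and id_labels is not None:
            p = np.clip(self._id_probs[np.arange(len(id_labels)), id_labels],
                        CLIP_EPS, 1.0)
            l2 = float(-np.mean(np.log(p)))
        if self._gender_probs is not None and gender_labels is not None:
            p = np.clip(self._gender_probs, CLIP_EPS, 1.0 - CLIP_EPS)
            l1 = float(-np.mean(gender_labels * np.log(p)
                                + (1 - gender_labels) * np.log(1 - p)))
        return l1, l2

    def predict(self, batch: dict[str, np.ndarray]):
        return self.forward(batch, training=False)

    def fused_features(self, batch: dict[str, np.ndarray]) -> np.ndarray:
        """The 900-d post-BN concatenated features (eval mode), for probing."""
        B = len(next(iter(batch.values())))
        blocks = []
        for m in MODALITIES:
            if m in self.modalities and m in batch:
                if m == "ecg":
                    feat = self.branches[m].features(batch[m], training=False)
                else:
                    emb = self.branches[m].embed(batch[m], training=False)
                    feat = self.projections[m].forward(emb, training=False)
                self.bns[m].set_mask(None)
                blocks.append(self.bns[m].forward(feat, training=False))
            else:
                blocks.append(np.zeros((B, FEATURE_DIM)))
        return np.concatenate(blocks, axis=1)

    def state(self) -> list[np.ndarray]:
        vals = [p.value.copy() for p in self.params()]
        vals.extend(bn.running_mean.copy() for bn in self.bns.values())
        vals.extend(bn.running_var.copy() for bn in self.bns.values())
        return vals

    def load_state(self, state: list[np.ndarray]) -> None:
        ps = self.params()
        for p, v in zip(ps, state[: len(ps)]):
            p.value[...] = v
        rest = state[len(ps) :]
        nbn = len(self.bns)
        for bn, v in zip(self.bns.values(), rest[:nbn]):
            bn.running_mean = v
        for bn, v in zip(self.bns.values(), rest[nbn:]):
            bn.running_var = v
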