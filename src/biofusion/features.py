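"""Per-modality feature extraction.

Every modality is embedded into a common 300-dimensional feature space:

* ECG: a shared 1-D convolution (kernel 7, same padding) maps each of the
  three 300-sample QRS timesteps to a 300-vector; after a rectifier, an
  element-wise maximum over the timestep axis collapses the sequence to a
  single 300-vector.  The temporal pooling makes the feature invariant to
  the ordering of the three beats — deliberate, since beat-to-beat
  ordering carries little identity information.
* Images: a backbone produces an embedding of arbitrary width, and a
  learned affine projection maps it to 300 dimensions so all modalities
  can be concatenated on equal footing.

The backbone is an interface.  The tested implementation is a small
trainable network (average-pool thumbnail -> 3x3 conv -> dense);
:class:`CallableBackbone` adapts any external embedding function (for
example a pretrained 2048-d residual-network average-pool extractor) to
the same contract.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .ecg import QRS_LENGTH, SEQUENCE_LENGTH, EcgSequence
from .noise import BiometricImage

FEATURE_DIM = 300
MODALITIES = ("ecg", "face", "fingerprint")


@dataclass
class FeatureVector:
    values: np.ndarray
    modality: str

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != (FEATURE_DIM,):
            raise ValueError(f"feature vector must have length {FEATURE_DIM}")
        if self.modality not in MODALITIES:
            raise ValueError(f"unknown modality {self.modality!r}")


class ImageBackbone:
    """Contract: ``embed`` maps a (B, H, W) image stack to (B, output_dim)."""

    name: str = "backbone"
    trainable: bool = False
    output_dim: int

    def embed(self, images: np.ndarray, training: bool = False) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def params(self) -> list[nn.Param]:
        return []

    def backward(self, grad: np.ndarray) -> None:
        """Propagate gradients into backbone parameters (trainable only)."""


class CallableBackbone(ImageBackbone):
    """Adapter wrapping a frozen external embedding function.

    Use this to plug in a pretrained extractor (e.g. a 50-layer residual
    network's 2048-d average-pooled features) without the package taking
    a framework dependency; the wrapped callable must be deterministic.
    """

    def __init__(self, fn, output_dim: int = 2048, name: str = "external"):
        self._fn = fn
        self.output_dim = output_dim
        self.name = name
        self.trainable = False

    def embed(self, images, training=False):
        out = np.asarray(self._fn(images), dtype=np.float64)
        if out.shape != (images.shape[0], self.output_dim):
            raise ValueError(
                f"backbone {self.name!r} returned shape {out.shape}, expected "
                f"({images.shape[0]}, {self.output_dim})"
            )
        return out


class SmallConvBackbone(ImageBackbone):
    """Trainable thumbnail backbone: avg-pool -> conv 3x3 -> dense.

    ``pool`` must divide both image dimensions.  Cheap enough to train on
    a CPU while leaving the identity signal of the synthetic images intact.
    """

    trainable = True

    def __init__(self, image_shape: tuple[int, int], pool: int,
                 n_filters: int = 6, embed_dim: int = 256,
                 rng: np.random.Generator | None = None, name: str = "smallconv"):
        rng = rng or np.random.default_rng(0)
        H, W = image_shape
        self.name = name
        self.output_dim = embed_dim
        self.net = nn.Sequential(
            nn.AvgPool2D(pool),
            nn.Conv2DSame(n_filters, 3, rng),
            nn.ReLU(),
            nn.Flatten(),
            nn.Dense((H // pool) * (W // pool) * n_filters, embed_dim, rng),
            nn.ReLU(),
        )

    def embed(self, images, training=False):
        return self.net.forward(images, training=training)

    def params(self):
        return self.net.params()

    def backward(self, grad):
        self.net.backward(grad)


class EcgConvExtractor:
    """1-D conv (kernel ``kernel_size``) + ReLU + max over the 3 timesteps."""

    def __init__(self, kernel_size: int = 7, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.net = nn.Sequential(
            nn.Conv1DSame(kernel_size, rng),
            nn.ReLU(),
            nn.TimestepMax(),
        )

    def features(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        x = np.asarray(x, dtype=np.float64)
        if x.ndim == 2:
            x = x[None]
        if x.shape[1:] != (SEQUENCE_LENGTH, QRS_LENGTH):
            raise ValueError(
                f"expected sequences of shape ({SEQUENCE_LENGTH}, {QRS_LENGTH})"
            )
        return self.net.forward(x, training=training)

    def params(self):
        return self.net.params()

    def backward(self, grad):
        self.net.backward(grad)


def extract_ecg_features(seq: EcgSequence, extractor: EcgConvExtractor) -> FeatureVector:
    """Embed one 3x300 sequence as a single 300-d feature vector."""
    out = extractor.features(seq.complexes[None] if seq.complexes.ndim == 2
                             else seq.complexes)
    return FeatureVector(out[0], "ecg")


def extract_image_features(image: BiometricImage, backbone: ImageBackbone,
                           projection: nn.Dense) -> FeatureVector:
    """Backbone embedding followed by the learned affine projection to 300."""
    if projection.W.value.shape != (backbone.output_dim, FEATURE_DIM):
        raise ValueError(
            f"projection expects ({backbone.output_dim}, {FEATURE_DIM}) weights, "
            f"got {projection.W.value.shape}"
        )
    emb = backbone.embed(image.pixels[None])
    out = projection.forward(emb, training=False)
    return FeatureVector(out[0], image.modality)
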