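"""Data augmentation and the noise operators used in robustness tests.

Three noise operators mirror the robustness protocol: additive zero-mean
Gaussian noise on normalized QRS sequences (default sd 0.1), and random
pixel blackout on images (default 97% of face pixels, 5% of fingerprint
pixels).  All operators are pure functions of (input, parameters, seed).
Augmentation (rotation / translation / crop-and-resize) expands image
pools while preserving subject and gender labels.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from PIL import Image
from scipy import ndimage

from .ecg import EcgSequence

FACE_SHAPE = (200, 180)        # rows x cols: 180 x 200 px, portrait
FINGERPRINT_SHAPE = (96, 96)

DEFAULT_ECG_SIGMA = 0.1
DEFAULT_FACE_BLACKOUT = 0.97
DEFAULT_FINGER_BLACKOUT = 0.05


@dataclass
class BiometricImage:
    """A grayscale image with modality tag and identity labels, values in [0, 1]."""

    pixels: np.ndarray
    modality: str                      # "face" | "fingerprint"
    subject_id: str = ""
    gender: str | None = None

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2 or min(self.pixels.shape) == 0:
            raise ValueError("pixels must be a non-empty 2-D array")
        if self.modality not in ("face", "fingerprint"):
            raise ValueError(f"unknown modality {self.modality!r}")


@dataclass
class NoiseSpec:
    """Noise levels for the three modalities plus the RNG seed."""

    ecg_sigma: float = DEFAULT_ECG_SIGMA
    face_blackout_fraction: float = DEFAULT_FACE_BLACKOUT
    fingerprint_blackout_fraction: float = DEFAULT_FINGER_BLACKOUT
    seed: int = 0

    def __post_init__(self):
        if self.ecg_sigma < 0:
            raise ValueError("ecg_sigma must be >= 0")
        for f in (self.face_blackout_fraction, self.fingerprint_blackout_fraction):
            if not 0.0 <= f <= 1.0:
                raise ValueError("blackout fractions must lie in [0, 1]")

    @classmethod
    def silent(cls) -> "NoiseSpec":
        return cls(ecg_sigma=0.0, face_blackout_fraction=0.0,
                   fingerprint_blackout_fraction=0.0)

    @property
    def is_silent(self) -> bool:
        return (self.ecg_sigma == 0.0 and self.face_blackout_fraction == 0.0
                and self.fingerprint_blackout_fraction == 0.0)


def add_gaussian_noise(seq: EcgSequence, sigma: float, seed: int) -> EcgSequence:
    """Add i.i.d. zero-mean Gaussian noise to a normalized sequence.

    Values are NOT re-clipped to [0, 1]; the noisy sequence can exceed the
    normalized range, matching how the robustness figures display it.
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if sigma == 0:
        return EcgSequence(seq.complexes.copy(), seq.subject_id, seq.gender)
    rng = np.random.default_rng(seed)
    noisy = seq.complexes + rng.normal(0.0, sigma, size=seq.complexes.shape)
    return EcgSequence(noisy, seq.subject_id, seq.gender)


def occlude_pixels(image: BiometricImage, fraction: float, seed: int) -> BiometricImage:
    """Set exactly ``round(fraction * n_pixels)`` distinct pixels to black.

    Positions are drawn uniformly without replacement; the count is exact,
    not expected.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must lie in [0, 1]")
    px = image.pixels.copy()
    n = px.size
    k = int(np.rint(fraction * n))
    if k > 0:
        rng = np.random.default_rng(seed)
        flat = rng.choice(n, size=k, replace=False)
        px.reshape(-1)[flat] = 0.0
    return replace(image, pixels=px)


def augment_image(
    image: BiometricImage,
    rotation_deg: float = 10.0,
    translate_frac: float = 0.05,
    crop_range: tuple[float, float] = (0.9, 1.0),
    seed: int = 0,
    order: int = 1,
) -> BiometricImage:
    """Random rotation, translation and centre-crop-then-resize.

    Angles are drawn uniformly in ±``rotation_deg``, shifts uniformly in
    ±``translate_frac`` of each dimension, and the crop fraction uniformly
    in ``crop_range``; the crop is resized back to the original shape so
    the output always has the modality's canonical size.  Labels are
    preserved.  ``order`` selects the interpolation (0 nearest, 1 linear).
    """
    lo, hi = crop_range
    if not (0.0 < lo <= hi <= 1.0):
        raise ValueError("crop_range must satisfy 0 < lo <= hi <= 1")
    rng = np.random.default_rng(seed)
    angle = rng.uniform(-rotation_deg, rotation_deg)
    h, w = image.pixels.shape
    dy = rng.uniform(-translate_frac, translate_frac) * h
    dx = rng.uniform(-translate_frac, translate_frac) * w
    crop = rng.uniform(lo, hi)

    px = image.pixels
    if angle != 0.0:
        px = ndimage.rotate(px, angle, reshape=False, order=order, mode="nearest")
    if dy != 0.0 or dx != 0.0:
        px = ndimage.shift(px, (dy, dx), order=order, mode="nearest")
    if crop < 1.0:
        ch, cw = max(1, int(round(h * crop))), max(1, int(round(w * crop)))
        y0, x0 = (h - ch) // 2, (w - cw) // 2
        region = px[y0 : y0 + ch, x0 : x0 + cw]
        px = ndimage.zoom(region, (h / ch, w / cw), order=max(order, 1))
        px = px[:h, :w]
        if px.shape != (h, w):  # zoom can undershoot by one pixel
            px = np.pad(px, ((0, h - px.shape[0]), (0, w - px.shape[1])), mode="edge")
    return replace(image, pixels=px)


def rotate_image(image: BiometricImage, angle_deg: float, order: int = 0) -> BiometricImage:
    """Deterministic rotation about the image centre (no resize)."""
    px = ndimage.rotate(image.pixels, angle_deg, reshape=False, order=order,
                        mode="nearest")
    return replace(image, pixels=px)


def apply_noise_to_arrays(
    ecg: np.ndarray,
    face: np.ndarray,
    finger: np.ndarray,
    spec: NoiseSpec,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised noise application to stacked dataset arrays.

    ``ecg`` (N, 3, 300), ``face`` (N, H, W), ``finger`` (N, h, w).  Each
    sample's occlusion mask uses an exact pixel count, seeded per sample
    from ``spec.seed`` so the operation is reproducible.
    """
    rng = np.random.default_rng(spec.seed)
    ecg_out = ecg.copy()
    if spec.ecg_sigma > 0:
        ecg_out += rng.normal(0.0, spec.ecg_sigma, size=ecg.shape)

    def _occlude_stack(stack: np.ndarray, fraction: float) -> np.ndarray:
        out = stack.copy()
        if fraction <= 0:
            return out
        n = stack[0].size
        k = int(np.rint(fraction * n))
        for i in range(len(out)):
            flat = rng.choice(n, size=k, replace=False)
            out[i].reshape(-1)[flat] = 0.0
        return out

    face_out = _occlude_stack(face, spec.face_blackout_fraction)
    finger_out = _occlude_stack(finger, spec.fingerprint_blackout_fraction)
    return ecg_out, face_out, finger_out


def save_image(image: BiometricImage, path: str | Path) -> None:
    arr = np.clip(image.pixels, 0.0, 1.0)
    Image.fromarray((arr * 255).astype(np.uint8)).save(path)


def load_image(path: str | Path, modality: str, subject_id: str = "",
               gender: str | None = None) -> BiometricImage:
    arr = np.asarray(Image.open(path).convert("L"), dtype=np.float64) / 255.0
    return BiometricImage(arr, modality, subject_id, gender)
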