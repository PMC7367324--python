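"""Virtual (chimeric) multimodal subjects, triplets and data splits.

Real multimodal cohorts with ECG, face and fingerprint from the same
person are not publicly available, so identities are assembled by
pairing sources across mutually exclusive single-modality pools under
the independence assumption: a face identity is matched with an ECG
identity of the same gender within the teens-to-thirties age band, and a
fingerprint identity is assigned uniformly at random — each source
identity used at most once.  Per virtual subject, the per-modality
sample pools (expanded by augmentation where needed) are paired into
(ECG, face, fingerprint) triplets without replacement, and triplets are
split 70/10/20 into train/validation/test stratified by subject, with
k-fold cross-validation folds (k = 8 by default) over the train+val pool.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .ecg import EcgSequence, record_to_sequences
from .noise import BiometricImage, augment_image

AGE_BAND = (13, 39)  # "teens to thirties"


class CapacityError(ValueError):
    """Raised when a source pool cannot supply enough compatible identities."""


@dataclass
class VirtualSubject:
    subject_id: int
    gender: str
    ecg_source: str
    face_source: str
    fingerprint_source: str
    age_band: str = "teens-thirties"


@dataclass
class TripletSample:
    """One (ECG sequence, face image, fingerprint image) training instance."""

    ecg: np.ndarray          # (3, 300)
    face: np.ndarray         # (200, 180)
    fingerprint: np.ndarray  # (96, 96)
    id_label: int
    gender_label: int        # 1 = male, 0 = female
    subject_id: int = -1

    def __post_init__(self):
        if self.subject_id == -1:
            self.subject_id = self.id_label


@dataclass
class SplitSpec:
    train_fraction: float = 0.7
    val_fraction: float = 0.1
    test_fraction: float = 0.2
    k_folds: int = 8
    seed: int = 0

    def __post_init__(self):
        total = self.train_fraction + self.val_fraction + self.test_fraction
        if abs(total - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")
        if self.k_folds < 2:
            raise ValueError("k_folds must be >= 2")


@dataclass
class Splits:
    """Index partitions into the triplet list."""

    train: np.ndarray
    val: np.ndarray
    test: np.ndarray
    folds: list[np.ndarray] = field(default_factory=list)  # partition of train+val


def match_virtual_subjects(ecg_pool: list[dict], face_pool: list[dict],
                           fingerprint_pool: list[dict], n_subjects: int,
                           seed: int = 0) -> list[VirtualSubject]:
    """Pair face identities with gender/age-compatible ECG identities.

    Pool entries are metadata dicts: ECG entries carry ``id``, ``gender``
    and ``age``; face entries ``id`` and ``gender``; fingerprint entries
    ``id``.  Fingerprints are assigned uniformly at random without
    replacement.  Raises :class:`CapacityError` naming the binding pool
    when compatible sources run out.
    """
    rng = np.random.default_rng(seed)
    if n_subjects > len(face_pool):
        raise CapacityError(
            f"face pool has {len(face_pool)} identities, need {n_subjects}")
    if n_subjects > len(fingerprint_pool):
        raise CapacityError(
            f"fingerprint pool has {len(fingerprint_pool)} identities, "
            f"need {n_subjects}")

    faces = [face_pool[i] for i in rng.permutation(len(face_pool))]
    ecg_by_gender: dict[str, list[dict]] = {"male": [], "female": []}
    for e in ecg_pool:
        if AGE_BAND[0] <= int(e["age"]) <= AGE_BAND[1]:
            ecg_by_gender[e["gender"]].append(e)
    for g in ecg_by_gender:
        pool = ecg_by_gender[g]
        ecg_by_gender[g] = [pool[i] for i in rng.permutation(len(pool))]

    fingerprints = [fingerprint_pool[i] for i in rng.permutation(len(fingerprint_pool))]

    subjects: list[VirtualSubject] = []
    for k in range(n_subjects):
        face = faces[k]
        gender = face["gender"]
        if not ecg_by_gender[gender]:
            raise CapacityError(
                f"ECG pool exhausted: no unused {gender} identity in the "
                f"{AGE_BAND[0]}-{AGE_BAND[1]} age band for virtual subject {k}")
        ecg = ecg_by_gender[gender].pop()
        subjects.append(VirtualSubject(k, gender, ecg["id"], face["id"],
                                       fingerprints[k]["id"]))
    return subjects


def expand_image_pool(images: list[BiometricImage], n: int,
                      seed: int = 0) -> list[BiometricImage]:
    """Grow an image pool to ``n`` samples by rotation/translation/crop."""
    if not images:
        raise ValueError("cannot expand an empty image pool")
    out = list(images[:n])
    rng = np.random.default_rng(seed)
    i = 0
    while len(out) < n:
        base = images[i % len(images)]
        out.append(augment_image(base, seed=int(rng.integers(0, 2**31 - 1))))
        i += 1
    return out


def expand_ecg_pool(records: list, n: int, seed: int = 0) -> list[EcgSequence]:
    """Build ``n`` sequences by drawing 3-beat combinations across records.

    Consecutive grouping of a 20 s record yields only ~8 sequences;
    drawing unordered beat triples (order carries no identity signal)
    expands the pool combinatorially.
    """
    rng = np.random.default_rng(seed)
    sequences: list[EcgSequence] = []
    per_record = int(np.ceil(n / max(len(records), 1)))
    for rec in records:
        sequences.extend(
            record_to_sequences(rec, mode="random", n_sequences=per_record, rng=rng))
    return sequences[:n]


def build_triplets(subject: VirtualSubject,
                   ecg_samples: list[EcgSequence],
                   face_samples: list[BiometricImage],
                   fingerprint_samples: list[BiometricImage],
                   n_triplets: int = 400, seed: int = 0) -> list[TripletSample]:
    """Pair per-modality samples into exactly ``n_triplets`` triplets.

    Each modality contributes a without-replacement random permutation of
    its pool, so every sample is used at most once (exactly once when the
    pool size equals ``n_triplets``).
    """
    for name, pool in (("ecg", ecg_samples), ("face", face_samples),
                       ("fingerprint", fingerprint_samples)):
        if len(pool) < n_triplets:
            raise ValueError(
                f"subject {subject.subject_id}: only {len(pool)} {name} samples "
                f"for {n_triplets} triplets — increase the augmentation factor")
    rng = np.random.default_rng(seed)
    idx = {name: rng.permutation(len(pool))[:n_triplets]
           for name, pool in (("ecg", ecg_samples), ("face", face_samples),
                              ("fingerprint", fingerprint_samples))}
    gender_label = 1 if subject.gender == "male" else 0
    return [
        TripletSample(
            ecg_samples[idx["ecg"][i]].complexes,
            face_samples[idx["face"][i]].pixels,
            fingerprint_samples[idx["fingerprint"][i]].pixels,
            subject.subject_id, gender_label,
        )
        for i in range(n_triplets)
    ]


def split_dataset(triplets: list[TripletSample], spec: SplitSpec) -> Splits:
    """Stratified-by-subject 70/10/20 split plus k folds over train+val.

    Every subject appears in all three partitions (closed-set
    identification requires each identity to be enrolled in training);
    fractions are exact to one sample per subject.  The k folds partition
    the train+val pool disjointly and exhaustively.
    """
    by_subject: dict[int, list[int]] = {}
    for i, t in enumerate(triplets):
        by_subject.setdefault(t.subject_id, []).append(i)
    rng = np.random.default_rng(spec.seed)
    train, val, test = [], [], []
    for sid in sorted(by_subject):
        idx = np.array(by_subject[sid])
        idx = idx[rng.permutation(len(idx))]
        n = len(idx)
        n_test = int(round(spec.test_fraction * n))
        n_val = int(round(spec.val_fraction * n))
        if n - n_test - n_val < 1:
            raise ValueError(f"subject {sid}: too few triplets ({n}) to split")
        test.extend(idx[:n_test])
        val.extend(idx[n_test : n_test + n_val])
        train.extend(idx[n_test + n_val :])
    trainval = np.array(sorted(train + val))
    shuffled = trainval[rng.permutation(len(trainval))]
    folds = [np.sort(shuffled[f :: spec.k_folds]) for f in range(spec.k_folds)]
    return Splits(np.sort(np.array(train, dtype=int)),
                  np.sort(np.array(val, dtype=int)),
                  np.sort(np.array(test, dtype=int)), folds)


def subjects_to_manifest(subjects: list[VirtualSubject]) -> "pd.DataFrame":
    """Subject manifest as a DataFrame (written as CSV by the CLI)."""
    import pandas as pd

    return pd.DataFrame(
        [{"subject_id": s.subject_id, "gender": s.gender,
          "ecg_source": s.ecg_source, "face_source": s.face_source,
          "fingerprint_source": s.fingerprint_source, "age_band": s.age_band}
         for s in subjects]
    )
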