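"""Training/evaluation engine and the four experiment protocols.

``build_dataset`` runs the full data path: synthetic source pools ->
virtual-subject matching -> per-subject sample expansion -> triplets ->
stratified 70/10/20 split with k folds.  ``train`` fits the multitask
network with Adam and early stopping on the validation metric (mean of
the available task accuracies); ``evaluate`` scores a held-out set,
optionally under the configured noise.  On top of these sit the four
protocols: modality ablation (7 subsets), single- vs multitask, the
clean/noisy matrix, and feature- vs score-level fusion.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import asdict, dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

from .fusion import FusionSpec, score_fuse
from .losses import LossWeights, grid_search_weights
from .model import MultimodalNet
from .nn import Adam
from .noise import NoiseSpec, apply_noise_to_arrays
from .synthetic import GeneratorConfig, generate_cohort
from .virtual import (SplitSpec, Splits, build_triplets, expand_ecg_pool,
                      expand_image_pool, match_virtual_subjects, split_dataset)

logger = logging.getLogger(__name__)

MODALITY_SUBSETS = (
    ("ecg",), ("face",), ("fingerprint",),
    ("ecg", "face"), ("ecg", "fingerprint"), ("face", "fingerprint"),
    ("ecg", "face", "fingerprint"),
)
# score-level weightings: equal, then 0.5 emphasis rotated over modalities
SCORE_WEIGHTINGS = (
    (1 / 3, 1 / 3, 1 / 3),
    (0.5, 0.25, 0.25),
    (0.25, 0.5, 0.25),
    (0.25, 0.25, 0.5),
)


@dataclass
class ExperimentConfig:
    modalities: tuple[str, ...] = ("ecg", "face", "fingerprint")
    tasks: tuple[str, ...] = ("id", "gender")
    fusion: FusionSpec = field(default_factory=FusionSpec)
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    noise_train: bool = True
    noise_train_fraction: float = 0.5  # fraction of train samples noise-augmented
    noise_test: bool = True
    loss_weights: LossWeights = field(default_factory=LossWeights)
    split: SplitSpec = field(default_factory=SplitSpec)
    n_subjects: int = 10
    triplets_per_subject: int = 60
    records_per_subject: int = 2
    images_per_subject: int = 10
    gender_ratio: float = 0.5
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    epochs: int = 40
    batch_size: int = 32
    lr: float = 1e-3
    patience: int = 8
    embed_dim: int = 128
    seed: int = 0

    def __post_init__(self):
        if not self.modalities:
            raise ValueError("need at least one modality")
        if not self.tasks:
            raise ValueError("need at least one task")

    def config_hash(self) -> str:
        return hashlib.md5(self.to_yaml().encode()).hexdigest()[:12]

    def to_yaml(self) -> str:
        return yaml.safe_dump(asdict(self), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "ExperimentConfig":
        raw = yaml.safe_load(text) or {}
        for key, typ in (("fusion", FusionSpec), ("noise", NoiseSpec),
                         ("loss_weights", LossWeights), ("split", SplitSpec),
                         ("generator", GeneratorConfig)):
            if key in raw and isinstance(raw[key], dict):
                raw[key] = typ(**raw[key])
        for key in ("modalities", "tasks"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


@dataclass
class MultimodalDataset:
    """Stacked triplet arrays plus split indices."""

    ecg: np.ndarray          # (N, 3, 300)
    face: np.ndarray         # (N, 200, 180)
    fingerprint: np.ndarray  # (N, 96, 96)
    id_labels: np.ndarray
    gender_labels: np.ndarray
    splits: Splits
    n_classes: int

    def arrays(self, idx: np.ndarray, modalities) -> dict[str, np.ndarray]:
        full = {"ecg": self.ecg, "face": self.face, "fingerprint": self.fingerprint}
        return {m: full[m][idx] for m in modalities}


@dataclass
class EvalReport:
    id_accuracy: float | None
    gender_accuracy: float | None
    n: int
    meta: dict = field(default_factory=dict)

    def metric(self) -> float:
        vals = [a for a in (self.id_accuracy, self.gender_accuracy) if a is not None]
        return float(np.mean(vals))


def build_dataset(config: ExperimentConfig) -> MultimodalDataset:
    """Cohort -> virtual subjects -> triplets -> splits, fully seeded."""
    rng = np.random.default_rng(config.seed)
    sub = lambda: int(rng.integers(0, 2**31 - 1))
    pools = generate_cohort(
        config.n_subjects, config.gender_ratio,
        records_per_subject=config.records_per_subject,
        faces_per_subject=config.images_per_subject,
        fingerprints_per_subject=config.images_per_subject,
        seed=sub(), cfg=config.generator,
    )
    ecg_meta = [{k: e[k] for k in ("id", "gender", "age")} for e in pools.ecg_pool]
    face_meta = [{k: f[k] for k in ("id", "gender")} for f in pools.face_pool]
    fing_meta = [{"id": p["id"]} for p in pools.fingerprint_pool]
    subjects = match_virtual_subjects(ecg_meta, face_meta, fing_meta,
                                      config.n_subjects, seed=sub())

    ecg_by_id = {e["id"]: e for e in pools.ecg_pool}
    face_by_id = {f["id"]: f for f in pools.face_pool}
    fing_by_id = {p["id"]: p for p in pools.fingerprint_pool}

    triplets = []
    n = config.triplets_per_subject
    for s in subjects:
        ecg_samples = expand_ecg_pool(ecg_by_id[s.ecg_source]["records"], n, sub())
        face_samples = expand_image_pool(face_by_id[s.face_source]["images"], n, sub())
        fing_samples = expand_image_pool(fing_by_id[s.fingerprint_source]["images"],
                                         n, sub())
        triplets.extend(build_triplets(s, ecg_samples, face_samples, fing_samples,
                                       n_triplets=n, seed=sub()))

    split_spec = replace(config.split, seed=sub())
    splits = split_dataset(triplets, split_spec)
    return MultimodalDataset(
        np.stack([t.ecg for t in triplets]),
        np.stack([t.face for t in triplets]),
        np.stack([t.fingerprint for t in triplets]),
        np.array([t.id_label for t in triplets]),
        np.array([t.gender_label for t in triplets]),
        splits, n_classes=config.n_subjects,
    )


def _check_no_leakage(splits: Splits) -> None:
    tr, va, te = set(splits.train), set(splits.val), set(splits.test)
    if tr & va or tr & te or va & te:
        raise AssertionError("train/val/test partitions overlap")


def _noisy(arrays: dict[str, np.ndarray], spec: NoiseSpec, seed: int):
    """Apply the configured noise to whichever modalities are present."""
    if spec.is_silent:
        return arrays
    B = len(next(iter(arrays.values())))
    zeros3 = np.zeros((B, 3, 300))
    zeros_f = np.zeros((B, 2, 2))
    e, f, p = apply_noise_to_arrays(
        arrays.get("ecg", zeros3), arrays.get("face", zeros_f),
        arrays.get("fingerprint", zeros_f), replace(spec, seed=seed))
    out = dict(arrays)
    for name, val in (("ecg", e), ("face", f), ("fingerprint", p)):
        if name in arrays:
            out[name] = val
    return out


def _accuracy(model: MultimodalNet, arrays, id_labels, gender_labels,
              batch_size: int = 256):
    n = len(id_labels)
    id_hits = 0
    gender_hits = 0
    for lo in range(0, n, batch_size):
        sl = slice(lo, min(lo + batch_size, n))
        sub = {m: a[sl] for m, a in arrays.items()}
        id_p, g_p = model.predict(sub)
        if id_p is not None:
            id_hits += int(np.sum(np.argmax(id_p, axis=1) == id_labels[sl]))
        if g_p is not None:
            gender_hits += int(np.sum((g_p >= 0.5).astype(int) == gender_labels[sl]))
    id_acc = 100.0 * id_hits / n if model.id_head is not None else None
    g_acc = 100.0 * gender_hits / n if model.gender_head is not None else None
    return id_acc, g_acc


def train(config: ExperimentConfig, dataset: MultimodalDataset):
    """Fit the network; returns (model, per-epoch log DataFrame).

    Training uses the train split (optionally noise-augmented), early
    stopping tracks the validation metric under the same conditions the
    test set will use, and the best-epoch parameters are restored.
    """
    _check_no_leakage(dataset.splits)
    rng = np.random.default_rng(config.seed + 1)
    model = MultimodalNet(dataset.n_classes, config.modalities, config.tasks,
                          seed=config.seed, embed_dim=config.embed_dim)
    opt = Adam(model.params(), lr=config.lr)

    tr_idx = dataset.splits.train
    va_idx = dataset.splits.val
    tr_arrays = dataset.arrays(tr_idx, config.modalities)
    va_arrays = dataset.arrays(va_idx, config.modalities)
    if config.noise_train and not config.noise.is_silent:
        # noise as augmentation: corrupt a seeded fraction of the training
        # rows so the model sees both clean and degraded inputs
        frac = config.noise_train_fraction
        noisy_all = _noisy(tr_arrays, config.noise, config.seed + 11)
        sel_rng = np.random.default_rng(config.seed + 17)
        k = int(round(frac * len(tr_idx)))
        sel = sel_rng.choice(len(tr_idx), size=k, replace=False)
        for m in tr_arrays:
            mixed = tr_arrays[m].copy()
            mixed[sel] = noisy_all[m][sel]
            tr_arrays[m] = mixed
    if config.noise_test:
        va_arrays = _noisy(va_arrays, config.noise, config.seed + 12)
    tr_id = dataset.id_labels[tr_idx]
    tr_gender = dataset.gender_labels[tr_idx].astype(np.float64)
    va_id = dataset.id_labels[va_idx]
    va_gender = dataset.gender_labels[va_idx]

    rows = []
    best_metric = -np.inf
    best_state = None
    since_best = 0
    n = len(tr_id)
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        l1_sum = l2_sum = 0.0
        for lo in range(0, n, config.batch_size):
            idx = order[lo : lo + config.batch_size]
            batch = {m: a[idx] for m, a in tr_arrays.items()}
            opt.zero_grad()
            model.forward(batch, training=True)
            l1, l2 = model.batch_losses(tr_id[idx], tr_gender[idx])
            if not np.isfinite(l1) or not np.isfinite(l2):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch} (L1={l1}, L2={l2})")
            model.backward(tr_id[idx] if model.id_head is not None else None,
                           tr_gender[idx] if model.gender_head is not None else None,
                           config.loss_weights)
            opt.step()
            l1_sum += l1 * len(idx)
            l2_sum += l2 * len(idx)
        l1_mean, l2_mean = l1_sum / n, l2_sum / n
        multitask = len(model.tasks) == 2
        ljoint = (config.loss_weights.w1 * l1_mean + config.loss_weights.w2 * l2_mean
                  if multitask else (l1_mean + l2_mean))
        va_id_acc, va_g_acc = _accuracy(model, va_arrays, va_id, va_gender)
        metric = float(np.mean([a for a in (va_id_acc, va_g_acc) if a is not None]))
        rows.append({"epoch": epoch, "l1": l1_mean, "l2": l2_mean,
                     "l_joint": ljoint, "val_id_acc": va_id_acc,
                     "val_gender_acc": va_g_acc, "val_metric": metric})
        logger.info("epoch %d L1=%.4f L2=%.4f joint=%.4f val=%.2f",
                    epoch, l1_mean, l2_mean, ljoint, metric)
        if metric > best_metric + 1e-9:
            best_metric = metric
            best_state = model.state()
            since_best = 0
        else:
            if metric >= best_metric - 1e-9:
                # tie on a small validation set: keep the more-trained state
                best_state = model.state()
            since_best += 1
            if since_best >= config.patience:
                break
    if best_state is not None:
        model.load_state(best_state)
    return model, pd.DataFrame(rows)


def evaluate(model: MultimodalNet, dataset: MultimodalDataset,
             indices: np.ndarray | None = None,
             noise: NoiseSpec | None = None,
             config: ExperimentConfig | None = None) -> EvalReport:
    """Score a held-out index set; ``noise=None`` evaluates clean."""
    if indices is None:
        indices = dataset.splits.test
    if len(indices) == 0:
        raise ValueError("empty evaluation set")
    arrays = dataset.arrays(indices, model.modalities)
    seed = (config.seed if config else 0) + 13
    if noise is not None and not noise.is_silent:
        arrays = _noisy(arrays, noise, seed)
    id_acc, g_acc = _accuracy(model, arrays, dataset.id_labels[indices],
                              dataset.gender_labels[indices])
    meta = {"noise": asdict(noise) if noise else None,
            "config_hash": config.config_hash() if config else None}
    return EvalReport(id_acc, g_acc, len(indices), meta)


def _train_eval(config: ExperimentConfig, dataset: MultimodalDataset,
                noise_eval: bool):
    model, _ = train(config, dataset)
    noise = config.noise if (noise_eval and config.noise_test) else None
    return model, evaluate(model, dataset, noise=noise, config=config)


def run_modality_ablation(config: ExperimentConfig,
                          dataset: MultimodalDataset) -> pd.DataFrame:
    """Train/evaluate all 7 non-empty modality subsets (both tasks)."""
    rows = []
    for subset in MODALITY_SUBSETS:
        cfg = replace(config, modalities=subset)
        _, report = _train_eval(cfg, dataset, noise_eval=True)
        rows.append({"ecg": "ecg" in subset, "face": "face" in subset,
                     "fingerprint": "fingerprint" in subset,
                     "id_accuracy": report.id_accuracy,
                     "gender_accuracy": report.gender_accuracy})
    return pd.DataFrame(rows)


def run_task_comparison(config: ExperimentConfig,
                        dataset: MultimodalDataset) -> pd.DataFrame:
    """ID-only, gender-only and multitask runs, with parameter counts."""
    rows = []
    for tasks in (("id",), ("gender",), ("id", "gender")):
        cfg = replace(config, tasks=tasks)
        model, report = _train_eval(cfg, dataset, noise_eval=True)
        rows.append({"tasks": "+".join(tasks),
                     "id_accuracy": report.id_accuracy,
                     "gender_accuracy": report.gender_accuracy,
                     "n_params": model.n_params})
    return pd.DataFrame(rows)


def run_noise_matrix(config: ExperimentConfig, dataset: MultimodalDataset,
                     subsets=None) -> pd.DataFrame:
    """Clean and noisy evaluation for each modality subset (one model each)."""
    subsets = subsets or (("ecg",), ("face",), ("fingerprint",),
                          ("ecg", "face", "fingerprint"))
    rows = []
    for subset in subsets:
        cfg = replace(config, modalities=subset)
        model, _ = train(cfg, dataset)
        for noisy in (False, True):
            report = evaluate(model, dataset,
                              noise=cfg.noise if noisy else None, config=cfg)
            rows.append({"modalities": "+".join(subset), "noisy": noisy,
                         "id_accuracy": report.id_accuracy,
                         "gender_accuracy": report.gender_accuracy})
    return pd.DataFrame(rows)


def run_fusion_comparison(config: ExperimentConfig,
                          dataset: MultimodalDataset) -> pd.DataFrame:
    """Feature-level fusion vs score-level sum/product/max x 4 weightings.

    Score-level runs train three unimodal classifiers, then combine their
    test-set probabilities; gender sigmoid outputs are fused as
    two-class (female, male) probability vectors and thresholded on the
    male-class probability.
    """
    rows = []
    cfg_feat = replace(config, modalities=("ecg", "face", "fingerprint"))
    _, report = _train_eval(cfg_feat, dataset, noise_eval=True)
    rows.append({"level": "feature", "rule": None, "weights": None,
                 "id_accuracy": report.id_accuracy,
                 "gender_accuracy": report.gender_accuracy})

    te = dataset.splits.test
    id_true = dataset.id_labels[te]
    gender_true = dataset.gender_labels[te]
    per_modality_probs = {}
    for m in ("ecg", "face", "fingerprint"):
        cfg = replace(config, modalities=(m,))
        model, _ = train(cfg, dataset)
        arrays = dataset.arrays(te, (m,))
        if config.noise_test:
            arrays = _noisy(arrays, config.noise, config.seed + 13)
        id_p, g_p = model.predict(arrays)
        per_modality_probs[m] = (id_p, np.stack([1 - g_p, g_p], axis=1))

    mods = ["ecg", "face", "fingerprint"]
    id_list = [per_modality_probs[m][0] for m in mods]
    g_list = [per_modality_probs[m][1] for m in mods]
    for rule in ("sum", "product", "max"):
        for weights in SCORE_WEIGHTINGS:
            spec = FusionSpec(level="score", rule=rule, weights=weights)
            id_fused = score_fuse(id_list, spec, mods)
            g_fused = score_fuse(g_list, spec, mods)
            id_acc = 100.0 * np.mean(np.argmax(id_fused, axis=1) == id_true)
            g_acc = 100.0 * np.mean((g_fused[:, 1] >= 0.5).astype(int) == gender_true)
            rows.append({"level": "score", "rule": rule,
                         "weights": tuple(round(w, 4) for w in weights),
                         "id_accuracy": float(id_acc),
                         "gender_accuracy": float(g_acc)})
    return pd.DataFrame(rows)


def grid_search_loss_weights(config: ExperimentConfig, dataset: MultimodalDataset,
                             grid=None) -> LossWeights:
    """Sweep (w1, 1-w1) candidates; metric = validation mean of task accuracies."""
    from .losses import DEFAULT_GRID

    grid = grid if grid is not None else DEFAULT_GRID

    def evaluate_fn(lw: LossWeights) -> float:
        cfg = replace(config, loss_weights=lw)
        model, _ = train(cfg, dataset)
        report = evaluate(model, dataset, indices=dataset.splits.val,
                          noise=cfg.noise if cfg.noise_test else None, config=cfg)
        return report.metric()

    return grid_search_weights(grid, evaluate_fn)
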