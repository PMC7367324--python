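# biofusion

Multimodal, multitask biometric identification: a tested pipeline that
fuses **ECG**, **face** and **fingerprint** data to jointly identify a
person (closed-set) and classify their gender, and that can be exercised
end to end on a fully synthetic multimodal cohort — no data downloads.

## Who this is for

Researchers and engineers studying multimodal biometric fusion: how much
a second or third modality buys under noise, whether a shared multitask
network beats independent single-task models, and how feature-level
fusion compares with score-level combination rules. The package is a
library plus a `biofusion` command-line tool.

## The model

Each modality is embedded into a common 300-dimensional feature space:

- **ECG** — records are resampled to 500 Hz; R peaks are detected
  (Pan–Tompkins-style band-pass → squaring → moving-window integration);
  a 300-sample window (150 each side of the R peak) is cropped and
  min-max normalized per beat; three QRS complexes form one input
  sequence *x*ₑ ∈ ℝ³ˣ³⁰⁰. A shared 1-D convolution maps each timestep to
  ℝ³⁰⁰ and an element-wise max over the three timesteps yields one
  300-vector (beat order carries no identity signal).
- **Face / fingerprint** — *x*_f (180×200 portrait) and *x*_p (96×96)
  pass through an image backbone (interface; a small trainable
  convolutional network by default, or any frozen external embedder such
  as a 2048-d residual-network average-pool extractor) followed by a
  learned affine projection to ℝ³⁰⁰.

**Feature-level fusion.** Each modality's feature is batch-normalized
using statistics over *present* samples only, absent modalities are
zero-filled (and excluded from the BN statistics), and the three blocks
are concatenated in fixed order into a 900-vector, so one network serves
any subset of modalities. A shared trunk (512, 256 rectified units)
feeds two heads:

- identification: softmax(yᵢ) = exp(yᵢ)/Σⱼexp(yⱼ), loss
  L₂ = −Σᵢ yᵢ log ŷᵢ (categorical cross-entropy);
- gender: a single sigmoid logit, loss
  L₁ = −y log ŷ − (1−y) log(1−ŷ) (binary cross-entropy);
- multitask objective **L_joint = w₁·L₁ + w₂·L₂** with w₁ + w₂ = 1
  (default 0.5/0.5; a grid search over (w₁, 1−w₁) is provided).

**Score-level fusion.** Alternatively, three unimodal classifiers are
trained and their class-probability vectors combined with a sum
(Σ wₘ pₘ), product (∏ pₘ^wₘ, renormalized) or max (maxₘ wₘ pₘ,
renormalized) rule.

**Virtual subjects.** Because no public corpus pairs ECG, face and
fingerprint for the same person, identities are *chimeric*: a face
identity is matched with a gender- and age-compatible ECG identity
(teens-to-thirties band), a fingerprint identity is assigned at random,
each source used at most once. Per subject, augmented samples are paired
into (ECG, face, fingerprint) triplets and split 70/10/20 into
train/validation/test, stratified by subject, with 8-fold
cross-validation folds over train+val.

**Robustness protocol.** Gaussian noise (σ = 0.1) on normalized ECG
sequences, blackout of 97% of face pixels and 5% of fingerprint pixels
(exact counts, uniformly without replacement).

The synthetic cohort generator produces separable per-subject beat
morphologies, face geometries and ridge patterns, with gender-correlated
structure and realistic nuisance variation; see `docs/methods.md`.

## Worked example

```python
from biofusion import ExperimentConfig, build_dataset, train, evaluate

cfg = ExperimentConfig(n_subjects=6, triplets_per_subject=40, seed=0)
dataset = build_dataset(cfg)          # synthetic cohort -> triplets -> splits
model, log = train(cfg, dataset)      # trimodal multitask training
noisy = evaluate(model, dataset, noise=cfg.noise, config=cfg)
clean = evaluate(model, dataset, config=cfg)
print(f"noisy  ID accuracy: {noisy.id_accuracy:.1f}%  gender: {noisy.gender_accuracy:.1f}%")
print(f"clean  ID accuracy: {clean.id_accuracy:.1f}%  gender: {clean.gender_accuracy:.1f}%")
print(f"parameters: {model.n_params}")
```

prints

```
noisy  ID accuracy: 97.9%  gender: 100.0%
clean  ID accuracy: 95.8%  gender: 100.0%
parameters: 1147111
```

i.e. on a 6-subject synthetic cohort (48 held-out triplets) the trimodal
multitask model identifies ~98% of noisy test triplets and classifies
gender perfectly; accuracy on clean inputs is in the same range, showing
the noise-augmented training generalizes to both conditions.

The same experiments run from the shell — `biofusion simulate`,
`prepare-data`, `train`, `evaluate`, `ablate-modality`, `compare-tasks`,
`noise-matrix`, `compare-fusion` — each taking `--config <YAML>`,
`--seed`, and noise overrides (`--ecg-sigma`, `--face-blackout`,
`--finger-blackout`), writing CSV + JSON reports.

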