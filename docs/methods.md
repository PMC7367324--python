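# Methods

This note documents the modelling choices, the synthetic data the
package is validated on, and the numerical conventions. It states no
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## ECG preprocessing

Records are brought to 500 Hz with Fourier-method resampling
(`scipy.signal.resample`). Polyphase filtering was considered and
rejected: on a band-limited test signal its edge transients are ~5×10⁻³
while the Fourier method is exact to ~10⁻¹³, and ECG records here are
long enough that the periodicity assumption is harmless.

R peaks are found Pan–Tompkins-style: a 5–15 Hz second-order Butterworth
band-pass (zero-phase), squaring, a 150 ms moving-window integration,
peak picking at 25% of the integrated signal's 99th percentile with a
200 ms refractory period, then refinement to the band-passed maximum
within ±75 ms. The threshold is relative, so the detector is invariant
to overall gain; it is validated against the generator's ground-truth
peak positions (recall and precision ≥ 95% required).

Each beat window is `[r−150, r+150)` — 300 samples total. The window
length is fixed by the downstream contract (the ECG extractor consumes
length-300 timesteps); windows that would cross a record boundary are
skipped, not padded. Min-max normalization maps each window onto [0, 1];
a constant (flat-line) window maps to zeros rather than raising, so
artifactual segments degrade gracefully. Grouping into 3-beat sequences
is consecutive and non-overlapping by default (remainder dropped); a
`random` mode draws unordered beat triples, used to expand a record's
~8 consecutive sequences into arbitrarily many training samples — valid
because the feature extractor is timestep-permutation-invariant by
construction.

## Network and training

All layers are implemented in numpy with explicit backpropagation
(finite-difference-checked): there is no deep-learning framework
dependency. Architecture defaults:

| component | choice | rationale |
|---|---|---|
| ECG extractor | 1-D conv, kernel 7, same-padding, ReLU, max over timesteps | single-layer description; kernel biased to pass-through at init |
| image backbone | avg-pool thumbnail (face ÷10, fingerprint ÷6) → 3×3 conv (6 filters) → dense 128, ReLU | trainable on CPU; interface accepts any frozen external embedder |
| projection | dense to 300 per image modality | all modalities share the feature width |
| normalisation | per-modality masked batch-norm | absent samples excluded from statistics, outputs forced to zero |
| trunk | dense 512 → 256, ReLU | conventional two-layer fusion network |
| heads | softmax over N identities; 1 sigmoid logit for gender | gender threshold 0.5 |
| optimiser | Adam, lr 10⁻³, batch 32, ≤40 epochs, early stopping patience 8 | conventional defaults, all configurable |

The batch-norm running statistics are exponential moving averages
(momentum 0.1) that are bias-corrected at read time, exactly as Adam
corrects its moment estimates; without this, the few dozen updates of a
desk-scale run leave evaluation-mode statistics pulled toward their
initialisation. When successive epochs tie on the validation metric
(common with small validation sets), early stopping keeps the
most-recent tied state rather than the first.

The multitask loss is w₁·BCE + w₂·CCE with w₁ = w₂ = 0.5; predicted
probabilities are clipped to [10⁻¹², 1−10⁻¹²]. Single-task models omit
the other head entirely, which is what makes the parameter-economy
comparison (one joint model vs two single-task models) meaningful. The
weight grid search is exposed as a pure function over an injected
evaluation closure, with ties broken toward 0.5.

## Fusion conventions

Feature-level: concatenation order is fixed (ecg, face, fingerprint);
absent blocks are exactly zero. Score-level rules for weights wₘ summing
to one:

- sum: Σ wₘ pₘ (already normalized);
- product: ∏ pₘ^wₘ, renormalized — the geometric weighting is chosen so
  that equal weights recover the textbook product rule and identical
  inputs are a fixed point;
- max: element-wise max of wₘ pₘ, renormalized.

Weighted product/max rules have no single canonical definition; these
forms are declared, and the brute-force oracle in the test suite pins
them. When fewer than three modalities supply scores, their weights are
renormalized. A product of disjoint one-hot inputs would yield an
all-zero vector; the implementation falls back to uniform in that
degenerate case.

## Noise and augmentation

Noise operators are pure functions of (input, parameters, seed).
Defaults follow the robustness protocol: ECG Gaussian noise σ = 0.1
added *after* per-beat normalization and not re-clipped; face blackout
fraction 0.97 and fingerprint 0.05 with an **exact** pixel count
round(f·N), positions uniform without replacement. Image augmentation
(rotation ±10°, translation ±5%, crop 90–100% then resize back) is mild
and label-preserving; ranges are configurable.

Training applies noise to a seeded 50% of training rows
(`noise_train_fraction`), reading the protocol's noise as augmentation:
one model then serves both clean and noisy evaluation. Training
everything on fully noisy data instead (fraction 1.0) degrades clean
face evaluation through feature-distribution shift.

A note on one discretisation issue: rotating a centred disk by ±10° with
nearest-neighbour interpolation is not exactly the identity on a pixel
lattice — boundary pixels within rounding distance of the radius can
flip — so the rotation-invariance test asserts ≥99% pixel agreement
rather than equality.

## Synthetic cohort

The generator targets the statistical contract the pipeline assumes, not
physiological realism:

- **ECG**: per-subject beat templates as sums of Gaussian bumps (P, Q,
  R, S, T amplitudes/widths/offsets), repeated at a per-subject RR
  interval with 20 ms jitter, plus 0.03 mV white noise; 20 s at 500 Hz
  gives ≥ 15 beats (≈25 at 75 bpm). True R-peak positions are stored as
  metadata, making the detector testable against ground truth.
- **Face**: 180×200 portrait renders from per-subject geometry (head
  ellipse, eyes, brows, nose, mouth, hairline) with nuisance scale ±5%,
  lighting gain ±10% and translation ±3 px — emulating a subject
  stepping toward the camera. The nuisance level is calibrated so a
  nearest-centroid baseline on clean images still beats chance ≥ 5×
  (the generator's identifiability contract).
- **Fingerprint**: 96×96 oriented sinusoids with a per-subject low-order
  orientation field, frequency and phase; impressions vary by ±4°
  rotation, phase jitter and additive noise.

Gender couples to the R-wave amplitude and resting rate (ECG) and to
head aspect ratio and brow intensity (face), so gender is learnable from
either modality. Phenotypes are redrawn until a minimum pairwise
distance in normalised parameter space holds, guaranteeing distinct
identities. Everything is seed-deterministic.

What the generator does **not** emulate: ECG pathology and electrode
artifacts, facial appearance variation (expression, pose, hairstyle),
fingerprint minutiae, and sensor-specific noise. Passing tests therefore
demonstrate that the pipeline's machinery recovers identity and gender
from data with the assumed statistical structure; they are not evidence
about accuracy on real biometric corpora.

## Virtual-subject construction

Matching follows the chimeric-subject convention: faces drive the
pairing; an ECG identity of the same gender with age in [13, 39] is
drawn per face; fingerprints are assigned uniformly without replacement.
Capacity violations raise an error naming the binding pool. Splits are
stratified per subject (70/10/20 exact to one sample per subject) —
closed-set identification requires every identity in training — and the
8 cross-validation folds partition the train+val pool disjointly.
Triplet pairing uses independent without-replacement permutations per
modality.

## Problem sizes

Desk-scale defaults: 10 virtual subjects, 60 triplets per subject
(train 420 / val 60 / test 120); the backbone and trunk sizes above give
~1.15 M parameters. These sizes keep a full experiment (several
trainings) to a few minutes on one CPU while preserving every qualitative
comparison of interest; all counts scale through `ExperimentConfig`
(e.g. 58 subjects × 400 triplets for a full-scale virtual cohort).

## Known limitations

- The pretrained image-backbone adapter (`CallableBackbone`) is an
  interface only; no pretrained weights ship with the package.
- WFDB-format reading is not implemented; ECG I/O is plain delimited
  text with a JSON sidecar (plus the in-memory generator).
- Score-level fusion reuses the probability outputs of independently
  trained unimodal networks; no joint calibration is attempted.
- Accuracy is computed per test triplet; no per-subject vote
  aggregation, and no open-set verification (FAR/FRR) support.
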