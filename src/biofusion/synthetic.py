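"""Synthetic multimodal cohort generator.

Produces three mutually exclusive single-modality pools — ECG records,
face-like images and fingerprint-like images — with the statistical
structure the pipeline assumes: per-subject-distinctive signal (separable
identities), gender-correlated structure in the ECG and face pools, and
within-subject nuisance variation (RR jitter and sensor noise for ECG;
head scale, lighting and position for faces; rotation/phase jitter for
ridge patterns).  No physiological or dermatoglyphic realism is
attempted; the generator targets the statistical contract only.

All generation is seed-deterministic, and each artefact records its
latent ground truth (true R-peak positions, phenotype parameters) so
downstream stages can be checked against the truth that produced their
inputs.

Defaults mirror the recording conditions the pipeline is built around:
20 s single-lead ECG records digitised at 500 Hz with ~75 bpm resting
rates (at least 15 beats per record), 180x200 portrait face images and
96x96 fingerprint images.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .ecg import EcgRecord
from .noise import FACE_SHAPE, FINGERPRINT_SHAPE, BiometricImage

ECG_DURATION_S = 20.0
ECG_RATE = 500.0


@dataclass
class GeneratorConfig:
    """Difficulty knobs: spread between subjects vs nuisance within them.

    The defaults create a regime where each single modality is learnable
    but imperfect once the default test-time noise is applied, so that
    fusing modalities measurably helps — the regime the multimodal
    comparison experiments need.
    """

    ecg_noise_sd: float = 0.03          # mV, additive sensor noise on raw records
    rr_jitter_sd_s: float = 0.02        # per-beat RR jitter
    face_scale_var: float = 0.05        # head-scale nuisance, fraction of size
    face_lighting_var: float = 0.10     # multiplicative lighting gain spread
    face_shift_px: float = 3.0          # translation nuisance, pixels
    ridge_rotation_deg: float = 4.0     # fingerprint placement jitter
    ridge_noise_sd: float = 0.04
    between_subject_spread: float = 1.0 # scales per-subject parameter ranges
    min_phenotype_distance: float = 0.35


@dataclass
class SubjectPhenotype:
    """Latent per-subject parameters for all three modalities."""

    subject_id: str
    gender: str                          # "male" | "female"
    age: int
    ecg: dict = field(default_factory=dict)
    face: dict = field(default_factory=dict)
    ridge: dict = field(default_factory=dict)

    def param_vector(self) -> np.ndarray:
        vals = []
        for d in (self.ecg, self.face, self.ridge):
            vals.extend(float(v) for v in d.values())
        return np.asarray(vals)


def _draw_phenotype(sid: str, gender: str, age: int, rng: np.random.Generator,
                    cfg: GeneratorConfig) -> SubjectPhenotype:
    s = cfg.between_subject_spread
    male = gender == "male"
    # ECG beat template: Gaussian bumps (amplitude mV, centre offset s, width s)
    # relative to the R peak.  Gender couples to R amplitude and resting rate.
    ecg = {
        "p_amp": 0.10 + 0.10 * s * rng.random(),
        "p_off": -0.18 + 0.03 * s * rng.random(),
        "p_wid": 0.020 + 0.010 * s * rng.random(),
        "q_amp": -(0.08 + 0.10 * s * rng.random()),
        "r_amp": (1.05 if male else 0.80) + 0.25 * s * rng.random(),
        "r_wid": 0.010 + 0.006 * s * rng.random(),
        "s_amp": -(0.10 + 0.15 * s * rng.random()),
        "t_amp": 0.20 + 0.20 * s * rng.random(),
        "t_off": 0.22 + 0.06 * s * rng.random(),
        "t_wid": 0.050 + 0.025 * s * rng.random(),
        "rr_s": (0.74 if male else 0.80) + 0.10 * s * rng.random(),
    }
    # Face geometry on the 180x200 portrait canvas (fractions of H, W).
    # Gender couples to head aspect and brow intensity.
    face = {
        "head_ry": 0.30 + 0.06 * s * rng.random(),
        "head_rx": (0.26 if male else 0.22) + 0.05 * s * rng.random(),
        "head_int": 0.55 + 0.25 * s * rng.random(),
        "eye_dy": -0.06 - 0.04 * s * rng.random(),
        "eye_dx": 0.08 + 0.04 * s * rng.random(),
        "eye_r": 0.015 + 0.015 * s * rng.random(),
        "eye_int": 0.05 + 0.15 * s * rng.random(),
        "mouth_dy": 0.14 + 0.05 * s * rng.random(),
        "mouth_w": 0.06 + 0.05 * s * rng.random(),
        "mouth_int": 0.15 + 0.20 * s * rng.random(),
        "brow_int": (0.10 if male else 0.30) + 0.15 * s * rng.random(),
        "hair_frac": 0.10 + 0.10 * s * rng.random(),
    }
    # Fingerprint: low-order orientation field + ridge frequency/phase.
    ridge = {
        "theta0": rng.uniform(0, np.pi),
        "curve_x": 1.2 * s * (rng.random() - 0.5),
        "curve_y": 1.2 * s * (rng.random() - 0.5),
        "freq": 7.0 + 4.0 * s * rng.random(),   # ridges per image width
        "phase": rng.uniform(0, 2 * np.pi),
    }
    return SubjectPhenotype(sid, gender, age, ecg, face, ridge)


def generate_phenotypes(n_subjects: int, gender_ratio: float, seed: int,
                        cfg: GeneratorConfig | None = None,
                        prefix: str = "S",
                        ages: np.ndarray | None = None) -> list[SubjectPhenotype]:
    """Draw ``n_subjects`` phenotypes with a minimum pairwise separation.

    ``gender_ratio`` is the male fraction; counts are rounded so the split
    is exact.  Candidates closer than ``min_phenotype_distance`` (in
    normalised parameter space) to an accepted phenotype are redrawn.
    """
    cfg = cfg or GeneratorConfig()
    rng = np.random.default_rng(seed)
    n_male = int(round(gender_ratio * n_subjects))
    genders = ["male"] * n_male + ["female"] * (n_subjects - n_male)
    if ages is None:
        ages = rng.integers(16, 36, size=n_subjects)  # teens-to-thirties band
    accepted: list[SubjectPhenotype] = []
    vectors: list[np.ndarray] = []
    for i, g in enumerate(genders):
        sid = f"{prefix}{i:03d}"
        for attempt in range(200):
            ph = _draw_phenotype(sid, g, int(ages[i]), rng, cfg)
            v = ph.param_vector()
            if not vectors:
                break
            ref = np.stack(vectors)
            scale = np.maximum(np.abs(ref).mean(axis=0), 1e-9)
            d = np.sqrt((((ref - v) / scale) ** 2).mean(axis=1)).min()
            if d >= cfg.min_phenotype_distance:
                break
        accepted.append(ph)
        vectors.append(ph.param_vector())
    return accepted


def _gauss(t: np.ndarray, amp: float, off: float, wid: float) -> np.ndarray:
    return amp * np.exp(-0.5 * ((t - off) / wid) ** 2)


def generate_ecg_record(phenotype: SubjectPhenotype, seed: int,
                        duration_s: float = ECG_DURATION_S,
                        rate: float = ECG_RATE,
                        noise_sd: float | None = None,
                        rr_jitter_sd: float | None = None,
                        cfg: GeneratorConfig | None = None) -> EcgRecord:
    """Render one record: jittered beat train of Gaussian bumps + white noise.

    True R-peak sample indices are stored in ``record.meta['r_peaks']``.
    With ``noise_sd=0`` and ``rr_jitter_sd=0`` the record equals the
    deterministic template train exactly.
    """
    if duration_s <= 0 or rate <= 0:
        raise ValueError("duration and rate must be positive")
    cfg = cfg or GeneratorConfig()
    noise_sd = cfg.ecg_noise_sd if noise_sd is None else noise_sd
    rr_jitter_sd = cfg.rr_jitter_sd_s if rr_jitter_sd is None else rr_jitter_sd
    rng = np.random.default_rng(seed)
    e = phenotype.ecg
    n = int(round(duration_s * rate))
    t = np.arange(n) / rate
    x = np.zeros(n)

    beat_times = []
    tc = 0.4  # first beat placed clear of the record edge
    while tc <= duration_s - 0.4 + 1e-9:  # epsilon guards float accumulation
        beat_times.append(tc)
        tc += e["rr_s"] + (rng.normal(0.0, rr_jitter_sd) if rr_jitter_sd > 0 else 0.0)

    for bt in beat_times:
        dt = t - bt
        x += _gauss(dt, e["p_amp"], e["p_off"], e["p_wid"])
        x += _gauss(dt, e["q_amp"], -0.025, 0.008)
        x += _gauss(dt, e["r_amp"], 0.0, e["r_wid"])
        x += _gauss(dt, e["s_amp"], 0.025, 0.008)
        x += _gauss(dt, e["t_amp"], e["t_off"], e["t_wid"])
    if noise_sd > 0:
        x += rng.normal(0.0, noise_sd, size=n)

    r_peaks = [int(round(bt * rate)) for bt in beat_times]
    return EcgRecord(x, rate, phenotype.subject_id, "I",
                     {"gender": phenotype.gender, "age": phenotype.age,
                      "r_peaks": r_peaks})


def generate_face_image(phenotype: SubjectPhenotype, seed: int,
                        nuisance: bool = True,
                        cfg: GeneratorConfig | None = None) -> BiometricImage:
    """Render a 180x200 portrait face-like image from subject geometry.

    Nuisance draws emulate the capture conditions of a subject stepping
    toward the camera: head-scale variation, lighting variation and
    translated position.  ``nuisance=False`` renders the canonical image,
    identical across calls.
    """
    cfg = cfg or GeneratorConfig()
    rng = np.random.default_rng(seed)
    H, W = FACE_SHAPE
    f = phenotype.face
    if nuisance:
        scale = 1.0 + rng.uniform(-cfg.face_scale_var, cfg.face_scale_var)
        gain = 1.0 + rng.uniform(-cfg.face_lighting_var, cfg.face_lighting_var)
        sy = rng.uniform(-cfg.face_shift_px, cfg.face_shift_px)
        sx = rng.uniform(-cfg.face_shift_px, cfg.face_shift_px)
    else:
        scale, gain, sy, sx = 1.0, 1.0, 0.0, 0.0

    yy, xx = np.mgrid[0:H, 0:W]
    cy, cx = H * 0.52 + sy, W * 0.5 + sx
    u = (xx - cx) / (W * scale)   # normalised face coordinates
    v = (yy - cy) / (H * scale)

    img = np.full((H, W), 0.12)
    head = (u / f["head_rx"]) ** 2 + (v / f["head_ry"]) ** 2 <= 1.0
    img[head] = f["head_int"]
    hair = head & (v < -f["head_ry"] * (1.0 - 2 * f["hair_frac"]))
    img[hair] = 0.08
    for sgn in (-1.0, 1.0):
        eye = (u - sgn * f["eye_dx"]) ** 2 + (v - f["eye_dy"]) ** 2 <= f["eye_r"] ** 2
        img[eye] = f["eye_int"]
        brow = (np.abs(u - sgn * f["eye_dx"]) <= 1.6 * f["eye_r"]) & (
            np.abs(v - (f["eye_dy"] - 0.05)) <= 0.012)
        img[brow & head] = f["brow_int"]
    nose = (np.abs(u) <= 0.012) & (v > f["eye_dy"]) & (v < 0.08)
    img[nose & head] = f["head_int"] * 0.75
    mouth = (u / f["mouth_w"]) ** 2 + ((v - f["mouth_dy"]) / 0.02) ** 2 <= 1.0
    img[mouth & head] = f["mouth_int"]

    img = np.clip(img * gain, 0.0, 1.0)
    return BiometricImage(img, "face", phenotype.subject_id, phenotype.gender)


def generate_fingerprint_image(phenotype: SubjectPhenotype, seed: int,
                               nuisance: bool = True,
                               cfg: GeneratorConfig | None = None) -> BiometricImage:
    """Render a 96x96 oriented-sinusoid ridge pattern.

    The subject's low-order orientation field bends the ridges; nuisance
    draws add a small placement rotation, a phase shift and additive
    noise, emulating repeated impressions of one finger.
    """
    cfg = cfg or GeneratorConfig()
    rng = np.random.default_rng(seed)
    H, W = FINGERPRINT_SHAPE
    r = phenotype.ridge
    if nuisance:
        rot = np.deg2rad(rng.uniform(-cfg.ridge_rotation_deg, cfg.ridge_rotation_deg))
        dphase = rng.uniform(-0.6, 0.6)
        noise_sd = cfg.ridge_noise_sd
    else:
        rot, dphase, noise_sd = 0.0, 0.0, 0.0

    yy, xx = np.mgrid[0:H, 0:W]
    u = (xx - W / 2) / W
    v = (yy - H / 2) / H
    ur = u * np.cos(rot) - v * np.sin(rot)
    vr = u * np.sin(rot) + v * np.cos(rot)
    theta = r["theta0"] + r["curve_x"] * ur + r["curve_y"] * vr
    carrier = ur * np.cos(theta) + vr * np.sin(theta)
    img = 0.5 + 0.5 * np.sin(2 * np.pi * r["freq"] * carrier + r["phase"] + dphase)
    if noise_sd > 0:
        img = img + rng.normal(0.0, noise_sd, size=img.shape)
    img = np.clip(img, 0.0, 1.0)
    return BiometricImage(img, "fingerprint", phenotype.subject_id, phenotype.gender)


@dataclass
class CohortPools:
    """Mutually exclusive single-modality source pools + latent truth."""

    ecg_pool: list[dict]          # {id, gender, age, records: [EcgRecord]}
    face_pool: list[dict]         # {id, gender, images: [BiometricImage]}
    fingerprint_pool: list[dict]  # {id, images: [BiometricImage]}
    manifest: dict                # latent phenotypes and generation parameters


def generate_cohort(n_subjects: int, gender_ratio: float = 0.5,
                    records_per_subject: int = 3,
                    faces_per_subject: int = 10,
                    fingerprints_per_subject: int = 10,
                    seed: int = 0,
                    cfg: GeneratorConfig | None = None) -> CohortPools:
    """Generate the three source pools, ready for virtual-subject matching.

    The pools use disjoint identity namespaces (E*/F*/P*) and independent
    phenotypes, mirroring mutually exclusive source databases; gender
    marginals match ``gender_ratio`` in the ECG and face pools so that
    gender-constrained matching of ``n_subjects`` virtual subjects is
    feasible by construction.
    """
    if n_subjects < 2:
        raise ValueError("need at least 2 subjects")
    cfg = cfg or GeneratorConfig()
    rng = np.random.default_rng(seed)
    sub = lambda: int(rng.integers(0, 2**31 - 1))

    ecg_ph = generate_phenotypes(n_subjects, gender_ratio, sub(), cfg, prefix="E")
    face_ph = generate_phenotypes(n_subjects, gender_ratio, sub(), cfg, prefix="F")
    fing_ph = generate_phenotypes(n_subjects, gender_ratio, sub(), cfg, prefix="P")

    ecg_pool = [
        {"id": ph.subject_id, "gender": ph.gender, "age": ph.age,
         "records": [generate_ecg_record(ph, sub(), cfg=cfg)
                     for _ in range(records_per_subject)]}
        for ph in ecg_ph
    ]
    face_pool = [
        {"id": ph.subject_id, "gender": ph.gender,
         "images": [generate_face_image(ph, sub(), cfg=cfg)
                    for _ in range(faces_per_subject)]}
        for ph in face_ph
    ]
    fingerprint_pool = [
        {"id": ph.subject_id,
         "images": [generate_fingerprint_image(ph, sub(), cfg=cfg)
                    for _ in range(fingerprints_per_subject)]}
        for ph in fing_ph
    ]
    manifest = {
        "seed": seed,
        "n_subjects": n_subjects,
        "gender_ratio": gender_ratio,
        "phenotypes": {
            "ecg": [vars(ph) for ph in ecg_ph],
            "face": [vars(ph) for ph in face_ph],
            "fingerprint": [vars(ph) for ph in fing_ph],
        },
    }
    return CohortPools(ecg_pool, face_pool, fingerprint_pool, manifest)
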