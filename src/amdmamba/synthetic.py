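"""Synthetic miniature cohort generator.

Produces a study-shaped dataset so the whole two-stage pipeline can be
exercised with known ground truth:

* **Images** — a dark circular "fundus" disc on black background with
  bright Gaussian blobs imitating drusen-like deposits.  Blob count is
  drawn from a class-conditional range, so expected lesion burden is
  strictly monotone across the four severity classes and class is
  recoverable from the image by construction.
* **Tabular covariates** — 52 variant dosage columns in {0,1,2} with
  per-variant allele frequencies, age ~ Normal(74, 5) truncated, binary
  sex, 3-level smoking status.
* **Survival outcomes** — proportional-hazards event times from a Weibull
  baseline scaled by exp(true log-risk), where the true log-risk is a
  linear combination of standardized lesion burden, selected variant
  dosages and standardized age.  Independent exponential censoring is
  calibrated by root-finding to hit the target censoring rate.

A truth table (true log-risk, class, burden, uncensored event time) is
written beside the data with a ``truth`` name and is only ever consumed by
tests and oracles, never by models.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from PIL import Image
from scipy.optimize import brentq

__all__ = ["GeneratorConfig", "SyntheticCohort", "generate_cohort", "write_cohort", "bayes_c_index"]

CLASS_NAMES = ("no", "early", "intermediate", "late")
SCORE_RANGES = {0: (1, 1), 1: (2, 5), 2: (6, 9), 3: (10, 12)}


@dataclass(frozen=True)
class GeneratorConfig:
    n_subjects: int = 300
    second_eye_prob: float = 0.5  # 1-2 eyes per subject
    image_size: int = 32
    class_proportions: tuple = (0.30, 0.30, 0.25, 0.15)
    # class-conditional blob-count ranges (inclusive); gaps keep classes separable
    blob_counts: tuple = ((0, 0), (1, 4), (6, 10), (13, 18))
    blob_sigma: tuple = (0.8, 1.6)
    blob_intensity: tuple = (0.5, 0.9)
    n_variants: int = 52
    allele_freqs: tuple | None = None  # default: drawn once per config seed
    # hazard: strong image-driven component, moderate tabular effects
    burden_coef: float = 2.5  # per SD of lesion burden
    variant_effects: tuple = ((0, 0.35), (1, -0.30), (2, 0.30), (3, 0.25))
    age_coef: float = 0.35  # per SD of age
    weibull_shape: float = 1.5
    weibull_scale: float = 9.0  # years
    censoring_rate: float = 0.60
    seed: int = 0

    def __post_init__(self):
        if abs(sum(self.class_proportions) - 1.0) > 1e-9:
            raise ValueError("class proportions must sum to 1")
        if not 0.0 < self.censoring_rate < 1.0:
            raise ValueError("censoring rate target must lie in (0, 1)")
        if self.image_size < int(6 * self.blob_sigma[1]):
            raise ValueError("image size too small for configured blob radii")


@dataclass
class SyntheticCohort:
    images: np.ndarray  # (N, H, W, 3) float in [0, 1]
    covariates: pd.DataFrame  # per-eye rows incl. severity score
    survival: pd.DataFrame  # baseline eyes only (score < 10 kept by loaders)
    truth: pd.DataFrame  # oracle-only
    manifest: dict = field(default_factory=dict)


def _draw_image(rng, size, n_blobs, sigma_range, intensity_range):
    """One fundus-like frame; returns (image, burden=total added intensity)."""
    yy, xx = np.mgrid[0:size, 0:size].astype(float)
    cx = cy = (size - 1) / 2.0
    r = np.hypot(xx - cx, yy - cy)
    disc = (r <= 0.47 * size).astype(float)
    base = rng.uniform(0.85, 1.15)
    img = np.stack(
        [0.55 * disc * base, 0.28 * disc * base, 0.10 * disc * base], axis=-1
    )
    burden = 0.0
    for _ in range(n_blobs):
        rho = 0.38 * size * np.sqrt(rng.uniform())
        theta = rng.uniform(0, 2 * np.pi)
        bx, by = cx + rho * np.cos(theta), cy + rho * np.sin(theta)
        sig = rng.uniform(*sigma_range)
        amp = rng.uniform(*intensity_range)
        blob = amp * np.exp(-((xx - bx) ** 2 + (yy - by) ** 2) / (2 * sig**2))
        img[..., 0] += blob
        img[..., 1] += 0.9 * blob
        img[..., 2] += 0.45 * blob
        burden += amp * 2 * np.pi * sig**2
    img += rng.normal(0, 0.02, size=img.shape)
    return np.clip(img, 0.0, 1.0), burden


def generate_images(cfg: GeneratorConfig, classes: np.ndarray, rng) -> tuple:
    imgs, burdens = [], []
    for c in classes:
        lo, hi = cfg.blob_counts[c]
        n_blobs = int(rng.integers(lo, hi + 1))
        img, burden = _draw_image(
            rng, cfg.image_size, n_blobs, cfg.blob_sigma, cfg.blob_intensity
        )
        imgs.append(img)
        burdens.append(burden)
    return np.stack(imgs), np.asarray(burdens)


def generate_tabular(cfg: GeneratorConfig, n_eyes: int, subject_of_eye, rng) -> pd.DataFrame:
    """Variant dosages and demographics; demographics are per subject."""
    if cfg.allele_freqs is not None:
        mafs = np.asarray(cfg.allele_freqs, dtype=float)
        if mafs.shape != (cfg.n_variants,):
            raise ValueError("allele_freqs length must equal n_variants")
    else:
        maf_rng = np.random.default_rng(cfg.seed + 104729)  # frozen per config
        mafs = maf_rng.uniform(0.1, 0.5, size=cfg.n_variants)
    n_subj = int(np.max(subject_of_eye)) + 1
    dosages_subj = rng.binomial(2, mafs[None, :], size=(n_subj, cfg.n_variants))
    age_subj = np.clip(rng.normal(74.0, 5.0, size=n_subj), 55.0, 90.0)
    sex_subj = rng.integers(0, 2, size=n_subj)
    smoke_subj = rng.choice(
        ["never", "former", "current"], p=(0.47, 0.47, 0.06), size=n_subj
    )
    rows = {"subject_id": [f"S{subject_of_eye[i]:04d}" for i in range(n_eyes)]}
    for v in range(cfg.n_variants):
        rows[f"rs{v + 1:04d}"] = dosages_subj[subject_of_eye, v]
    rows["age"] = age_subj[subject_of_eye]
    rows["sex"] = sex_subj[subject_of_eye]
    rows["smoking_status"] = smoke_subj[subject_of_eye]
    return pd.DataFrame(rows)


def true_log_risk(cfg: GeneratorConfig, burdens, covariates: pd.DataFrame) -> np.ndarray:
    zb = (burdens - burdens.mean()) / max(burdens.std(), 1e-12)
    za = (covariates["age"].to_numpy() - 74.0) / 5.0
    risk = cfg.burden_coef * zb + cfg.age_coef * za
    for idx, coef in cfg.variant_effects:
        risk = risk + coef * covariates[f"rs{idx + 1:04d}"].to_numpy()
    return risk - risk.mean()


def generate_survival(cfg: GeneratorConfig, risk: np.ndarray, rng) -> pd.DataFrame:
    n = len(risk)
    u = rng.uniform(size=n)
    t_event = cfg.weibull_scale * (-np.log(u) * np.exp(-risk)) ** (1.0 / cfg.weibull_shape)
    t_event = np.maximum(t_event, 1e-3)

    def censored_frac(rate):
        return np.mean(1.0 - np.exp(-rate * t_event)) - cfg.censoring_rate

    try:
        rate = brentq(censored_frac, 1e-8, 1e4)
    except ValueError as err:
        raise ValueError("censoring rate target unattainable") from err
    t_cens = rng.exponential(1.0 / rate, size=n)
    t_cens = np.maximum(t_cens, 1e-3)
    observed = np.minimum(t_event, t_cens)
    delta = (t_event <= t_cens).astype(int)
    return pd.DataFrame(
        {"time_years": observed, "event": delta, "true_event_time": t_event}
    )


def generate_cohort(cfg: GeneratorConfig) -> SyntheticCohort:
    rng = np.random.default_rng(cfg.seed)
    # subjects, eyes, severity
    n_eyes_per = 1 + (rng.uniform(size=cfg.n_subjects) < cfg.second_eye_prob)
    subject_of_eye = np.repeat(np.arange(cfg.n_subjects), n_eyes_per)
    n_eyes = len(subject_of_eye)
    eye_ids = []
    seen: dict = {}
    for s in subject_of_eye:
        seen[s] = seen.get(s, 0) + 1
        eye_ids.append("OD" if seen[s] == 1 else "OS")
    classes = rng.choice(4, p=cfg.class_proportions, size=n_eyes)
    scores = np.array(
        [rng.integers(SCORE_RANGES[c][0], SCORE_RANGES[c][1] + 1) for c in classes]
    )

    images, burdens = generate_images(cfg, classes, rng)
    covariates = generate_tabular(cfg, n_eyes, subject_of_eye, rng)
    covariates.insert(1, "eye_id", eye_ids)
    covariates.insert(2, "severity_score", scores)

    risk = true_log_risk(cfg, burdens, covariates)
    surv = generate_survival(cfg, risk, rng)
    survival = pd.DataFrame(
        {
            "subject_id": covariates["subject_id"],
            "eye_id": covariates["eye_id"],
            "time_years": surv["time_years"],
            "event": surv["event"],
        }
    )
    truth = pd.DataFrame(
        {
            "subject_id": covariates["subject_id"],
            "eye_id": covariates["eye_id"],
            "true_log_risk": risk,
            "true_class": classes,
            "lesion_burden": burdens,
            "true_event_time": surv["true_event_time"],
        }
    )
    manifest = {
        "seed": cfg.seed,
        "config": asdict(cfg),
        "n_eyes": int(n_eyes),
        "columns": list(covariates.columns),
    }
    return SyntheticCohort(images, covariates, survival, truth, manifest)


def write_cohort(cohort: SyntheticCohort, out_dir) -> None:
    """Write layout: images/*.png, covariates.tsv, survival.tsv, truth.tsv."""
    from pathlib import Path

    out = Path(out_dir)
    (out / "images").mkdir(parents=True, exist_ok=True)
    names = []
    for i, (sid, eid) in enumerate(
        zip(cohort.covariates["subject_id"], cohort.covariates["eye_id"])
    ):
        name = f"{sid}_{eid}.png"
        arr = (cohort.images[i] * 255.0).round().astype(np.uint8)
        Image.fromarray(arr).save(out / "images" / name)
        names.append(name)
    cov = cohort.covariates.copy()
    cov.insert(0, "image", names)
    cov.to_csv(out / "covariates.tsv", sep="\t", index=False)
    cohort.survival.to_csv(out / "survival.tsv", sep="\t", index=False)
    cohort.truth.to_csv(out / "truth.tsv", sep="\t", index=False)
    with open(out / "manifest.json", "w") as fh:
        json.dump(cohort.manifest, fh, indent=2, default=str)


def bayes_c_index(truth: pd.DataFrame, survival: pd.DataFrame) -> float:
    """Concordance of the TRUE log-risk against observed outcomes.

    This is the ceiling any fitted risk score can approach on this cohort.
    """
    from .survival import concordance_index

    merged = survival.merge(truth, on=["subject_id", "eye_id"])
    return concordance_index(
        merged["time_years"].to_numpy(),
        merged["event"].to_numpy(),
        merged["true_log_risk"].to_numpy(),
    )
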