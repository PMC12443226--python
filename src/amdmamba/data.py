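"""Cohort I/O and covariate encoding.

Data dictionary (fixed column order, pinned by ``column_manifest``):

* ``subject_id``, ``eye_id`` — identifiers; folds always split by subject.
* ``severity_score`` — integer 1..12 per eye.
* ``rs0001``..``rs00NN`` — variant dosages in {0, 1, 2} (52 by default).
* ``age`` — years; z-scored with training-fold statistics at encoding time.
* ``sex`` — 0/1.
* ``smoking_status`` — never/former/current; one-hot encoded (3 columns).

The encoded tabular vector e therefore has length n_variants + 1 + 1 + 3.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

__all__ = ["Cohort", "load_cohort", "column_manifest", "encode_covariates", "normalize_images"]

SMOKING_LEVELS = ("never", "former", "current")


@dataclass
class Cohort:
    images: np.ndarray  # (N, H, W, 3) float in [0, 1]
    covariates: pd.DataFrame
    survival: pd.DataFrame


def load_cohort(data_dir, image_size: int | None = None) -> Cohort:
    """Load a cohort directory (images/, covariates.tsv, survival.tsv).

    Truth files are oracle-only and are deliberately not loaded here.
    """
    data_dir = Path(data_dir)
    cov = pd.read_csv(data_dir / "covariates.tsv", sep="\t")
    surv = pd.read_csv(data_dir / "survival.tsv", sep="\t")
    imgs = []
    for name in cov["image"]:
        with Image.open(data_dir / "images" / name) as im:
            im = im.convert("RGB")
            if image_size is not None and im.size != (image_size, image_size):
                im = im.resize((image_size, image_size), Image.BILINEAR)
            imgs.append(np.asarray(im, dtype=np.float64) / 255.0)
    return Cohort(np.stack(imgs), cov.drop(columns=["image"]), surv)


def column_manifest(n_variants: int = 52) -> dict:
    variant_cols = [f"rs{v + 1:04d}" for v in range(n_variants)]
    return {
        "id_columns": ["subject_id", "eye_id"],
        "severity_column": "severity_score",
        "variant_columns": variant_cols,
        "demographics": {
            "age": "z-scored with training-fold mean/sd",
            "sex": "binary 0/1",
            "smoking_status": f"one-hot over {list(SMOKING_LEVELS)}",
        },
        "encoded_order": variant_cols + ["age_z", "sex"]
        + [f"smoking_{s}" for s in SMOKING_LEVELS],
    }


def encode_covariates(
    cov: pd.DataFrame, age_stats: tuple | None = None, n_variants: int | None = None
):
    """Encode per-eye covariates into the tabular vector e.

    `age_stats` (mean, sd) must come from the training fold; if None they
    are computed from `cov` (and returned so validation reuses them).
    """
    if n_variants is None:
        n_variants = sum(c.startswith("rs") for c in cov.columns)
    variant_cols = [f"rs{v + 1:04d}" for v in range(n_variants)]
    missing = [c for c in variant_cols + ["age", "sex", "smoking_status"] if c not in cov]
    if missing:
        raise ValueError(f"covariate table missing columns: {missing}")
    if age_stats is None:
        age_stats = (float(cov["age"].mean()), float(cov["age"].std(ddof=0)) or 1.0)
    mu, sd = age_stats
    parts = [cov[variant_cols].to_numpy(dtype=float)]
    parts.append(((cov["age"].to_numpy(dtype=float) - mu) / sd)[:, None])
    parts.append(cov["sex"].to_numpy(dtype=float)[:, None])
    smoke = cov["smoking_status"].astype(str).to_numpy()
    onehot = np.stack([(smoke == s).astype(float) for s in SMOKING_LEVELS], axis=1)
    if not np.all(onehot.sum(axis=1) == 1):
        bad = sorted(set(smoke) - set(SMOKING_LEVELS))
        raise ValueError(f"unknown smoking levels: {bad}")
    parts.append(onehot)
    return np.concatenate(parts, axis=1), age_stats


def normalize_images(images: np.ndarray, mean, std) -> np.ndarray:
    """Per-channel normalization (applied after any geometric augmentation)."""
    mean = np.asarray(mean, dtype=np.float64)
    std = np.asarray(std, dtype=np.float64)
    return (images - mean) / std
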