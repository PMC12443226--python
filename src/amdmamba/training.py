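"""Two-stage training driver and cross-validation orchestration.

Stage 1 trains the backbone plus cosine-prototype head to classify grouped
severity from images.  Stage 2 freezes the backbone (and prototypes),
precomputes the pooled multi-scale features once, and trains the attention
fusion and survival head under the negative Cox partial log-likelihood on
baseline eyes without late disease (score < 10), checkpointing on
validation concordance.

All randomness (weight init, fold splits, augmentation, batch order) flows
from a single integer seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .backbone import Backbone, build_backbone
from .config import ModelConfig, StagePlan
from .data import encode_covariates, normalize_images
from .fusion import Stage2Model
from .metric_head import PrototypeClassifier, n_classes, score_to_class
from .nn import Adam, Tensor
from .survival import concordance_index, cox_loss_tensor

__all__ = [
    "make_folds",
    "augment_images",
    "train_stage1",
    "train_stage2",
    "summarize_folds",
    "Stage1Result",
    "Stage2Result",
]


def summarize_folds(fold_metrics: list) -> dict:
    """Cross-validation summary: mean +- SD per metric over fold dicts."""
    keys = set().union(*(m.keys() for m in fold_metrics))
    out = {}
    for k in sorted(keys):
        vals = np.array([m[k] for m in fold_metrics if k in m], dtype=float)
        out[k] = {"mean": float(vals.mean()), "sd": float(vals.std(ddof=1)) if len(vals) > 1 else 0.0,
                  "per_fold": vals.tolist()}
    return out


def make_folds(subject_ids, k: int, seed: int):
    """Deterministic K-fold split by subject ID (sizes within +-1)."""
    unique = np.unique(np.asarray(subject_ids))
    if k < 2:
        raise ValueError("need at least 2 folds")
    if k > len(unique):
        raise ValueError(f"K={k} exceeds number of subjects ({len(unique)})")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(unique)
    folds = []
    for chunk in np.array_split(perm, k):
        val = set(chunk.tolist())
        train = set(unique.tolist()) - val
        folds.append((sorted(train), sorted(val)))
    return folds


def augment_images(images, rng, max_rotation: float = 10.0, flip_prob: float = 0.5):
    """Random +-10 degree rotation and horizontal flip (p = 0.5), seeded.

    Geometric only; channel normalization is applied afterwards by callers.
    """
    images = np.asarray(images, dtype=np.float64)
    out = np.empty_like(images)
    for i, img in enumerate(images):
        angle = rng.uniform(-max_rotation, max_rotation) if max_rotation > 0 else 0.0
        aug = img
        if angle != 0.0:
            aug = ndimage.rotate(
                aug, angle, axes=(0, 1), reshape=False, order=1, mode="constant", cval=0.0
            )
        if flip_prob > 0 and rng.uniform() < flip_prob:
            aug = aug[:, ::-1, :]
        out[i] = aug
    return out


@dataclass
class Stage1Result:
    backbone: Backbone
    classifier: PrototypeClassifier
    history: list = field(default_factory=list)
    best_val_accuracy: float = float("nan")
    train_accuracy: float = float("nan")


@dataclass
class Stage2Result:
    model: Stage2Model
    history: list = field(default_factory=list)
    best_val_cindex: float = float("nan")


def _batched_latents(backbone, images, batch: int = 64):
    """Pooled f4 latents plus per-scale pooled maps, without gradients."""
    frozen_latents, pooled = [], None
    for lo in range(0, len(images), batch):
        feats = backbone(Tensor(images[lo : lo + batch]))
        lat = Backbone.latent(feats).data
        frozen_latents.append(lat)
        per_scale = [f.data.mean(axis=(1, 2)) for f in feats]
        if pooled is None:
            pooled = [[p] for p in per_scale]
        else:
            for acc, p in zip(pooled, per_scale):
                acc.append(p)
    return np.concatenate(frozen_latents), [np.concatenate(p) for p in pooled]


def _accuracy(backbone, classifier, images, labels, norm, batch: int = 64):
    preds = []
    for lo in range(0, len(images), batch):
        x = normalize_images(images[lo : lo + batch], *norm)
        feats = backbone(Tensor(x))
        preds.append(classifier.predict(Backbone.latent(feats)))
    return float(np.mean(np.concatenate(preds) == labels))


def train_stage1(
    images,
    scores,
    subject_ids,
    cfg: ModelConfig,
    seed: int,
    val_subjects=None,
    plan: StagePlan | None = None,
) -> Stage1Result:
    """Severity-classification pretraining with the metric cross-entropy."""
    plan = plan or cfg.stage1
    labels = score_to_class(np.asarray(scores), cfg.grouping)
    subject_ids = np.asarray(subject_ids)
    if val_subjects is not None:
        val_mask = np.isin(subject_ids, list(val_subjects))
    else:
        val_mask = np.zeros(len(labels), dtype=bool)
    train_mask = ~val_mask

    C = n_classes(cfg.grouping)
    present = np.unique(labels[train_mask])
    absent = sorted(set(range(C)) - set(present.tolist()))
    if absent and cfg.grouping != "twelve_class":
        raise ValueError(f"classes absent from training data: {absent}")

    rng = np.random.default_rng(seed)
    backbone = build_backbone(cfg.backbone, seed=int(rng.integers(2**31 - 1)))
    classifier = PrototypeClassifier(
        C, backbone.latent_dim, init_seed=cfg.metric_head.init_seed,
        temperature=cfg.metric_head.temperature,
    )
    params = list(backbone.parameters()) + list(classifier.parameters())
    opt = Adam(params, lr=plan.learning_rate)
    norm = (cfg.backbone.norm_mean, cfg.backbone.norm_std)

    tr_idx = np.flatnonzero(train_mask)
    history, best = [], (-1.0, None, None)
    for epoch in range(plan.epochs):
        order = rng.permutation(tr_idx)
        losses, n_correct = [], 0
        for lo in range(0, len(order), plan.batch_size):
            sel = order[lo : lo + plan.batch_size]
            batch_imgs = images[sel]
            if plan.augment:
                batch_imgs = augment_images(batch_imgs, rng)
            x = normalize_images(batch_imgs, *norm)
            feats = backbone(Tensor(x))
            logits = classifier.cosine_logits(Backbone.latent(feats))
            n_correct += int((np.argmax(logits.data, axis=-1) == labels[sel]).sum())
            loss = classifier.loss(None, labels[sel], logits=logits)
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(loss.item())
        # train accuracy tallied from the (pre-update, augmented) batch logits
        train_acc = n_correct / len(order)
        rec = {"epoch": epoch, "loss": float(np.mean(losses)), "train_accuracy": train_acc}
        if val_mask.any():
            rec["val_accuracy"] = _accuracy(
                backbone, classifier, images[val_mask], labels[val_mask], norm
            )
            score = rec["val_accuracy"]
        else:
            score = train_acc
        history.append(rec)
        if score > best[0]:
            best = (score, backbone.state_dict(), classifier.state_dict())
    backbone.load_state_dict(best[1])
    classifier.load_state_dict(best[2])
    final_train_acc = _accuracy(backbone, classifier, images[tr_idx], labels[tr_idx], norm)
    return Stage1Result(
        backbone, classifier, history,
        best_val_accuracy=best[0] if val_mask.any() else float("nan"),
        train_accuracy=final_train_acc,
    )


def select_stage2_rows(covariates, survival):
    """Baseline eyes without late disease: severity score < 10."""
    merged = survival.merge(
        covariates, on=["subject_id", "eye_id"], validate="one_to_one"
    )
    return merged.loc[merged["severity_score"] < 10].reset_index(drop=True)


def train_stage2(
    cohort_images,
    covariates,
    survival,
    stage1: Stage1Result,
    cfg: ModelConfig,
    seed: int,
    val_subjects,
    plan: StagePlan | None = None,
) -> Stage2Result:
    """Cox-objective training of fusion + survival head on frozen features."""
    plan = plan or cfg.stage2
    stage1.backbone.freeze()
    stage1.classifier.freeze()

    rows = select_stage2_rows(covariates, survival)
    key = covariates.reset_index().rename(columns={"index": "_img_idx"})
    rows = rows.merge(key[["subject_id", "eye_id", "_img_idx"]], on=["subject_id", "eye_id"])
    images = cohort_images[rows["_img_idx"].to_numpy()]
    time = rows["time_years"].to_numpy(dtype=float)
    event = rows["event"].to_numpy(dtype=int)
    if event.sum() == 0:
        raise ValueError("stage-2 cohort contains no events")

    val_mask = np.isin(rows["subject_id"].to_numpy(), list(val_subjects))
    train_mask = ~val_mask
    age_stats = None
    e_train, age_stats = encode_covariates(rows.loc[train_mask], None)
    e_val, _ = encode_covariates(rows.loc[val_mask], age_stats) if val_mask.any() else (
        np.zeros((0, e_train.shape[1])), age_stats,
    )

    norm = (cfg.backbone.norm_mean, cfg.backbone.norm_std)
    x = normalize_images(images, *norm)
    latents, pooled = _batched_latents(stage1.backbone, x)

    rng = np.random.default_rng(seed + 1)
    model = Stage2Model(
        cfg.backbone.dims, e_train.shape[1], cfg.fusion, stage1.classifier,
        np.random.default_rng(seed + 2),
    )
    opt = Adam(model.parameters(), lr=plan.learning_rate)

    tr_idx = np.flatnonzero(train_mask)
    va_idx = np.flatnonzero(val_mask)
    e_all = np.zeros((len(rows), e_train.shape[1]))
    e_all[tr_idx] = e_train
    if val_mask.any():
        e_all[va_idx] = e_val

    def predict(idx):
        beta, _ = model([p[idx] for p in pooled], e_all[idx], latents[idx])
        return beta

    history, best = [], (-np.inf, None)
    for epoch in range(plan.epochs):
        order = rng.permutation(tr_idx)
        losses = []
        for lo in range(0, len(order), plan.batch_size):
            sel = order[lo : lo + plan.batch_size]
            if event[sel].sum() == 0:
                warnings.warn("skipping batch without events (Cox loss undefined)")
                continue
            beta = predict(sel)
            loss = cox_loss_tensor(beta, time[sel], event[sel], reduction="mean")
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(loss.item())
        rec = {"epoch": epoch, "loss": float(np.mean(losses)) if losses else float("nan")}
        if val_mask.any() and event[va_idx].sum() > 0:
            val_beta = predict(va_idx).data
            rec["val_cindex"] = concordance_index(time[va_idx], event[va_idx], val_beta)
            score = rec["val_cindex"]
        else:
            score = -rec["loss"]
        history.append(rec)
        if score > best[0]:
            best = (score, model.state_dict())
    model.load_state_dict(best[1])
    result = Stage2Result(model, history, best_val_cindex=best[0] if val_mask.any() else float("nan"))
    # expose pieces needed for evaluation
    result.rows = rows
    result.time = time
    result.event = event
    result.val_mask = val_mask
    result.age_stats = age_stats
    result.predict_beta = lambda idx=None: predict(
        np.arange(len(rows)) if idx is None else idx
    ).data
    return result
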