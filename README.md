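# amdmamba

Multimodal survival prognosis for progression of age-related macular
degeneration (AMD), built for researchers studying image-based risk
models. The package combines a visual state-space (2-D selective scan)
backbone with cosine-prototype metric pretraining on AMD severity
phenotypes, attention-based fusion of multi-scale image features with
genetic and socio-demographic covariates, a Cox partial-likelihood
survival head, and a dichotomized-risk biomarker with the full survival
evaluation suite (C-index, time-dependent AUC, Kaplan–Meier / log-rank,
Cox screening). A synthetic cohort generator with planted ground truth
makes the entire two-stage pipeline testable on one CPU.

## The model in brief

**Backbone.** Images pass through patch embedding and four stages of
visual state-space (VSS) blocks with downsampling, yielding multi-scale
feature maps f1..f4. Each block is

    X_out = X + CA( LN( FFN(SS2D(LN(X))) + SA(LN(X)) ) )

where SS2D runs an input-conditioned state-space recurrence along four
directional flattenings of the token grid, SA is a CBAM-style spatial
gate, and CA a squeeze-and-excitation channel gate.

**Stage 1 (metric pretraining).** A learnable prototype matrix
g ∈ R^{C×d} gives class logits y_i = cos(f4, g_i); training minimizes
softmax cross-entropy over the cosine logits for C grouped severity
classes (no/early/intermediate/late by default; 12-class and binary
groupings are configurable).

**Stage 2 (survival).** With the backbone frozen, covariates
e (52 variant dosages + encoded demographics) are projected to a query
q = W_q e, which absorbs each pooled scale f̄_i as a single key/value
token: q ← q + MHSA(q, W_k f̄_i, W_v f̄_i), followed by a residual
feed-forward block. The fused embedding is modulated by the predicted
class prototype, u* = q + q ⊙ g_ŝ (hard; soft and off modes exist),
and a shallow MLP outputs the log-risk β, trained with the negative Cox
partial log-likelihood

    L(β) = − Σ_{i: δ_i=1} [ β_i − log Σ_{j: t_j ≥ t_i} exp(β_j) ].

**Biomarker.** β dichotomized at the training median defines low/high
risk groups, evaluated with KM curves, the log-rank test and Cox
proportional-hazards screening.

See `docs/methods.md` for assumptions, parameter defaults and what the
synthetic cohort does and does not emulate.

## Worked example

```bash
amdmamba simulate --out cohort/ --seed 5 --subjects 40
amdmamba pretrain --data cohort/ --out run/s1 --seed 1 --tiny
amdmamba train-survival --data cohort/ --stage1 run/s1 --out run/s2 --seed 1 --tiny
amdmamba evaluate --predictions run/s2/predictions.csv --out run/metrics.json
amdmamba stratify --predictions run/s2/predictions.csv --out run/strat.json
```

On the default 300-subject synthetic cohort (the same computation the
acceptance script performs, seed 1) the pipeline prints:

```
stage1_train_accuracy   0.9643   (n=364 eyes)
stage1_val_accuracy     0.9775   (n=89 eyes)
stage2_val_cindex       0.788    (n=79 baseline eyes)
bayes_val_cindex        0.8348   (oracle ceiling: true log-risk as score)
val_auc_5yr             0.7587
biomarker_hazard_ratio  3.7392   (high vs low risk group)
biomarker_logrank_p     0.0029
```

Reading these: Stage 1 learns the planted severity signal almost
perfectly; the Stage-2 validation C-index (0.79) comes within 0.05 of
the best any model could do on this cohort (0.83, the concordance of the
generator's true log-risk); and the dichotomized biomarker separates
progression curves with a hazard ratio near 4.

## Layout

```
src/amdmamba/
  nn/          reverse-mode autodiff engine (NumPy, float64)
  backbone.py  patch embed, SS2D (+ loop reference), SA, CA, VSS blocks
  metric_head.py  cosine prototypes, metric cross-entropy, groupings
  fusion.py    pooling, query projection, MHSA fusion, guidance, MLP head
  survival.py  Cox loss, C-index, IPCW AUC, dichotomization, KM, screening
  training.py  folds, augmentation, two-stage driver
  synthetic.py cohort generator (images, tabular, Weibull-Cox outcomes)
  cli.py       simulate / pretrain / train-survival / evaluate / stratify
```
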