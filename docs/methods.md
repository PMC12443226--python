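# Methods

## Problem setting

`amdmamba` models progression of age-related macular degeneration (AMD) to
its late stage from three modalities: a color fundus photograph of the eye,
variant dosages for 52 genetic loci, and socio-demographic covariates (age,
sex, smoking status). Each eye carries an AMD severity scale score on the
1–12 step scale (≥ 10 denotes late AMD), grouped into four phenotype
classes: *no* (1), *early* (2–5), *intermediate* (6–9), *late* (10–12).
The model predicts a per-eye log-risk β used in a Cox proportional-hazards
sense; its dichotomization at the training median defines a two-level
(low/high) prognostic biomarker.

## Model

### Backbone

A four-stage visual state-space encoder. Images are patch-embedded
(patch 4) and processed by VSS blocks with patch-merging downsampling
between stages, producing multi-scale feature maps f1..f4 with halving
resolution and doubling width. Each block computes

    X_out = X + CA( LN( FFN(SS2D(LN(X))) + SA(LN(X)) ) )

* **SS2D** — the token grid is flattened along four directions (row-major,
  reversed, column-major, reversed) and each sequence runs through a
  selective state-space recurrence with input-conditioned step size Δ,
  input matrix B and readout C (shared across directions), negative
  diagonal state matrix A = −exp(A_log), and skip coefficient D. The four
  directional outputs are summed. A deliberately slow per-element loop
  implementation ships alongside the vectorized one and is used as the
  oracle in tests (agreement < 1e−5 absolute).
* **SA** — CBAM-style spatial attention: channel-mean and channel-max maps,
  a k×k convolution (k = 7) and a sigmoid produce a per-position gate in
  (0, 1).
* **CA** — squeeze-and-excitation channel attention: global average pool,
  bottleneck MLP (reduction ratio 16; 4 in the tiny profile), sigmoid gate
  per channel.
* The two `LN(X)` occurrences are separate learnable LayerNorm instances;
  the FFN (GELU, expansion 4; 2 in tiny) has no inner residual — the outer
  skip is the only one, as written above.

### Stage 1 — metric pretraining

A learnable prototype matrix g ∈ R^{C×d} holds one row per phenotype
class. Class logits are cosine similarities cos(f4, g_i) of the pooled
final feature map; training minimizes softmax cross-entropy over the raw
cosine logits. No temperature is applied by default (the logits are
bounded in [−1, 1], which bounds the loss from below; the raw-cosine form
is kept deliberately, with an optional temperature available but off).
Prototypes initialize as random unit-norm rows; argmax ties break to the
lowest class index.

### Stage 2 — multimodal survival head

The backbone and prototypes are frozen (verified bit-exactly by parameter
hashes). Covariates are encoded as e = [52 dosages, z-scored age (training
-fold statistics), binary sex, 3-level smoking one-hot] and projected to an
initial query q = W_q e (no bias). For each scale in ascending order the
pooled feature map — adapted to the common width d by a per-scale linear
map, since the stage widths differ — serves as a single key/value token:

    q ← q + MHSA(q, W_k f̄_i, W_v f̄_i);   q ← q + FFN(q)

W_k, W_v are shared across scales; the MHSA uses 4 heads; a query
projection and output projection complete the attention in the usual way
(with a single token the softmax weight is identically 1). The `stage`
counter on the fused embedding counts scales absorbed (0 after the
projection, 4 when complete); the completed embedding is the q4 of the
equations above.

The fused embedding is modulated by the Stage-1 prototype ("label
guidance"): hard mode selects g_ŝ for ŝ = argmax cosine class and computes
u* = q + q ⊙ g_ŝ; soft mode uses the class-probability-weighted prototype
mixture; off disables guidance. A shallow MLP (d → d/2 → 1, one ReLU) maps
u* to the scalar log-risk β.

Training minimizes the negative Cox partial log-likelihood with risk set
R(t) = {j : t_j ≥ t} and the Breslow convention for ties (the plain
formula is exactly Breslow under ties; Efron is available behind a flag).
Stage 2 uses only baseline eyes without late disease (score < 10).
Checkpoint selection is by validation C-index, mirroring the training
procedure the model family uses at full scale.

## Evaluation

* **Harrell's C** over comparable pairs (t_i < t_j, δ_i = 1), ties in the
  score counted ½ — invariant under monotone transforms of β.
* **Time-dependent AUC** at a horizon (5 years by default): cumulative
  cases / dynamic controls with inverse-probability-of-censoring weights
  1/G(t_i−), G the Kaplan–Meier estimate of the censoring distribution.
  With no censoring before the horizon this reduces to the plain rank-sum
  AUC; the implementation is pinned against a from-scratch hand
  computation and against an independent library implementation.
* **Biomarker** — β dichotomized at the *training* median (values exactly
  at the threshold go to low); Kaplan–Meier curves per group with a
  two-group log-rank test, and univariate/multivariate Cox screening
  (hazard ratios, 95% CIs, Wald p; multivariate restricted to covariates
  with univariate p < 0.05). KM, log-rank and the Cox fits delegate to
  lifelines; a singular multivariate design raises an error naming the
  collinear columns.

## Synthetic cohort

The generator emulates the structure of a large AMD imaging study in
miniature so every stage has ground truth:

* **Images** (32×32 by default): dark fundus-like disc, bright Gaussian
  "drusen-like" blobs whose count is drawn from class-conditional ranges
  (0 / 1–4 / 6–10 / 13–18), pixel noise σ = 0.02. Expected lesion burden
  is strictly monotone in class and a scalar burden threshold recovers the
  class at ≥ 90% accuracy — the cohort is separable by construction, which
  is what makes the Stage-1 learnability check meaningful.
* **Tabular**: 52 dosage columns with allele frequencies drawn once per
  configuration (uniform 0.1–0.5), age ~ N(74, 5²) truncated to [55, 90],
  binary sex, smoking never/former/current at 47/47/6%.
* **Survival**: true log-risk = 2.5·z(burden) + 0.35·rs0001 − 0.30·rs0002
  + 0.30·rs0003 + 0.25·rs0004 + 0.35·z(age); event times from a Weibull
  baseline (shape 1.5, scale 9 y) scaled by exp(risk) via inverse-transform
  sampling; independent exponential censoring with its rate solved by
  root-finding to hit a 60% censoring target. The image-driven effect
  deliberately dominates, mirroring imaging as the primary prognostic
  signal. The real cohort this emulates is far more heavily censored
  (~88%); at miniature scale that would leave too few events for any
  stable concordance estimate, so 60% is the design point, chosen for
  statistical power, not realism.
* A truth table (true log-risk, class, burden, uncensored event time) is
  written beside the data and consumed only by tests and oracles. The
  Bayes-optimal concordance — Harrell's C computed with the true log-risk
  as the score — is the ceiling against which trained models are judged.

What the generator does **not** emulate: retinal anatomy beyond a disc,
linkage structure between variants, correlated outcomes of fellow eyes
(folds still split by subject), longitudinal imagery, and realistic
class-overlapping lesion distributions. Passing tests therefore show the
machinery is correct and can learn a clean planted signal; they say
nothing about performance on real fundus photographs.

## Problem sizes and numerical choices

All computation is float64 NumPy on a hand-written reverse-mode autodiff
engine (`amdmamba.nn`); the networks are small enough that this is the
simplest fully-inspectable route. The `tiny` profile — 32×32 images,
widths 8/16/32/64, depths 1/1/1/1, state dim 4; Stage 1: 50 epochs, batch
32, Adam 3e−3; Stage 2: 300 epochs, full batch, Adam 3e−3 — is the
package's working scale for tests and examples; the `full_scale` profile
records the full-scale layout and optimizer settings (Adam
1e−4, batches 96/512, 50/100 epochs) but is not exercised at desk scale.
A `micro` profile (4 + 60 epochs) powers the ablation-parity checks.
The default cohort is 300 subjects (~450 eyes, 1–2 per subject, ~60%
second-eye rate).

Other numerical choices: softplus-parameterized Δ initialized near 0.1
with A_log = log(1..N) per channel (standard S4-style real init); log-sum-
exp shifts by the detached maximum in both the softmax and the Cox
denominator; LayerNorm ε = 1e−5; cosine similarity raises on zero-norm
inputs rather than silently adding an epsilon; Stage-2 features are
precomputed once from the frozen backbone (no Stage-2 augmentation —
equivalent under a frozen backbone and much cheaper).

## Known limitations

* No GPU kernels; the `full_scale` profile is a configuration record, not
  a runnable target on one CPU.
* Per-eye records are treated as independent in the Cox likelihood and
  the screening fits; no robust/cluster variance for fellow eyes.
* No competing risks, no proportional-hazards diagnostics.
* The prototype matrix stays frozen in Stage 2; the alternative (letting
  it continue to train) is untested.
* Hard-label guidance recomputes ŝ per forward pass from the frozen
  backbone latent; this is equivalent to precomputing it, and cheap at
  this scale.
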