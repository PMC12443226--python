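"""Stage-2 multimodal head: multi-scale attention fusion + survival MLP.

The tabular covariate vector e (variant dosages + encoded demographics) is
projected to an initial query q = Wq e.  For each backbone scale i = 1..4,
the pooled feature map is adapted to the common width d and serves as a
single key/value token; the query is updated by residual multi-head
attention followed by a residual feed-forward block:

    q <- q + MHSA(q, k_i, v_i);   q <- q + FFN(q)

After all four scales are absorbed, the final fused embedding q4 is
modulated by the Stage-1 class prototype via an elementwise product with
a skip connection,

    u* = q + q .* g_s        (hard: s = argmax cosine class;
                              soft: prototype mixture weighted by class
                              probabilities; off: u* = q)

and a shallow MLP maps u* to the scalar log-risk beta.

The `stage` attribute of a FusedEmbedding counts how many scales have been
absorbed: 0 right after the query projection, 4 when fusion is complete.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import FusionConfig
from .metric_head import PrototypeClassifier
from .nn import FeedForward, Linear, Module, Tensor

__all__ = ["FusedEmbedding", "SingleTokenMHSA", "MultiScaleFusion", "SurvivalHead", "Stage2Model"]


@dataclass
class FusedEmbedding:
    q: Tensor  # (B, d)
    stage: int  # number of scales absorbed, 0..4


def pool_feature_map(f: Tensor) -> Tensor:
    """Global average pool over spatial positions: (B,h,w,c) -> (B,c)."""
    f = f if isinstance(f, Tensor) else Tensor(f)
    return f.mean(axis=(1, 2))


class SingleTokenMHSA(Module):
    """Multi-head attention of a query vector over one key/value token.

    With a single key the softmax is identically 1, so the output reduces
    to the (head-wise) value projection passed through the output map; the
    general softmax is still computed so the module extends to more tokens.
    """

    def __init__(self, dim: int, heads: int, rng):
        if dim % heads != 0:
            raise ValueError(f"dim {dim} not divisible by heads {heads}")
        self.dim = dim
        self.heads = heads
        self.Wq = Linear(dim, dim, rng, bias=False)
        self.Wo = Linear(dim, dim, rng, bias=False)

    def forward(self, q: Tensor, k: Tensor, v: Tensor) -> Tensor:
        B, d = q.shape
        h = self.heads
        dh = d // h
        qh = self.Wq(q).reshape(B, h, dh)
        kh = k.reshape(B, h, dh)
        vh = v.reshape(B, h, dh)
        scores = (qh * kh).sum(axis=-1, keepdims=True) * (1.0 / np.sqrt(dh))  # (B,h,1)
        # softmax over the (single) token axis
        weights = scores.exp() / scores.exp().sum(axis=-1, keepdims=True)
        out = (vh * weights).reshape(B, d)
        return self.Wo(out)


class MultiScaleFusion(Module):
    """Pools f1..f4, adapts them to width d, and runs the fusion loop."""

    def __init__(self, scale_dims, d_e: int, cfg: FusionConfig, rng):
        self.d = scale_dims[-1]
        self.adapters = [Linear(c, self.d, rng) for c in scale_dims]
        self.Wq_in = Linear(d_e, self.d, rng, bias=False)
        self.Wk = Linear(self.d, self.d, rng, bias=False)
        self.Wv = Linear(self.d, self.d, rng, bias=False)
        self.attn = SingleTokenMHSA(self.d, cfg.heads, rng)
        self.ffn = FeedForward(self.d, cfg.ffn_ratio, rng)

    def pool(self, f: Tensor, scale_index: int) -> Tensor:
        """Pooled + width-adapted representation of one scale (1-based index)."""
        return self.adapters[scale_index - 1](pool_feature_map(f))

    def project_query(self, e: Tensor) -> FusedEmbedding:
        e = e if isinstance(e, Tensor) else Tensor(e)
        return FusedEmbedding(q=self.Wq_in(e), stage=0)

    def fuse_step(self, emb: FusedEmbedding, f_bar: Tensor) -> FusedEmbedding:
        k = self.Wk(f_bar)
        v = self.Wv(f_bar)
        q = emb.q + self.attn(emb.q, k, v)
        q = q + self.ffn(q)
        return FusedEmbedding(q=q, stage=emb.stage + 1)

    def forward(self, pooled_raw: list[Tensor], e: Tensor) -> FusedEmbedding:
        """pooled_raw: per-scale globally pooled maps, widths (c_1..c_4)."""
        emb = self.project_query(e)
        for adapter, f_pool in zip(self.adapters, pooled_raw):
            f_pool = f_pool if isinstance(f_pool, Tensor) else Tensor(f_pool)
            emb = self.fuse_step(emb, adapter(f_pool))
        return emb


def apply_label_guidance(
    emb: FusedEmbedding,
    classifier: PrototypeClassifier,
    f4_vector,
    mode: str,
) -> Tensor:
    """Modulate the fused embedding by the Stage-1 phenotype prototype."""
    if emb.stage != 4:
        raise ValueError(f"label guidance expects a fully fused embedding, stage={emb.stage}")
    q = emb.q
    if mode == "off":
        return q
    g = classifier.prototypes
    if mode == "hard":
        s = classifier.predict(f4_vector)
        g_sel = g[s]  # (B, d) advanced indexing
        return q + q * g_sel
    if mode == "soft":
        p = Tensor(classifier.soft_weights(f4_vector))  # (B, C) constants
        mix = p @ g
        return q + q * mix
    raise ValueError(f"unknown guidance mode {mode!r}")


class SurvivalHead(Module):
    """Shallow MLP u* -> log-risk beta: d -> d//2 -> 1 with one ReLU."""

    def __init__(self, dim: int, rng):
        hidden = max(1, dim // 2)
        self.fc1 = Linear(dim, hidden, rng)
        self.fc2 = Linear(hidden, 1, rng)

    def forward(self, u_star: Tensor) -> Tensor:
        u_star = u_star if isinstance(u_star, Tensor) else Tensor(u_star)
        return self.fc2(self.fc1(u_star).relu()).reshape(u_star.shape[0])


class Stage2Model(Module):
    """Fusion + label guidance + survival head over frozen backbone features."""

    def __init__(self, scale_dims, d_e: int, cfg: FusionConfig,
                 classifier: PrototypeClassifier, rng):
        self.fusion = MultiScaleFusion(scale_dims, d_e, cfg, rng)
        self.head = SurvivalHead(scale_dims[-1], rng)
        self.classifier = classifier  # frozen; not trained here
        self.guidance_mode = cfg.guidance_mode

    def named_parameters(self, prefix: str = ""):
        # the frozen classifier's prototypes are not stage-2 parameters
        yield from self.fusion.named_parameters(prefix + "fusion.")
        yield from self.head.named_parameters(prefix + "head.")

    def forward(self, pooled_raw: list[Tensor], e: Tensor, f4_vector) -> tuple[Tensor, Tensor]:
        emb = self.fusion(pooled_raw, e)
        u_star = apply_label_guidance(emb, self.classifier, f4_vector, self.guidance_mode)
        beta = self.head(u_star)
        return beta, u_star
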