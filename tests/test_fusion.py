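"""Multi-scale attention fusion, label guidance and the survival head."""

import numpy as np
import pytest

from amdmamba.config import FusionConfig
from amdmamba.fusion import (
    MultiScaleFusion,
    Stage2Model,
    SurvivalHead,
    apply_label_guidance,
    pool_feature_map,
)
from amdmamba.metric_head import PrototypeClassifier
from amdmamba.nn import Tensor

DIMS = (8, 16, 32, 64)
D = DIMS[-1]
DE = 10


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def fusion(rng):
    return MultiScaleFusion(DIMS, DE, FusionConfig(heads=4, ffn_ratio=2.0), rng)


@pytest.fixture
def classifier():
    return PrototypeClassifier(4, D, init_seed=0)


def _pooled_inputs(rng, batch=3):
    return [Tensor(rng.normal(size=(batch, c))) for c in DIMS]


# -------------------------------------------------------------------- pooling
def test_pool_constant_map_gives_channel_values(rng):
    v = rng.normal(size=6)
    f = np.broadcast_to(v, (2, 4, 4, 6)).copy()
    np.testing.assert_allclose(pool_feature_map(Tensor(f)).data, np.tile(v, (2, 1)))


def test_pool_identity_on_1x1_map(rng):
    f = rng.normal(size=(3, 1, 1, 5))
    np.testing.assert_allclose(pool_feature_map(Tensor(f)).data, f[:, 0, 0, :])


def test_pool_matches_mean_oracle(rng):
    f = rng.normal(size=(2, 3, 5, 4))
    np.testing.assert_allclose(
        pool_feature_map(Tensor(f)).data, f.mean(axis=(1, 2)), atol=1e-12
    )


# ------------------------------------------------------------ query projection
def test_query_projection_is_linear(fusion, rng):
    zero = fusion.project_query(Tensor(np.zeros((2, DE))))
    np.testing.assert_allclose(zero.q.data, 0.0)
    assert zero.stage == 0
    e = rng.normal(size=(2, DE))
    np.testing.assert_allclose(
        fusion.project_query(Tensor(e)).q.data, e @ fusion.Wq_in.weight.data, atol=1e-12
    )


def test_identity_like_projection_returns_covariates(rng):
    fus = MultiScaleFusion(DIMS, D, FusionConfig(), rng)
    fus.Wq_in.weight.data[:] = np.eye(D)
    e = rng.normal(size=(2, D))
    np.testing.assert_allclose(fus.project_query(Tensor(e)).q.data, e)


# ------------------------------------------------------------------ fuse step
def test_double_residual_passthrough_when_zeroed(fusion, rng):
    fusion.attn.Wo.weight.data[:] = 0.0
    fusion.ffn.fc2.weight.data[:] = 0.0
    fusion.ffn.fc2.bias.data[:] = 0.0
    emb = fusion.project_query(Tensor(rng.normal(size=(2, DE))))
    out = fusion.fuse_step(emb, Tensor(rng.normal(size=(2, D))))
    np.testing.assert_allclose(out.q.data, emb.q.data, atol=1e-12)
    assert out.stage == emb.stage + 1


def test_single_key_attention_equals_value_projection_oracle(fusion, rng):
    """With one key/value token the softmax weight is 1, so the attention
    output is Wo(Wv f) for any query."""
    f_bar = rng.normal(size=(3, D))
    k = Tensor(f_bar @ fusion.Wk.weight.data)
    v_data = f_bar @ fusion.Wv.weight.data
    expected = v_data @ fusion.attn.Wo.weight.data
    for q_seed in (1, 2):
        q = Tensor(np.random.default_rng(q_seed).normal(size=(3, D)))
        out = fusion.attn(q, k, Tensor(v_data)).data
        np.testing.assert_allclose(out, expected, atol=1e-10)


def test_stage_counter_increments_across_loop(fusion, rng):
    emb = fusion.project_query(Tensor(rng.normal(size=(2, DE))))
    stages = [emb.stage]
    for adapter, f in zip(fusion.adapters, _pooled_inputs(rng, 2)):
        emb = fusion.fuse_step(emb, adapter(f))
        stages.append(emb.stage)
    assert stages == [0, 1, 2, 3, 4]


def test_fusion_order_matters(fusion, rng):
    e = Tensor(rng.normal(size=(2, DE)))
    pooled = [Tensor(rng.normal(size=(2, c))) for c in DIMS]
    out = fusion(pooled, e).q.data
    # swapping two scales of equal adapted width changes the result
    swapped = fusion.project_query(e)
    order = [1, 0, 2, 3]
    for i in order:
        swapped = fusion.fuse_step(swapped, fusion.adapters[i](pooled[i]))
    assert not np.allclose(out, swapped.q.data)


# -------------------------------------------------------------- label guidance
def test_guidance_identities(fusion, classifier, rng):
    emb = fusion(_pooled_inputs(rng), Tensor(rng.normal(size=(3, DE))))
    f4 = rng.normal(size=(3, D))
    # an (effectively) zero prototype: tiny norm keeps the cosine defined
    classifier.prototypes.data[:] = 0.0
    classifier.prototypes.data[:, 0] = 1e-9
    u = apply_label_guidance(emb, classifier, f4, "hard").data
    np.testing.assert_allclose(u, emb.q.data, atol=1e-8)
    classifier.prototypes.data[:] = 1.0
    u = apply_label_guidance(emb, classifier, f4, "hard").data
    np.testing.assert_allclose(u, 2.0 * emb.q.data, atol=1e-10)
    np.testing.assert_allclose(
        apply_label_guidance(emb, classifier, f4, "off").data, emb.q.data
    )


def test_guidance_modes_match_elementwise_oracles(fusion, classifier, rng):
    emb = fusion(_pooled_inputs(rng), Tensor(rng.normal(size=(3, DE))))
    f4 = rng.normal(size=(3, D))
    q = emb.q.data
    g = classifier.prototypes.data
    hard = apply_label_guidance(emb, classifier, f4, "hard").data
    s = classifier.predict(f4)
    np.testing.assert_allclose(hard, q + q * g[s], atol=1e-12)
    soft = apply_label_guidance(emb, classifier, f4, "soft").data
    p = classifier.soft_weights(f4)
    np.testing.assert_allclose(soft, q + q * (p @ g), atol=1e-12)


def test_guidance_requires_fully_fused_embedding(fusion, classifier, rng):
    emb = fusion.project_query(Tensor(rng.normal(size=(1, DE))))
    with pytest.raises(ValueError, match="stage"):
        apply_label_guidance(emb, classifier, rng.normal(size=(1, D)), "hard")


# --------------------------------------------------------------- survival head
def test_survival_head_zero_weights_give_zero(rng):
    head = SurvivalHead(D, rng)
    for p in head.parameters():
        p.data[:] = 0.0
    out = head(Tensor(rng.normal(size=(4, D)))).data
    np.testing.assert_allclose(out, 0.0)


def test_survival_head_monotone_with_positive_weights(rng):
    head = SurvivalHead(4, rng)
    head.fc1.weight.data[:] = np.abs(head.fc1.weight.data)
    head.fc2.weight.data[:] = np.abs(head.fc2.weight.data)
    base = np.zeros((1, 4))
    lo = head(Tensor(base)).data[0]
    hi = head(Tensor(base + 1.0)).data[0]
    assert hi >= lo


def test_survival_head_matches_matrix_oracle(rng):
    head = SurvivalHead(D, rng)
    u = rng.normal(size=(3, D))
    expected = (
        np.maximum(u @ head.fc1.weight.data + head.fc1.bias.data, 0.0)
        @ head.fc2.weight.data
        + head.fc2.bias.data
    )[:, 0]
    np.testing.assert_allclose(head(Tensor(u)).data, expected, atol=1e-12)


# ------------------------------------------------------------------ end-to-end
def test_stage2_forward_deterministic_and_tabular_only_path(rng, classifier):
    cfg = FusionConfig(guidance_mode="off")
    model = Stage2Model(DIMS, DE, cfg, classifier, np.random.default_rng(1))
    pooled = [p.data for p in _pooled_inputs(rng)]
    e = rng.normal(size=(3, DE))
    f4 = rng.normal(size=(3, D))
    b1, _ = model(pooled, e, f4)
    b2, _ = model(pooled, e, f4)
    np.testing.assert_array_equal(b1.data, b2.data)
    # zero the attention output and FFN: beta then depends on e only
    model.fusion.attn.Wo.weight.data[:] = 0.0
    model.fusion.ffn.fc2.weight.data[:] = 0.0
    model.fusion.ffn.fc2.bias.data[:] = 0.0
    beta_a, _ = model(pooled, e, f4)
    other = [np.random.default_rng(9).normal(size=p.shape) for p in pooled]
    beta_b, _ = model(other, e, f4)
    np.testing.assert_allclose(beta_a.data, beta_b.data, atol=1e-12)
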