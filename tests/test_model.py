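"""Gated-attention MIL network: pooling, fusion, heads, routing, invariance."""

import numpy as np
import pytest

from pathomil.encoding import FeatureBag
from pathomil.model import (
    AttentionWeights,
    ClinicalVector,
    GatedAttentionMIL,
    ModelConfig,
)

from conftest import make_bag, make_clinical

TINY = ModelConfig(input_dim=3, clinical_dim=2, attention_hidden=2, fusion_dim=2,
                   dropout=0.0)


def tiny_model(seed=0, task="classification"):
    cfg = ModelConfig(input_dim=3, clinical_dim=2, attention_hidden=2,
                      fusion_dim=2, dropout=0.0, task=task)
    return GatedAttentionMIL(cfg, seed=seed)


def set_params(model, **arrays):
    for k, v in arrays.items():
        model.params[k].data = np.asarray(v, dtype=np.float64)


class TestAttentionPool:
    def test_single_instance_gets_full_attention(self):
        m = tiny_model()
        bag = make_bag([[1.0, 2.0, 3.0]])
        att, emb = m.attention_pool(bag, "PDS")
        assert np.allclose(att.alpha, [1.0])
        h_proj = np.maximum(
            bag.features @ m.params["W_proj"].data + m.params["b_proj"].data, 0
        )
        assert np.allclose(emb.m_wsi, h_proj[0])

    def test_identical_instances_share_attention_uniformly(self):
        m = tiny_model()
        bag = make_bag(np.tile([0.5, -1.0, 2.0], (7, 1)))
        att, emb = m.attention_pool(bag, "IDS")
        assert np.allclose(att.alpha, 1 / 7)

    def test_matches_hand_computed_gated_attention_chain(self):
        """Arithmetic oracle with fixture weights through tanh/sigmoid/softmax."""
        m = tiny_model()
        W_proj = np.array([[1.0, 0.0], [0.0, 1.0], [0.5, -0.5]])
        V = np.array([[0.3, -0.2], [0.1, 0.4]])
        U = np.array([[-0.5, 0.2], [0.3, 0.1]])
        w = np.array([0.7, -0.3])
        set_params(m, W_proj=W_proj, b_proj=[0.0, 0.0], V_PDS=V,
                   bV_PDS=[0.0, 0.0], U_PDS=U, bU_PDS=[0.0, 0.0], w_PDS=w)
        H = np.array([[1.0, 0.0, 2.0], [0.0, 1.0, -1.0], [2.0, 2.0, 0.0]])
        bag = make_bag(H)
        att, emb = m.attention_pool(bag, "PDS")
        # independent forward in plain numpy
        hp = np.maximum(H @ W_proj, 0.0)
        scores = (np.tanh(hp @ V) * (1 / (1 + np.exp(-(hp @ U))))) @ w
        e = np.exp(scores - scores.max())
        alpha = e / e.sum()
        assert np.allclose(att.alpha, alpha, atol=1e-6)
        assert np.allclose(emb.m_wsi, alpha @ hp, atol=1e-6)

    def test_empty_bag_and_bad_route_raise(self):
        m = tiny_model()
        with pytest.raises(ValueError):
            m.attention_pool(make_bag([[1, 2, 3]]), "XXX")
        with pytest.raises(ValueError, match="input_dim"):
            m.attention_pool(make_bag([[1.0, 2.0]]), "PDS")

    def test_alpha_is_probability_vector(self, rng):
        m = tiny_model(seed=4)
        for _ in range(20):
            bag = make_bag(rng.standard_normal((rng.integers(1, 30), 3)))
            att, _ = m.attention_pool(bag, "IDS")
            assert np.all(att.alpha >= 0)
            assert abs(att.alpha.sum() - 1.0) < 1e-6


class TestGateFuse:
    def test_zero_gate_weights_give_half_half_mixture(self):
        m = tiny_model()
        set_params(m, W_gate=np.zeros((4, 2)), b_gate=[0.0, 0.0])
        m_wsi = np.array([1.0, -2.0])
        clin = np.array([0.5, 0.25])
        fused = m.gate_fuse(m_wsi, clin)
        assert np.allclose(fused.gate, 0.5)
        expected = 0.5 * (m_wsi @ m.params["W_wsi"].data) + \
            0.5 * (clin @ m.params["W_clin"].data)
        assert np.allclose(fused.m_fused, expected)

    def test_forced_gate_one_ignores_clinical_branch(self):
        m = tiny_model(seed=2)
        m_wsi = np.array([0.3, 0.7])
        f1 = m.gate_fuse(m_wsi, np.array([10.0, -10.0]), force_gate=1.0)
        f2 = m.gate_fuse(m_wsi, np.array([-5.0, 5.0]), force_gate=1.0)
        assert np.allclose(f1.m_fused, f2.m_fused)
        assert np.allclose(f1.m_fused, m_wsi @ m.params["W_wsi"].data)

    def test_matches_hand_computed_fusion(self):
        m = tiny_model()
        W_wsi = np.array([[0.2, -0.1], [0.4, 0.3]])
        W_clin = np.array([[-0.3, 0.5], [0.1, 0.2]])
        W_gate = np.array([[0.1, 0.2], [-0.2, 0.3], [0.4, -0.1], [0.0, 0.5]])
        b_gate = np.array([0.05, -0.05])
        set_params(m, W_wsi=W_wsi, W_clin=W_clin, W_gate=W_gate, b_gate=b_gate)
        mv = np.array([0.6, -0.4])
        cv = np.array([1.0, 2.0])
        fused = m.gate_fuse(mv, cv)
        g = 1 / (1 + np.exp(-(np.concatenate([mv, cv]) @ W_gate + b_gate)))
        expected = g * (mv @ W_wsi) + (1 - g) * (cv @ W_clin)
        assert np.allclose(fused.gate, g, atol=1e-6)
        assert np.allclose(fused.m_fused, expected, atol=1e-6)

    def test_clinical_schema_mismatch_raises(self):
        m = tiny_model()
        with pytest.raises(ValueError, match="clinical"):
            m.gate_fuse(np.zeros(2), np.zeros(5))


class TestHeads:
    def test_zero_logits_give_uniform_probabilities(self):
        m = tiny_model()
        set_params(m, W_head=np.zeros((2, 2)), b_head=[0.0, 0.0])
        pred = m.predict_slide(np.array([3.0, -1.0]))
        assert np.allclose(pred.class_probs, [0.5, 0.5])

    def test_zero_survival_head_gives_zero_risk(self):
        m = tiny_model(task="survival")
        set_params(m, W_head=np.zeros((2, 1)), b_head=[0.0])
        assert m.predict_slide(np.array([7.0, -2.0])).risk == 0.0

    def test_probabilities_match_hand_softmax(self):
        m = tiny_model()
        W = np.array([[1.0, -1.0], [0.5, 0.5]])
        b = np.array([0.1, -0.1])
        set_params(m, W_head=W, b_head=b)
        f = np.array([0.2, 0.8])
        logits = f @ W + b
        expected = np.exp(logits) / np.exp(logits).sum()
        assert np.allclose(m.predict_slide(f).class_probs, expected, atol=1e-9)

    def test_instance_logits_match_hand_computation(self):
        m = tiny_model()
        W_proj = np.eye(3)[:, :2]
        Wi = np.array([[0.5, -0.5], [0.2, 0.8]])
        bi = np.array([0.0, 0.1])
        set_params(m, W_proj=W_proj, b_proj=[0.0, 0.0], W_inst=Wi, b_inst=bi)
        H = np.array([[1.0, 2.0, 0.0], [0.0, -1.0, 3.0]])
        got = m.instance_logits(make_bag(H))
        hp = np.maximum(H @ W_proj, 0)
        assert got.shape == (2, 2)
        assert np.allclose(got, hp @ Wi + bi)


class TestMILInvariants:
    def test_permutation_invariance_of_full_forward(self, rng):
        m = tiny_model(seed=3)
        clin = make_clinical([0.5, -0.5])
        for _ in range(20):
            feats = rng.standard_normal((rng.integers(2, 40), 3))
            perm = rng.permutation(len(feats))
            out1 = m.forward(make_bag(feats), clin)
            out2 = m.forward(make_bag(feats[perm]), clin)
            assert np.allclose(out1["m_wsi"].data, out2["m_wsi"].data, atol=1e-6)
            assert np.allclose(out1["gate"].data, out2["gate"].data, atol=1e-6)
            assert np.allclose(out1["m_fused"].data, out2["m_fused"].data, atol=1e-6)
            assert np.allclose(out1["logits"].data, out2["logits"].data, atol=1e-6)
            assert np.allclose(out1["alpha"].data[perm], out2["alpha"].data,
                               atol=1e-6)

    def test_gate_endpoints_decouple_modalities(self, rng):
        m = tiny_model(seed=5)
        bag_a = make_bag(rng.standard_normal((6, 3)))
        bag_b = make_bag(rng.standard_normal((6, 3)))
        clin_a = make_clinical([1.0, 2.0])
        clin_b = make_clinical([-3.0, 0.5])
        # g ≡ 1: clinical input irrelevant
        p1 = m.predict(bag_a, clin_a, force_gate=1.0)
        p2 = m.predict(bag_a, clin_b, force_gate=1.0)
        assert np.allclose(p1.class_probs, p2.class_probs)
        # g ≡ 0: imaging input irrelevant
        p3 = m.predict(bag_a, clin_a, force_gate=0.0)
        p4 = m.predict(bag_b, clin_a, force_gate=0.0)
        assert np.allclose(p3.class_probs, p4.class_probs)

    def test_routing_touches_only_active_attention_path(self, rng):
        from pathomil.autodiff import Tensor
        from pathomil.losses import cross_entropy_logits
        from pathomil.training import Adam

        m = tiny_model(seed=6)
        before = m.state_dict()
        opt = Adam(m.params, lr=1e-3, weight_decay=1e-4)
        bag = make_bag(rng.standard_normal((10, 3)))
        out = m.forward(bag, make_clinical([0.1, 0.2], surgery="PDS"))
        loss = cross_entropy_logits(out["logits"], 1)
        m.zero_grad()
        loss.backward()
        opt.step()
        after = m.state_dict()
        for k in before:
            if "_IDS" in k or k in ("W_inst", "b_inst"):
                assert np.array_equal(before[k], after[k]), k
        assert not np.array_equal(before["V_PDS"], after["V_PDS"])
        assert not np.array_equal(before["W_proj"], after["W_proj"])


class TestCheckpoint:
    def test_round_trip_and_schema_guard(self, tmp_path, rng):
        m = tiny_model(seed=9)
        schema = ("age", "stage")
        path = tmp_path / "model.npz"
        m.save(path, schema=schema)
        loaded = GatedAttentionMIL.load(path, expected_schema=schema)
        bag = make_bag(rng.standard_normal((4, 3)))
        clin = make_clinical([0.3, 0.4])
        assert np.allclose(
            m.predict(bag, clin).class_probs, loaded.predict(bag, clin).class_probs
        )
        with pytest.raises(ValueError, match="schema"):
            GatedAttentionMIL.load(path, expected_schema=("stage", "age"))


def test_attention_weights_reject_invalid_vectors():
    with pytest.raises(ValueError):
        AttentionWeights(alpha=np.array([0.5, 0.2]), path_used="PDS")
    with pytest.raises(ValueError):
        ClinicalVector(np.array([np.nan]), "PDS")
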