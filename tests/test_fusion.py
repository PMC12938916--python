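"""FiLM modulation and metadata-keyed cross-attention fusion."""

import numpy as np
import pytest

from dermafuse.amcr import AmcrConfig
from dermafuse.autodiff import Tensor
from dermafuse.backbone import BackboneConfig
from dermafuse.datamodel import FeatureMap
from dermafuse.fusion import (
    CrossAttention, FusionConfig, MdfmCaf, Modulator, cross_attention,
    flatten_tokens, fuse, mdfm_caf_forward, modulate, unflatten_tokens,
)
from dermafuse.network import LesionNet
from dermafuse.schema import MetadataSchema

rng = np.random.default_rng(0)
TINY = FusionConfig(channels=4, embed_dim=3)


def _neutralise(mod: Modulator):
    mod.gamma_fc.weight.data[:] = 0
    mod.gamma_fc.bias.data[:] = 1.0
    mod.beta_fc.weight.data[:] = 0
    mod.beta_fc.bias.data[:] = 0


class TestModulationParams:
    def test_constant_params(self):
        mod = Modulator(TINY, np.random.default_rng(0))
        _neutralise(mod)
        g, b = mod(Tensor(rng.normal(size=(2, 3))))
        assert np.allclose(g.data, 1.0) and np.allclose(b.data, 0.0)

    def test_zero_embedding_returns_biases(self):
        mod = Modulator(TINY, np.random.default_rng(0))
        g, b = mod(Tensor(np.zeros((1, 3))))
        assert np.allclose(g.data, mod.gamma_fc.bias.data)
        assert np.allclose(b.data, mod.beta_fc.bias.data)

    def test_matches_affine_oracle(self):
        mod = Modulator(TINY, np.random.default_rng(1))
        e = rng.normal(size=(2, 3))
        g, b = mod(Tensor(e))
        assert np.allclose(g.data, e @ mod.gamma_fc.weight.data.T + mod.gamma_fc.bias.data,
                           atol=1e-6)
        assert np.allclose(b.data, e @ mod.beta_fc.weight.data.T + mod.beta_fc.bias.data,
                           atol=1e-6)


class TestModulate:
    def test_identity(self):
        fm = FeatureMap(rng.normal(size=(3, 2, 2)), stage="recalibrated")
        out = modulate(fm, np.ones(3), np.zeros(3))
        assert np.array_equal(out.values, fm.values)

    def test_zero_scale_gives_constant_channels(self):
        fm = FeatureMap(rng.normal(size=(3, 2, 2)))
        out = modulate(fm, np.zeros(3), np.array([1.0, -2.0, 3.0]))
        for c, beta in enumerate([1.0, -2.0, 3.0]):
            assert np.allclose(out.values[c], beta)

    def test_hand_arithmetic(self):
        fm = FeatureMap(np.array([[[1.0, 2.0], [3.0, 4.0]]]))
        out = modulate(fm, np.array([2.0]), np.array([-1.0]))
        assert np.array_equal(out.values[0], [[1.0, 3.0], [5.0, 7.0]])

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            modulate(FeatureMap(np.zeros((3, 2, 2))), np.ones(5), np.zeros(5))


class TestTokenGrid:
    def test_flatten_unflatten_are_inverse_bijections(self):
        F = Tensor(rng.normal(size=(2, 4, 3, 3)))
        X = flatten_tokens(F)
        assert X.shape == (2, 9, 4)
        assert np.array_equal(unflatten_tokens(X, 3, 3).data, F.data)


def _identity_attention(cfg: FusionConfig) -> CrossAttention:
    ca = CrossAttention(cfg, np.random.default_rng(0))
    C = cfg.channels
    for layer in (ca.q, ca.k, ca.v):
        layer.weight.data = np.eye(C)
        layer.bias.data[:] = 0
    ca.k_meta.weight.data[:] = 0
    ca.k_meta.bias.data[:] = 0
    return ca


class TestCrossAttention:
    def test_softmax_rows_normalised(self):
        ca = CrossAttention(TINY, np.random.default_rng(1))
        F = Tensor(rng.normal(size=(1, 4, 2, 2)))
        e = Tensor(rng.normal(size=(1, 3)))
        X = flatten_tokens(F)
        Q, K, V = ca.q(X), ca.k(X), ca.v(X)
        K_M = ca.k_meta(e).reshape(1, 1, 4)
        scores = (Q @ (K + K_M).transpose(0, 2, 1)) * (1 / np.sqrt(4))
        rows = scores.softmax(axis=-1).data
        assert np.allclose(rows.sum(axis=-1), 1.0, atol=1e-6)

    def test_zero_metadata_key_reduces_to_self_attention(self):
        cfg = FusionConfig(channels=3, embed_dim=2)
        ca = CrossAttention(cfg, np.random.default_rng(2))
        ca.k_meta.weight.data[:] = 0
        ca.k_meta.bias.data[:] = 0
        F = rng.normal(size=(1, 3, 2, 2))
        out = ca(Tensor(F), Tensor(rng.normal(size=(1, 2)))).data

        # independent numpy self-attention oracle
        X = F.reshape(1, 3, 4).transpose(0, 2, 1)[0]
        Q = X @ ca.q.weight.data.T + ca.q.bias.data
        K = X @ ca.k.weight.data.T + ca.k.bias.data
        V = X @ ca.v.weight.data.T + ca.v.bias.data
        S = Q @ K.T / np.sqrt(3)
        P = np.exp(S - S.max(axis=1, keepdims=True))
        P /= P.sum(axis=1, keepdims=True)
        expected = (P @ V).T.reshape(3, 2, 2)
        assert np.allclose(out[0], expected, atol=1e-6)

    def test_two_token_identity_projection_hand_example(self):
        # tokens [1,0] and [0,1], C=2: scores/sqrt(2) give softmax row
        # (0.6698, 0.3302) and the same attention output row
        cfg = FusionConfig(channels=2, embed_dim=2)
        ca = _identity_attention(cfg)
        F = np.array([[[1.0], [0.0]], [[0.0], [1.0]]])  # C=2, H=2, W=1
        out = ca(Tensor(F[None]), Tensor(np.zeros((1, 2)))).data[0]
        assert out[:, 0, 0] == pytest.approx([0.6698, 0.3302], abs=1e-4)

    def test_metadata_gradient_flows_through_key_path(self):
        cfg = FusionConfig(channels=3, embed_dim=2)
        ca = CrossAttention(cfg, np.random.default_rng(3))
        F = Tensor(rng.normal(size=(1, 3, 2, 2)))  # image path blocked (no grad)
        e = Tensor(rng.normal(size=(1, 2)), requires_grad=True)
        ca(F, e).sum().backward()
        assert e.grad is not None and np.any(e.grad != 0)


class TestFuse:
    def test_zero_attention_is_identity(self):
        fm = FeatureMap(rng.normal(size=(3, 2, 2)), stage="modulated")
        out = fuse(fm, FeatureMap(np.zeros((3, 2, 2))))
        assert np.array_equal(out.values, fm.values)
        assert out.stage == "fused"

    def test_additivity(self):
        F = rng.normal(size=(3, 2, 2))
        A = rng.normal(size=(3, 2, 2))
        out = fuse(FeatureMap(F), FeatureMap(A))
        assert np.allclose(out.values - F, A)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            fuse(FeatureMap(np.zeros((3, 2, 2))), FeatureMap(np.zeros((3, 3, 3))))


class TestMdfmCafForward:
    def test_neutral_parameters_give_identity(self):
        module = MdfmCaf(TINY, np.random.default_rng(0))
        _neutralise(module.modulator)
        module.attn.v.weight.data[:] = 0
        module.attn.v.bias.data[:] = 0
        fm = FeatureMap(rng.normal(size=(4, 2, 2)), stage="recalibrated")
        out = mdfm_caf_forward(fm, np.zeros(3), module)
        assert np.allclose(out.values, fm.values, atol=1e-12)
        assert out.stage == "fused"

    def test_matches_stage_by_stage_oracle(self):
        module = MdfmCaf(TINY, np.random.default_rng(5))
        F = rng.normal(size=(4, 2, 2))
        e = rng.normal(size=(3,))
        out = mdfm_caf_forward(FeatureMap(F, stage="recalibrated"), e, module).values

        gamma = e @ module.modulator.gamma_fc.weight.data.T + module.modulator.gamma_fc.bias.data
        beta = e @ module.modulator.beta_fc.weight.data.T + module.modulator.beta_fc.bias.data
        F_mod = F * gamma[:, None, None] + beta[:, None, None]
        X = F_mod.reshape(4, 4).T
        ca = module.attn
        Q = X @ ca.q.weight.data.T + ca.q.bias.data
        K = X @ ca.k.weight.data.T + ca.k.bias.data
        V = X @ ca.v.weight.data.T + ca.v.bias.data
        K_M = e @ ca.k_meta.weight.data.T + ca.k_meta.bias.data
        S = Q @ (K + K_M).T / np.sqrt(4)
        P = np.exp(S - S.max(axis=1, keepdims=True))
        P /= P.sum(axis=1, keepdims=True)
        A = (P @ V).T.reshape(4, 2, 2)
        assert np.allclose(out, F_mod + A, atol=1e-6)

    def test_output_shape_equals_input_shape(self):
        module = MdfmCaf(TINY, np.random.default_rng(1))
        fm = FeatureMap(rng.normal(size=(4, 3, 3)), stage="recalibrated")
        assert mdfm_caf_forward(fm, np.zeros(3), module).shape == (4, 3, 3)


class TestDegradation:
    def test_neutral_metadata_yields_finite_softmax(self):
        """With all-unknown/median metadata the forward pass stays finite and
        produces a valid probability vector (image-heavy inference)."""
        net = LesionNet(BackboneConfig.tiny(input_size=16),
                        AmcrConfig(embed_dim=8, hidden_dim=4), seed=0)
        # initialise batch-norm statistics with one training-mode pass
        from dermafuse.autodiff import no_grad
        with no_grad():
            net(Tensor(rng.normal(size=(2, 3, 16, 16))), Tensor(rng.normal(size=(2, 81))))
        net.eval()
        neutral = MetadataSchema.default().neutral_vector().values
        with no_grad():
            logits = net(Tensor(rng.normal(size=(1, 3, 16, 16))), Tensor(neutral[None]))
        probs = logits.softmax(axis=-1).data
        assert np.all(np.isfinite(probs))
        assert probs.sum() == pytest.approx(1.0, abs=1e-6)
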