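"""Channel recalibration: pooling, metadata embedding, attention gates,
MC-dropout variance and the uncertainty-to-weight mapping."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dermafuse.amcr import (
    AmcrConfig, ChannelAttention, MetadataEmbedder, global_average_pool,
    mc_predictive_variance, mc_softmax_samples, recalibrate, uncertainty_weight,
)
from dermafuse.autodiff import Tensor
from dermafuse.datamodel import FeatureMap

from conftest import CycleModel, NoisyScalarModel

rng = np.random.default_rng(0)


class TestGlobalAveragePool:
    def test_constant_channel(self):
        fm = FeatureMap(np.full((3, 4, 4), 3.0))
        assert np.allclose(global_average_pool(fm).data, 3.0)

    def test_hand_mean(self):
        fm = np.array([[[1.0, 2.0], [3.0, 4.0]]])
        assert global_average_pool(fm).data == pytest.approx([2.5])

    @given(st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_permutation_invariant_over_spatial_positions(self, seed):
        r = np.random.default_rng(seed)
        x = r.normal(size=(2, 3, 3))
        perm = r.permutation(9)
        shuffled = x.reshape(2, 9)[:, perm].reshape(2, 3, 3)
        assert np.allclose(global_average_pool(x).data,
                           global_average_pool(shuffled).data)

    def test_empty_spatial_dims_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            global_average_pool(np.zeros((2, 0, 3)))


TINY = AmcrConfig(metadata_dim=5, embed_dim=4, hidden_dim=3, dropout=0.5, mc_passes=3)


def _identity_bn(bn):
    bn.set_running_stats(np.zeros(bn.gamma.shape[0]), np.ones(bn.gamma.shape[0]) - 1e-5)


class TestMetadataEmbedder:
    def test_zero_input_zero_bias_gives_zero_embedding(self):
        emb = MetadataEmbedder(TINY, np.random.default_rng(0))
        emb.fc.bias.data[:] = 0
        _identity_bn(emb.bn)
        emb.eval()
        out = emb(Tensor(np.zeros((1, 5))))
        assert np.allclose(out.data, 0.0)

    def test_eval_mode_deterministic(self):
        emb = MetadataEmbedder(TINY, np.random.default_rng(0))
        _identity_bn(emb.bn)
        emb.eval()
        M = Tensor(rng.normal(size=(2, 5)))
        assert np.array_equal(emb(M).data, emb(M).data)

    def test_matches_affine_relu_oracle(self):
        emb = MetadataEmbedder(TINY, np.random.default_rng(3))
        _identity_bn(emb.bn)
        emb.eval()
        M = rng.normal(size=(4, 5))
        expected = np.maximum(
            (M @ emb.fc.weight.data.T + emb.fc.bias.data) /
            np.sqrt(1.0 - 1e-5 + emb.bn.eps), 0.0)
        assert np.allclose(emb(Tensor(M)).data, expected, atol=1e-6)

    def test_uninitialised_bn_eval_is_state_error(self):
        emb = MetadataEmbedder(TINY, np.random.default_rng(0))
        emb.eval()
        with pytest.raises(RuntimeError, match="running statistics"):
            emb(Tensor(np.zeros((1, 5))))


class TestChannelAttention:
    def test_zero_parameters_give_half_gates(self):
        att = ChannelAttention(4, TINY, np.random.default_rng(0))
        for layer in (att.fc1, att.fc2):
            layer.weight.data[:] = 0
            layer.bias.data[:] = 0
        alpha = att(Tensor(np.ones((1, 4))), Tensor(np.ones((1, 4))))
        assert np.allclose(alpha.data, 0.5)

    def test_gates_strictly_inside_unit_interval(self):
        att = ChannelAttention(6, TINY, np.random.default_rng(1))
        alpha = att(Tensor(rng.normal(size=(3, 6)) * 10),
                    Tensor(rng.normal(size=(3, 4)) * 10)).data
        assert alpha.min() > 0.0 and alpha.max() < 1.0

    def test_matches_two_layer_oracle(self):
        att = ChannelAttention(4, TINY, np.random.default_rng(2))
        z = rng.normal(size=(2, 4))
        e = rng.normal(size=(2, 4))
        joint = np.concatenate([z, e], axis=1)
        h = np.maximum(joint @ att.fc1.weight.data.T + att.fc1.bias.data, 0)
        expected = 1 / (1 + np.exp(-(h @ att.fc2.weight.data.T + att.fc2.bias.data)))
        assert np.allclose(att(Tensor(z), Tensor(e)).data, expected, atol=1e-6)


class TestRecalibrate:
    def test_unit_gates_identity(self):
        fm = FeatureMap(rng.normal(size=(3, 2, 2)))
        out = recalibrate(fm, np.ones(3))
        assert np.array_equal(out.values, fm.values)
        assert out.stage == "recalibrated"

    def test_zero_gates_annihilate(self):
        fm = FeatureMap(rng.normal(size=(3, 2, 2)))
        assert np.all(recalibrate(fm, np.zeros(3)).values == 0)

    def test_contraction_for_gates_in_unit_interval(self):
        fm = FeatureMap(rng.normal(size=(4, 3, 3)))
        alpha = rng.uniform(0.01, 0.99, 4)
        out = recalibrate(fm, alpha)
        assert np.all(np.abs(out.values) <= np.abs(fm.values) + 1e-12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="channel count"):
            recalibrate(FeatureMap(np.zeros((3, 2, 2))), np.ones(5))


class TestEndToEndRecalibration:
    def test_composition_matches_from_scratch_oracle(self):
        """Pool -> embed -> attention -> gate equals a hand-coded numpy chain."""
        cfg = AmcrConfig(metadata_dim=5, embed_dim=4, hidden_dim=3, dropout=0.0)
        r = np.random.default_rng(9)
        emb = MetadataEmbedder(cfg, r)
        att = ChannelAttention(4, cfg, r)
        _identity_bn(emb.bn)
        emb.eval()
        att.eval()

        F = rng.normal(size=(1, 4, 2, 2))
        M = rng.normal(size=(1, 5))
        z = global_average_pool(Tensor(F))
        e = emb(Tensor(M))
        alpha = att(z, e)
        out = recalibrate(Tensor(F), alpha).data

        # independent composition
        z_o = F.mean(axis=(2, 3))
        e_o = np.maximum((M @ emb.fc.weight.data.T + emb.fc.bias.data) /
                         np.sqrt(1 - 1e-5 + emb.bn.eps), 0)
        joint = np.concatenate([z_o, e_o], axis=1)
        h = np.maximum(joint @ att.fc1.weight.data.T + att.fc1.bias.data, 0)
        a_o = 1 / (1 + np.exp(-(h @ att.fc2.weight.data.T + att.fc2.bias.data)))
        expected = F * a_o[:, :, None, None]
        assert np.allclose(out, expected, atol=1e-6)


class TestMcVariance:
    def test_zero_dropout_rate_gives_zero_variance(self):
        model = NoisyScalarModel(p=0.0)
        var = mc_predictive_variance(model, np.zeros((3, 2, 2)), np.zeros(5), T=5)
        assert np.allclose(var, 0.0)

    def test_single_pass_gives_zero_variance(self):
        model = NoisyScalarModel(p=0.5)
        var = mc_predictive_variance(model, np.zeros((3, 2, 2)), np.zeros(5), T=1)
        assert np.allclose(var, 0.0)

    def test_population_variance_hand_example(self):
        # two passes yielding class probabilities 0.4 and 0.6 -> variance 0.01
        model = CycleModel([np.log([0.4, 0.6]), np.log([0.6, 0.4])])
        var = mc_predictive_variance(model, np.zeros((3, 2, 2)), np.zeros(5), T=2)
        assert var == pytest.approx([0.01, 0.01])

    def test_invalid_pass_count_rejected(self):
        with pytest.raises(ValueError, match="T"):
            mc_predictive_variance(NoisyScalarModel(), np.zeros((3, 2, 2)),
                                   np.zeros(5), T=0)

    def test_seeded_and_reproducible(self):
        model = NoisyScalarModel(p=0.5)
        a = mc_predictive_variance(model, np.zeros((3, 2, 2)), np.zeros(5), T=8, seed=3)
        b = mc_predictive_variance(model, np.zeros((3, 2, 2)), np.zeros(5), T=8, seed=3)
        assert np.array_equal(a, b)

    def test_estimator_variance_shrinks_with_more_passes(self):
        """The variance estimate stabilises as T grows (estimator consistency)."""
        model = NoisyScalarModel(p=0.5)
        spread = {}
        for T in (10, 100, 1000):
            estimates = [mc_predictive_variance(model, np.zeros((3, 2, 2)),
                                                np.zeros(5), T=T, seed=s)[0]
                         for s in range(12)]
            spread[T] = np.var(estimates)
        assert spread[1000] < spread[100] < spread[10]


class TestUncertaintyWeight:
    def test_logistic_at_zero(self):
        assert uncertainty_weight(0.0) == 0.5

    def test_direct_evaluation(self):
        assert uncertainty_weight(0.25, lam=0.1) == pytest.approx(
            1 / (1 + np.exp(-0.025)))

    @given(st.floats(0.0, 0.25), st.floats(0.0, 0.25))
    @settings(max_examples=50, deadline=None)
    def test_monotone_and_bounded_on_softmax_variances(self, a, b):
        lo, hi = sorted((a, b))
        w_lo, w_hi = uncertainty_weight(lo), uncertainty_weight(hi)
        if hi - lo > 1e-12:  # strictly increasing wherever floats can resolve it
            assert w_lo < w_hi
        else:
            assert w_lo <= w_hi
        # softmax variance is at most 0.25, so weights live in this band
        assert 0.5 <= w_lo <= w_hi <= 1 / (1 + np.exp(-0.025))

    def test_negative_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            uncertainty_weight(-0.1)
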