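"""Pooling, affine fusion, prediction head, and loss-function oracles."""

import math

import numpy as np
import pytest

from gsfl.fusion_head_loss import (
    FusionHead,
    LossConfig,
    bce_with_logits,
    contrastive_loss,
    fusion_loss,
    global_attention_pool_masked,
    global_attention_pool_segments,
)
from gsfl.nn import Linear, Tensor


@pytest.fixture
def gate(rng):
    return Linear(4, 1, rng)


class TestGlobalAttentionPool:
    def test_single_item_returns_itself(self, gate, rng):
        x = Tensor(rng.normal(size=(1, 4)))
        out = global_attention_pool_segments(x, np.array([0]), 1, gate)
        np.testing.assert_allclose(out.data, x.data, atol=1e-12)

    def test_identical_items_return_common_vector(self, gate):
        row = np.arange(4.0)
        x = Tensor(np.tile(row, (5, 1)))
        out = global_attention_pool_segments(x, np.zeros(5, dtype=int), 1, gate)
        np.testing.assert_allclose(out.data[0], row, atol=1e-12)

    def test_weights_sum_to_one_per_molecule(self, gate, rng):
        x = Tensor(rng.normal(size=(7, 4)))
        seg = np.array([0, 0, 0, 1, 1, 2, 2])
        out = global_attention_pool_segments(x, seg, 3, gate)
        # pooled vector is a convex combination: lies within coordinate bounds
        for s in range(3):
            rows = x.data[seg == s]
            assert np.all(out.data[s] <= rows.max(axis=0) + 1e-12)
            assert np.all(out.data[s] >= rows.min(axis=0) - 1e-12)

    def test_masked_variant_matches_segment_variant(self, gate, rng):
        x = rng.normal(size=(2, 3, 4))
        mask = np.ones((2, 3))
        dense = global_attention_pool_masked(Tensor(x), mask, gate).data
        flat = Tensor(x.reshape(6, 4))
        seg = np.repeat([0, 1], 3)
        ragged = global_attention_pool_segments(flat, seg, 2, gate).data
        np.testing.assert_allclose(dense, ragged, atol=1e-12)

    def test_empty_pool_raises(self, gate):
        with pytest.raises(ValueError):
            global_attention_pool_masked(Tensor(np.zeros((1, 3, 4))),
                                         np.zeros((1, 3)), gate)


@pytest.fixture
def head(rng):
    return FusionHead(d_seq=6, d_graph=4, fusion_dim=5, rng=rng, dropout=0.0)


class TestWeightedFusion:
    def test_identity_weights_pass_sequence_through(self, head, rng):
        head.W_s.W.data = np.eye(5)
        head.W_g.W.data = np.zeros((5, 5))
        head.b.data = np.zeros(5)
        H_s = Tensor(rng.normal(size=(3, 5)))
        H_g = Tensor(rng.normal(size=(3, 5)))
        np.testing.assert_allclose(head.weighted_fusion(H_s, H_g).data,
                                   H_s.data, atol=1e-12)

    def test_zero_inputs_give_bias(self, head):
        head.b.data = np.arange(5.0)
        out = head.weighted_fusion(Tensor(np.zeros((2, 5))),
                                   Tensor(np.zeros((2, 5))))
        np.testing.assert_allclose(out.data, np.tile(np.arange(5.0), (2, 1)))

    def test_linearity_in_each_argument(self, head, rng):
        a, a2 = Tensor(rng.normal(size=(2, 5))), Tensor(rng.normal(size=(2, 5)))
        g = Tensor(rng.normal(size=(2, 5)))
        zero = Tensor(np.zeros((2, 5)))
        lhs = head.weighted_fusion(a + a2, g).data
        rhs = (head.weighted_fusion(a, g).data
               + head.weighted_fusion(a2, g).data
               - head.weighted_fusion(zero, g).data)
        np.testing.assert_allclose(lhs, rhs, atol=1e-10)

    def test_width_mismatch_raises(self, head, rng):
        with pytest.raises(ValueError):
            head.weighted_fusion(Tensor(rng.normal(size=(2, 3))),
                                 Tensor(rng.normal(size=(2, 5))))


class TestPredictionHead:
    def test_logit_shape(self, head, rng):
        logits, Z_s, Z_g = head(Tensor(rng.normal(size=(4, 6))),
                                Tensor(rng.normal(size=(4, 4))))
        assert logits.shape == (4,)
        assert Z_s.shape == (4, 5) and Z_g.shape == (4, 5)

    def test_all_zero_weights_give_probability_half(self, rng):
        h = FusionHead(d_seq=6, d_graph=4, fusion_dim=5, rng=rng, dropout=0.0)
        for p in h.parameters():
            p.data = np.zeros_like(p.data)
        logits, _, _ = h(Tensor(rng.normal(size=(3, 6))),
                         Tensor(rng.normal(size=(3, 4))))
        np.testing.assert_allclose(logits.data, 0.0)
        np.testing.assert_allclose(1 / (1 + np.exp(-logits.data)), 0.5)

    def test_head_parameter_count_matches_layer_sizes(self, head):
        fusion_dim = 5
        expected = (fusion_dim * 256 + 256) + (256 * 64 + 64) + (64 * 1 + 1)
        got = sum(p.data.size for p in head.head.parameters())
        assert got == expected


class TestContrastiveLoss:
    def test_orthonormal_pair_value_is_minus_two(self):
        z = np.eye(2)
        loss = contrastive_loss(Tensor(z), Tensor(z), temperature=1.0)
        assert loss.data == pytest.approx(-2.0, abs=1e-9)

    def test_rotation_invariance(self, rng):
        zs = rng.normal(size=(5, 4))
        zg = rng.normal(size=(5, 4))
        q, _ = np.linalg.qr(rng.normal(size=(4, 4)))
        a = contrastive_loss(Tensor(zs), Tensor(zg), 0.5).data
        b = contrastive_loss(Tensor(zs @ q), Tensor(zg @ q), 0.5).data
        assert a == pytest.approx(b, abs=1e-9)

    def test_worst_case_alignment_is_positive(self):
        # anchor orthogonal to its positive but collinear with negatives
        zs = np.array([[1.0, 0.0], [0.0, 1.0], [0.0, 1.0]])
        zg = np.array([[0.0, 1.0], [0.0, 1.0], [0.0, 1.0]])
        T = 1.0
        loss = contrastive_loss(Tensor(zs), Tensor(zg), T).data
        # s-anchor i=0 term alone: -log(e^0 / (2 e^{1/T})) > 0
        assert loss > 0

    def test_monotone_in_matched_similarity(self):
        base = np.array([[1.0, 0.0], [0.0, 1.0]])
        losses = []
        for eps in (0.0, 0.3, 0.6):
            zs = base.copy()
            zg = base.copy()
            zg[0] = [math.cos(eps), math.sin(eps)]  # rotate positive away
            losses.append(contrastive_loss(Tensor(zs), Tensor(zg), 0.5).data)
        assert losses[0] < losses[1] < losses[2]

    def test_small_batch_and_bad_temperature_raise(self, rng):
        z = Tensor(rng.normal(size=(1, 3)))
        with pytest.raises(ValueError):
            contrastive_loss(z, z, 1.0)
        z2 = Tensor(rng.normal(size=(2, 3)))
        with pytest.raises(ValueError):
            contrastive_loss(z2, z2, 0.0)

    def test_ntxent_variant_is_nonnegative_shifted(self):
        z = np.eye(2)
        loss = contrastive_loss(Tensor(z), Tensor(z), 1.0, variant="ntxent")
        # denominator now includes the positive pair, so each term is
        # -log(e/(e+1)) > 0
        expected = 2 * (-math.log(math.e / (math.e + 1.0)))
        assert loss.data == pytest.approx(expected, abs=1e-12)


class TestBCEAndFusionLoss:
    def test_zero_logit_label_one_is_ln2(self):
        loss = bce_with_logits(Tensor(np.array([0.0])), np.array([1]))
        assert loss.data == pytest.approx(math.log(2.0), abs=1e-12)

    def test_saturated_logits_vanish(self):
        logits = Tensor(np.array([20.0, -20.0]))
        loss = bce_with_logits(logits, np.array([1, 0]))
        assert loss.data < 1e-6

    def test_sum_over_samples(self):
        logits = Tensor(np.zeros(4))
        loss = bce_with_logits(logits, np.array([1, 1, 0, 0]))
        assert loss.data == pytest.approx(4 * math.log(2.0), abs=1e-12)

    def test_alpha_zero_reduces_to_bce(self, rng):
        logits = Tensor(rng.normal(size=(4,)))
        labels = np.array([0, 1, 0, 1])
        zs = Tensor(rng.normal(size=(4, 3)))
        zg = Tensor(rng.normal(size=(4, 3)))
        total, bce_v, con_v = fusion_loss(
            logits, labels, zs, zg, LossConfig(alpha=0.0))
        assert con_v == 0.0
        assert total.data == pytest.approx(
            bce_with_logits(logits, labels).data)

    def test_invalid_labels_raise(self, rng):
        with pytest.raises(ValueError):
            bce_with_logits(Tensor(rng.normal(size=(2,))), np.array([0, 2]))

    def test_gradient_reaches_both_branch_weights(self, head, rng):
        H_s = Tensor(rng.normal(size=(4, 6)))
        H_g = Tensor(rng.normal(size=(4, 4)))
        logits, Z_s, Z_g = head(H_s, H_g)
        loss, _, _ = fusion_loss(logits, np.array([0, 1, 1, 0]), Z_s, Z_g,
                                 LossConfig(alpha=0.1, temperature=0.5))
        loss.backward()
        assert head.W_s.W.grad is not None and np.abs(head.W_s.W.grad).sum() > 0
        assert head.W_g.W.grad is not None and np.abs(head.W_g.W.grad).sum() > 0
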