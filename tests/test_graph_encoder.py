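"""Message passing and feature attention against hand/loop oracles."""

import numpy as np
import pytest

from gsfl.data_io import ATOM_FDIM, build_mol_graph
from gsfl.graph_encoder import GraphEncoder, batch_graphs
from gsfl.nn import Tensor


@pytest.fixture
def encoder(rng):
    return GraphEncoder(d_hidden=8, n_layers=3, rng=rng, dropout=0.0,
                        reduction_ratio=4)


def _batch(smiles_list):
    return batch_graphs([build_mol_graph(s) for s in smiles_list])


class TestInitHidden:
    def test_zero_features_give_zero_hidden(self, encoder):
        batch = _batch(["CCO"])
        batch.atom_features = np.zeros_like(batch.atom_features)
        batch.edge_features = np.zeros_like(batch.edge_features)
        h_v, h_e = encoder.init_hidden(batch)
        assert np.all(h_v.data == 0) and np.all(h_e.data == 0)

    def test_shapes_for_worked_example(self, encoder):
        batch = _batch(["c1(ccc2nc3CCCCc3c(c2c1)N)N"])
        h_v, h_e = encoder.init_hidden(batch)
        assert h_v.shape == (16, 8)
        assert h_e.shape == (36, 8)  # 2 x 18 directed edges

    def test_nonnegative_after_relu(self, encoder):
        h_v, h_e = encoder.init_hidden(_batch(["CC(=O)NC"]))
        assert np.all(h_v.data >= 0) and np.all(h_e.data >= 0)


class TestMessagePassStep:
    def test_single_atom_message_is_zero(self, encoder):
        batch = _batch(["C"])
        h_v, h_e = encoder.init_hidden(batch)
        m = encoder._aggregate(h_e, batch)
        assert m.shape == (1, 8)
        assert np.all(m.data == 0)

    def test_zero_edge_weight_freezes_edge_states(self, encoder):
        batch = _batch(["CCO"])
        encoder.W_edge.W.data = np.zeros_like(encoder.W_edge.W.data)
        h_v, h_e = encoder.init_hidden(batch)
        h_e0 = h_e
        for k in (1, 2, 3):
            h_v, h_e = encoder.message_pass_step(h_v, h_e, h_e0, batch, k)
            np.testing.assert_allclose(h_e.data, h_e0.data)

    def test_two_atom_message_is_squared_edge_state(self, encoder):
        # one incoming edge: sum and max coincide, so m = h_e ⊙ h_e
        batch = _batch(["CO"])
        _, h_e = encoder.init_hidden(batch)
        m = encoder._aggregate(h_e, batch)
        for atom in (0, 1):
            incoming = [i for i, (u, v) in enumerate([(0, 1), (1, 0)])
                        if v == atom]
            expect = h_e.data[incoming[0]] ** 2
            np.testing.assert_allclose(m.data[atom], expect)

    def test_out_of_range_iteration_raises(self, encoder):
        batch = _batch(["CC"])
        h_v, h_e = encoder.init_hidden(batch)
        with pytest.raises(ValueError):
            encoder.message_pass_step(h_v, h_e, h_e, batch, 4)

    def test_loop_oracle_on_path_graph(self, rng):
        """One step on a 3-atom path computed with explicit Python loops."""
        enc = GraphEncoder(d_hidden=4, n_layers=1, rng=rng, dropout=0.0,
                           reduction_ratio=2)
        batch = _batch(["CCO"])
        h_v, h_e = enc.init_hidden(batch)
        h_v1, h_e1 = enc.message_pass_step(h_v, h_e, h_e, batch, 1)

        # oracle: explicit per-atom / per-edge arithmetic
        edges = [(0, 1), (1, 0), (1, 2), (2, 1)]
        hv0, he0 = h_v.data, h_e.data
        m = np.zeros((3, 4))
        for atom in range(3):
            inc = [i for i, (u, v) in enumerate(edges) if v == atom]
            s = np.sum([he0[i] for i in inc], axis=0)
            mx = np.max([he0[i] for i in inc], axis=0)
            m[atom] = s * mx
        l1, l2 = enc.communicate[0].layers
        hv1 = np.maximum(
            np.concatenate([m, hv0], axis=1) @ l1.W.data + l1.b.data, 0.0
        ) @ l2.W.data + l2.b.data
        np.testing.assert_allclose(h_v1.data, hv1, atol=1e-10)
        he1 = np.zeros_like(he0)
        for i, (u, v) in enumerate(edges):
            he1[i] = np.maximum(
                he0[i] + (hv1[u] - he0[i]) @ enc.W_edge.W.data, 0.0)
        np.testing.assert_allclose(h_e1.data, he1, atol=1e-10)


class TestReadout:
    def test_output_shape(self, encoder):
        batch = _batch(["CC(=O)NC", "c1ccccc1"])
        out = encoder(batch)
        assert out.shape == (batch.n_atoms, 8)

    def test_single_layer_equals_step_plus_readout(self, rng):
        enc = GraphEncoder(d_hidden=8, n_layers=1, rng=rng, dropout=0.0)
        batch = _batch(["CCO"])
        full = enc(batch).data
        h_v, h_e = enc.init_hidden(batch)
        h_v, h_e = enc.message_pass_step(h_v, h_e, h_e, batch, 1)
        manual = enc.readout_nodes(h_v, h_e, batch)
        manual = enc.feature_attention(manual, batch)
        np.testing.assert_allclose(full, manual.data)

    def test_deterministic_at_inference(self, encoder):
        batch = _batch(["CC(=O)NC"])
        np.testing.assert_array_equal(encoder(batch).data, encoder(batch).data)


class TestFeatureAttention:
    def test_zero_excitation_halves_hidden(self, rng):
        enc = GraphEncoder(d_hidden=8, n_layers=1, rng=rng, reduction_ratio=4)
        enc.W1_fa.W.data = np.zeros_like(enc.W1_fa.W.data)
        enc.W2_fa.W.data = np.zeros_like(enc.W2_fa.W.data)
        batch = _batch(["CCO"])
        h = Tensor(np.random.default_rng(1).normal(size=(3, 8)))
        out = enc.feature_attention(h, batch)
        np.testing.assert_allclose(out.data, 0.5 * h.data)

    def test_zero_hidden_stays_zero(self, encoder):
        batch = _batch(["CCO"])
        out = encoder.feature_attention(Tensor(np.zeros((3, 8))), batch)
        assert np.all(out.data == 0)

    def test_singleton_pooling(self, encoder):
        batch = _batch(["C"])
        h = Tensor(np.random.default_rng(2).normal(size=(1, 8)))
        from gsfl.nn import segment_max, segment_sum
        g_sum = segment_sum(h, batch.atom_graph_ids, 1)
        g_max = segment_max(h, batch.atom_graph_ids, 1)
        np.testing.assert_allclose(g_sum.data, h.data)
        np.testing.assert_allclose(g_max.data, h.data)

    def test_attention_weights_strictly_inside_unit_interval(self, encoder):
        batch = _batch(["CC(=O)NC"])
        h = encoder(batch)
        g_sum_W2 = encoder.W2_fa(h)
        c = encoder.W1_fa(g_sum_W2.relu()).sigmoid().data
        assert np.all(c > 0) and np.all(c < 1)

    def test_magnitude_never_grows(self, encoder):
        batch = _batch(["CC(=O)NC"])
        h = Tensor(np.random.default_rng(3).normal(size=(batch.n_atoms, 8)))
        out = encoder.feature_attention(h, batch)
        assert np.all(np.abs(out.data) <= np.abs(h.data) + 1e-15)


class TestWholeEncoder:
    def test_permutation_equivariance(self, rng):
        """Relabeling atoms permutes output rows identically."""
        enc = GraphEncoder(d_hidden=8, n_layers=2, rng=rng, dropout=0.0)
        g = build_mol_graph("CC(=O)Nc1ccccc1")
        batch = batch_graphs([g])
        out = enc(batch).data

        perm = np.random.default_rng(4).permutation(g.n_atoms)
        inv = np.argsort(perm)
        g2 = build_mol_graph("CC(=O)Nc1ccccc1")
        g2.atom_features = g.atom_features[perm]
        g2.edges = [(int(inv[u]), int(inv[v])) for u, v in g.edges]
        batch2 = batch_graphs([g2])
        out2 = enc(batch2).data
        np.testing.assert_allclose(out2, out[perm], atol=1e-10)

    def test_finite_outputs_on_generated_corpus(self, rng, toy_smiles):
        enc = GraphEncoder(d_hidden=16, n_layers=3, rng=rng, dropout=0.0)
        batch = _batch(toy_smiles[:200])
        out = enc(batch).data
        assert np.isfinite(out).all()

    def test_batching_equals_individual_encoding(self, encoder):
        smiles = ["CCO", "c1ccccc1", "CC(=O)N"]
        together = encoder(_batch(smiles)).data
        offset = 0
        for s in smiles:
            single = encoder(_batch([s])).data
            np.testing.assert_allclose(
                together[offset:offset + len(single)], single, atol=1e-10)
            offset += len(single)
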