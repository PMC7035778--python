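"""Message passing encoder: shapes, hand-checked values, oracle and gradients."""

import numpy as np
import pytest

import molmpn as m
from molmpn import chemgraph as cg
from molmpn import encoder as enc

from oracle import reference_encode

CAFFEINE = "CN1C=NC2=C1C(=O)N(C)C(=O)N2C"


def params64(hidden=4, depth=3, seed=0, activation="relu"):
    return enc.init_encoder_params(hidden, depth, seed=seed, activation=activation, dtype=np.float64)


class TestMergedEdgeInput:
    def test_single_bond_rows(self):
        g = m.mol_to_graph("CN")
        X = enc.merged_edge_input(g)
        assert X.shape == (2, 150)
        for e in range(2):
            np.testing.assert_array_equal(X[e, :139], g.atom_features[g.edge_source[e]])
            np.testing.assert_array_equal(X[e, 139:], g.edge_features[e])

    def test_reverse_edges_differ_only_in_atom_block(self):
        g = m.mol_to_graph("CN")
        X = enc.merged_edge_input(g)
        assert not np.array_equal(X[0, :139], X[1, :139])
        np.testing.assert_array_equal(X[0, 139:], X[1, 139:])

    def test_caffeine_shape(self):
        assert enc.merged_edge_input(m.mol_to_graph(CAFFEINE)).shape == (30, 150)


class TestInitMessages:
    def test_zero_weights_give_zero_messages(self):
        g = m.mol_to_graph("CCO")
        p = params64()
        p.W_inp[...] = 0.0
        assert np.all(enc.init_messages(g, p).messages == 0.0)

    def test_all_ones_row_counts_active_bits(self):
        g = m.mol_to_graph("CC")
        p = enc.EncoderParams(W_inp=np.ones((1, 150)), W_h=np.ones((1, 1)),
                              W_o=np.ones((1, 1)), W_ah=np.ones((1, 139)),
                              hidden_size=1, depth=1)
        X = enc.merged_edge_input(g)
        np.testing.assert_allclose(enc.init_messages(g, p).messages[:, 0], X.sum(axis=1))

    def test_identical_merged_features_get_identical_messages(self):
        # both directed edges of ethane have the same source features
        g = m.mol_to_graph("CC")
        msgs = enc.init_messages(g, params64()).messages
        np.testing.assert_array_equal(msgs[0], msgs[1])


class TestUpdateMessages:
    def test_degree_one_sources_are_constant_in_depth(self):
        g = m.mol_to_graph("CC")  # both sources have no other neighbour
        p = params64()
        m1 = enc.init_messages(g, p)
        m2 = enc.update_messages(m1, g, p)
        np.testing.assert_array_equal(m1.messages, m2.messages)
        assert m2.depth == 2

    def test_interior_edges_do_change(self):
        g = m.mol_to_graph("CCO")
        p = params64(seed=3)
        m1 = enc.init_messages(g, p)
        m2 = enc.update_messages(m1, g, p)
        # edges leaving the middle carbon aggregate a neighbour message
        changed = np.abs(m2.messages - m1.messages).max(axis=1) > 0
        assert changed.any()

    def test_three_atom_path_matches_bruteforce(self):
        g = m.mol_to_graph("CCO")
        p = params64(hidden=2, depth=2, seed=7)
        G = enc.encode(g, p).G
        np.testing.assert_allclose(G, reference_encode(g, p), atol=1e-12)


class TestNodeHidden:
    def test_isolated_atom_uses_self_features_only(self):
        g = m.mol_to_graph("C")
        p = params64()
        G = enc.encode(g, p).G
        expect = np.maximum(p.W_o @ (p.W_ah @ g.atom_features[0].astype(float)), 0.0)
        np.testing.assert_allclose(G[0], expect, atol=1e-12)

    def test_zero_weights_give_zero_representation(self):
        g = m.mol_to_graph(CAFFEINE)
        p = params64()
        for w in (p.W_inp, p.W_h, p.W_o, p.W_ah):
            w[...] = 0.0
        assert np.all(enc.encode(g, p).G == 0.0)


class TestEncode:
    def test_batch_equals_stack_of_singles(self, fixture_graphs):
        p = params64(hidden=6, depth=3, seed=1)
        batch = m.batch_graphs(fixture_graphs)
        G_batch = enc.encode(batch, p).G
        G_stack = np.vstack([enc.encode(g, p).G for g in fixture_graphs])
        np.testing.assert_allclose(G_batch, G_stack, atol=1e-10)

    def test_depth_one_is_node_hidden_of_initial_messages(self):
        g = m.mol_to_graph("CCO")
        p = params64(depth=1)
        G = enc.encode(g, p).G
        G2 = enc.node_hidden(g, enc.init_messages(g, p), p).G
        np.testing.assert_array_equal(G, G2)

    @pytest.mark.parametrize("activation", ["relu", "tanh"])
    def test_oracle_equivalence_on_fixture_molecules(self, fixture_graphs, activation):
        p = params64(hidden=5, depth=4, seed=9, activation=activation)
        for g in fixture_graphs:
            np.testing.assert_allclose(
                enc.encode(g, p).G, reference_encode(g, p), atol=1e-10)

    def test_permutation_equivariance(self, rng):
        from rdkit import Chem
        mol = Chem.MolFromSmiles(CAFFEINE)
        perm = rng.permutation(mol.GetNumAtoms()).tolist()
        alt = Chem.MolToSmiles(Chem.RenumberAtoms(mol, perm), canonical=False)
        p = params64(hidden=6, depth=3, seed=2)
        G1 = enc.encode(m.mol_to_graph(CAFFEINE), p).G
        G2 = enc.encode(m.mol_to_graph(alt), p).G
        # same multiset of atom representations regardless of atom order
        r1 = np.array(sorted(map(tuple, np.round(G1, 8))))
        r2 = np.array(sorted(map(tuple, np.round(G2, 8))))
        np.testing.assert_allclose(r1, r2, atol=1e-6)

    def test_locality_radius_bounded_by_depth(self):
        # with depth 2, atom 0 of a chain cannot see an extension at distance 3+
        p = params64(hidden=4, depth=2, seed=5)
        G_short = enc.encode(m.mol_to_graph("CCCC"), p).G
        G_long = enc.encode(m.mol_to_graph("CCCCC"), p).G
        np.testing.assert_allclose(G_short[0], G_long[0], atol=1e-12)
        # ...but a depth-4 encoder does see it
        p4 = params64(hidden=4, depth=5, seed=5)
        G_short4 = enc.encode(m.mol_to_graph("CCCC"), p4).G
        G_long4 = enc.encode(m.mol_to_graph("CCCCC"), p4).G
        assert np.abs(G_short4[0] - G_long4[0]).max() > 0


class TestCachedForwardAndBackward:
    def test_cached_forward_matches_plain_encode(self, fixture_graphs):
        p = params64(hidden=6, depth=3, seed=4)
        batch = m.batch_graphs(fixture_graphs)
        G_plain = enc.encode(batch, p).G
        G_cached, _ = enc.encode_with_cache(batch, p)
        np.testing.assert_allclose(G_plain, G_cached, atol=1e-12)

    @pytest.mark.parametrize("activation", ["tanh", "elu", "selu", "leakyrelu"])
    def test_gradients_match_finite_differences(self, activation, fixture_graphs):
        p = params64(hidden=3, depth=3, seed=6, activation=activation)
        g = fixture_graphs[0]
        target = np.linspace(-1, 1, g.n_atoms * 3).reshape(g.n_atoms, 3)

        def loss_of(params):
            G, _ = enc.encode_with_cache(g, params)
            return 0.5 * float(((G - target) ** 2).sum())

        G, cache = enc.encode_with_cache(g, p)
        grads = enc.encode_backward(G - target, g, p, cache)
        rng = np.random.default_rng(0)
        for name in ("W_inp", "W_h", "W_o", "W_ah"):
            w = getattr(p, name)
            flat = w.reshape(-1)
            for _ in range(4):
                i = rng.integers(flat.size)
                eps, old = 1e-6, flat[i]
                flat[i] = old + eps
                lp = loss_of(p)
                flat[i] = old - eps
                lm = loss_of(p)
                flat[i] = old
                num = (lp - lm) / (2 * eps)
                ana = grads[name].reshape(-1)[i]
                assert abs(num - ana) <= 1e-6 * max(1.0, abs(num)), (name, activation)


def test_invalid_activation_rejected():
    with pytest.raises(ValueError, match="unknown activation"):
        enc.get_activation("swish")


def test_dimension_mismatch_rejected():
    with pytest.raises(ValueError, match="shape"):
        enc.EncoderParams(W_inp=np.zeros((4, 150)), W_h=np.zeros((4, 4)),
                          W_o=np.zeros((4, 4)), W_ah=np.zeros((4, 100)),
                          hidden_size=4, depth=2)
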