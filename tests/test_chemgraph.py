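"""Dataset I/O, cleaning, featurization and directed-graph construction."""

import numpy as np
import pytest
from rdkit import Chem

import molmpn as m
from molmpn import chemgraph as cg

CAFFEINE = "CN1C=NC2=C1C(=O)N(C)C(=O)N2C"


# ---------------------------------------------------------------------------
# dataset reading / cleaning


def _write(tmp_path, text, name="d.csv"):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestReadDataset:
    def test_reads_one_record_per_row(self, tmp_path):
        p = _write(tmp_path, "smiles,value\nCCO,1.2\nc1ccccc1,2.1\n")
        recs = m.read_dataset(p, ["value"])
        assert len(recs) == 2
        assert recs[0].smiles == "CCO" and recs[0].targets[0] == pytest.approx(1.2)
        assert all(r.mask.all() for r in recs)

    def test_blank_cell_is_unobserved(self, tmp_path):
        p = _write(tmp_path, "smiles,value\nCCO,1.2\nCCN,\n")
        recs = m.read_dataset(p, ["value"])
        assert recs[0].mask[0] and not recs[1].mask[0]

    def test_disjoint_two_property_coverage(self, tmp_path):
        p = _write(tmp_path, "smiles,logp,logs\nCCO,1.0,\nCCN,,2.0\nCCC,0.5,0.6\n")
        recs = m.read_dataset(p, ["logp", "logs"])
        masks = np.stack([r.mask for r in recs])
        assert masks.tolist() == [[True, False], [False, True], [True, True]]

    def test_missing_column_is_an_error(self, tmp_path):
        p = _write(tmp_path, "smiles,value\nCCO,1.2\n")
        with pytest.raises(ValueError, match="nope"):
            m.read_dataset(p, ["nope"])

    def test_empty_file_gives_empty_list(self, tmp_path):
        assert m.read_dataset(_write(tmp_path, "")) == []

    def test_roundtrip_through_writer(self, tmp_path):
        recs = [m.DatasetRecord("CCO", [1.0, 2.0], [True, False]),
                m.DatasetRecord("CCN", [0.0, 3.0], [False, True])]
        p = tmp_path / "out.csv"
        m.write_dataset(recs, p, ["a", "b"])
        back = m.read_dataset(p, ["a", "b"])
        assert len(back) == 2
        assert np.array_equal(back[0].mask, [True, False])
        assert back[1].targets[1] == pytest.approx(3.0)


class TestCleanDataset:
    def test_duplicates_collapse_keeping_max(self):
        recs = [m.DatasetRecord("CCO", [1.0], [True]),
                m.DatasetRecord("OCC", [2.0], [True])]
        out = m.clean_dataset(recs)
        assert len(out) == 1
        assert out[0].smiles == Chem.MolToSmiles(Chem.MolFromSmiles("CCO"))
        assert out[0].targets[0] == pytest.approx(2.0)

    def test_max_is_per_property(self):
        recs = [m.DatasetRecord("CCO", [1.0, 5.0], [True, True]),
                m.DatasetRecord("OCC", [2.0, 3.0], [True, True])]
        out = m.clean_dataset(recs)
        assert out[0].targets.tolist() == [2.0, 5.0]

    def test_masks_merge_across_duplicates(self):
        recs = [m.DatasetRecord("CCO", [1.0, 0.0], [True, False]),
                m.DatasetRecord("OCC", [0.0, 3.0], [False, True])]
        out = m.clean_dataset(recs)
        assert out[0].mask.tolist() == [True, True]
        assert out[0].targets.tolist() == [1.0, 3.0]

    def test_empty_input(self):
        assert m.clean_dataset([]) == []

    def test_unparseable_rows_dropped_not_fatal(self):
        recs = [m.DatasetRecord("CCO", [1.0], [True]),
                m.DatasetRecord("not_a_smiles", [3.0], [True])]
        out = m.clean_dataset(recs)
        assert [r.targets[0] for r in out] == [1.0]

    def test_idempotent(self, small_records):
        once = m.clean_dataset(small_records)
        twice = m.clean_dataset(once)
        assert [r.smiles for r in once] == [r.smiles for r in twice]
        assert all(np.array_equal(a.targets, b.targets) for a, b in zip(once, twice))


# ---------------------------------------------------------------------------
# featurization

# block boundaries of the atom feature vector
_TYPE = slice(0, 118)
_DEGREE = slice(118, 124)
_CHARGE = slice(124, 129)
_CHIRAL = slice(129, 133)
_HYBRID = slice(133, 138)
_AROMATIC = 138


class TestFeaturizeAtom:
    def test_ethane_carbon_blocks(self):
        atom = Chem.MolFromSmiles("CC").GetAtomWithIdx(0)
        v = m.featurize_atom(atom)
        assert len(v) == 139
        assert v[_TYPE].argmax() == 6 - 1 and v[_TYPE].sum() == 1  # carbon
        assert v[_DEGREE].tolist() == [0, 1, 0, 0, 0, 0]           # one heavy neighbour
        assert v[_CHARGE].tolist() == [0, 0, 1, 0, 0]              # neutral
        assert v[_HYBRID].tolist() == [0, 0, 1, 0, 0]              # sp3
        assert v[_AROMATIC] == 0

    def test_every_block_is_one_hot(self, fixture_smiles):
        for s in fixture_smiles:
            mol = Chem.MolFromSmiles(s)
            Chem.AssignStereochemistry(mol, cleanIt=True, force=True)
            for atom in mol.GetAtoms():
                v = m.featurize_atom(atom)
                assert len(v) == m.ATOM_FDIM == 139
                assert v[_TYPE].sum() == 1
                for block in (_DEGREE, _CHARGE, _CHIRAL, _HYBRID):
                    assert v[block].sum() <= 1
                assert v[_AROMATIC] in (0.0, 1.0)

    def test_benzene_carbon_is_aromatic(self):
        v = m.featurize_atom(Chem.MolFromSmiles("c1ccccc1").GetAtomWithIdx(0))
        assert v[_AROMATIC] == 1

    def test_chirality_cip_code(self):
        mol = Chem.MolFromSmiles("C[C@H](N)C(=O)O")  # L-alanine, S centre
        Chem.AssignStereochemistry(mol, cleanIt=True, force=True)
        v = m.featurize_atom(mol.GetAtomWithIdx(1))
        assert v[_CHIRAL].tolist() == [0, 1, 0, 0]

    def test_degree_above_buckets_clamps_with_warning(self):
        atom = Chem.MolFromSmiles("FS(F)(F)(F)(F)F").GetAtomWithIdx(1)  # SF6
        with pytest.warns(UserWarning, match="clamped"):
            v = m.featurize_atom(atom)
        assert v[_DEGREE].tolist() == [0, 0, 0, 0, 0, 1]


class TestFeaturizeBond:
    def test_acyclic_single_bond(self):
        bond = Chem.MolFromSmiles("CC").GetBondWithIdx(0)
        v = m.featurize_bond(bond)
        assert len(v) == m.BOND_FDIM == 11
        assert v[:4].tolist() == [1, 0, 0, 0]
        assert v[4] == 0                        # not in a ring
        assert v[5:].tolist() == [1, 0, 0, 0, 0, 0]  # stereo none

    def test_benzene_bond_aromatic_and_in_ring(self):
        v = m.featurize_bond(Chem.MolFromSmiles("c1ccccc1").GetBondWithIdx(0))
        assert v[:4].tolist() == [0, 0, 0, 1] and v[4] == 1

    def test_double_triple_orders(self):
        assert m.featurize_bond(Chem.MolFromSmiles("C=C").GetBondWithIdx(0))[:4].tolist() == [0, 1, 0, 0]
        assert m.featurize_bond(Chem.MolFromSmiles("C#C").GetBondWithIdx(0))[:4].tolist() == [0, 0, 1, 0]

    def test_stereo_double_bond(self):
        mol = Chem.MolFromSmiles("C/C=C/C")
        Chem.AssignStereochemistry(mol, cleanIt=True, force=True)
        v = m.featurize_bond(mol.GetBondWithIdx(1))
        assert v[5:].sum() == 1 and v[5] == 0   # some stereo bucket other than none


# ---------------------------------------------------------------------------
# graphs


class TestMolToGraph:
    def test_one_bond_two_directed_edges(self):
        g = m.mol_to_graph("CN")
        assert g.n_atoms == 2 and g.n_bonds == 1 and g.n_edges == 2
        assert {(int(s), int(t)) for s, t in zip(g.edge_source, g.edge_target)} == {(0, 1), (1, 0)}

    def test_single_heavy_atom(self):
        g = m.mol_to_graph("C")
        assert g.n_atoms == 1 and g.n_edges == 0

    def test_caffeine_counts(self):
        g = m.mol_to_graph(CAFFEINE)
        assert g.n_atoms == 14 and g.n_edges == 30

    def test_unparseable_smiles_raises(self):
        with pytest.raises(ValueError, match="not parseable"):
            m.mol_to_graph("x#!")

    def test_index_lists_mutually_consistent(self, fixture_graphs):
        for g in fixture_graphs + [m.mol_to_graph(CAFFEINE)]:
            assert g.n_edges == 2 * g.n_bonds
            rev = g.edge2revedge
            assert np.array_equal(rev[rev], np.arange(g.n_edges))      # involution
            assert not np.any(rev == np.arange(g.n_edges))             # no fixed points
            assert np.array_equal(g.edge_source[rev], g.edge_target)
            assert np.array_equal(g.edge_target[rev], g.edge_source)
            for y, edges in enumerate(g.node2edge):
                assert all(g.edge_target[e] == y for e in edges)
            for x, neigh in enumerate(g.node2neinode):
                expect = sorted(g.edge_target[e] for e in range(g.n_edges) if g.edge_source[e] == x)
                assert sorted(neigh) == expect

    def test_featurization_is_permutation_covariant(self, rng):
        mol = Chem.MolFromSmiles(CAFFEINE)
        perm = rng.permutation(mol.GetNumAtoms()).tolist()
        renumbered = Chem.RenumberAtoms(mol, perm)
        g1 = m.mol_to_graph(CAFFEINE)
        g2 = m.mol_to_graph(Chem.MolToSmiles(renumbered, canonical=False))
        # atom rows are the same multiset under any renumbering, and both
        # orderings describe the same bond structure
        assert sorted(map(tuple, g1.atom_features)) == sorted(map(tuple, g2.atom_features))
        assert g1.n_bonds == g2.n_bonds

    def test_json_dump_roundtrips(self):
        import json
        g = m.mol_to_graph("CCO")
        d = json.loads(g.to_json())
        assert d["n_atoms"] == 3 and len(d["edge_source"]) == 4


class TestBatchGraphs:
    def test_single_graph_identity(self, fixture_graphs):
        b = m.batch_graphs([fixture_graphs[0]])
        assert m.unbatch_graphs(b) == [fixture_graphs[0]]

    def test_atom_and_edge_conservation(self, fixture_graphs):
        b = m.batch_graphs(fixture_graphs)
        assert b.n_atoms == sum(g.n_atoms for g in fixture_graphs)
        assert b.n_edges == sum(g.n_edges for g in fixture_graphs)

    def test_roundtrip_exact(self, fixture_graphs):
        b = m.batch_graphs(fixture_graphs)
        back = m.unbatch_graphs(b)
        for g0, g1 in zip(fixture_graphs, back):
            assert np.array_equal(g0.atom_features, g1.atom_features)
            assert np.array_equal(g0.edge_source, g1.edge_source)

    def test_no_index_crosses_molecule_boundary(self, fixture_graphs):
        b = m.batch_graphs(fixture_graphs)
        for (a0, an), (e0, en) in zip(b.atom_scope, b.edge_scope):
            sel = slice(e0, e0 + en)
            assert np.all((b.edge_source[sel] >= a0) & (b.edge_source[sel] < a0 + an))
            assert np.all((b.edge2revedge[sel] >= e0) & (b.edge2revedge[sel] < e0 + en))

    def test_empty_list_is_an_error(self):
        with pytest.raises(ValueError):
            m.batch_graphs([])
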