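"""Graph featurization, interatomic matrices, descriptors, fingerprints."""

import numpy as np
import pytest
from rdkit import Chem

from pcfkit import featurize
from pcfkit.featurize import (
    ATOM_FEATURE_DIM,
    BOND_FEATURE_DIM,
    InvalidStructureError,
    compute_descriptors,
    compute_fingerprint,
    coulomb_matrix,
    descriptor_manifest,
    featurize_graph,
)

from conftest import random_smiles_pool


class TestGraph:
    def test_ethane(self):
        g = featurize_graph("CC")
        assert g.n_atoms == 2 and g.n_bonds == 2
        assert g.topo_dist[0, 1] == 1
        assert set(map(tuple, g.bond_index)) == {(0, 1), (1, 0)}

    def test_benzene_aromatic_ring_flags_and_distances(self):
        g = featurize_graph("c1ccccc1")
        # aromatic flag is the last atom one-hot block: [not, yes]
        assert np.all(g.atom_feats[:, -1] == 1)
        assert np.all(g.bond_feats[:, -1] == 1)  # in-ring flag
        assert g.topo_dist.max() == 3  # shortest paths on a 6-cycle
        assert g.n_bonds == 12

    def test_methane_degenerate(self):
        g = featurize_graph("C")
        assert g.n_atoms == 1 and g.n_bonds == 0
        assert g.adjacency.shape == (1, 1) and g.adjacency[0, 0] == 0

    def test_parse_failure(self):
        with pytest.raises(InvalidStructureError):
            featurize_graph("((((")

    def test_one_hot_blocks_sum_to_one_on_fuzz_pool(self):
        # element(12)+degree(7)+chirality(4)+hybridization(6)+numH(6)+aromatic(2)
        atom_blocks = [(0, 12), (12, 19), (19, 23), (23, 29), (29, 35), (35, 37)]
        bond_blocks = [(0, 4), (4, 10), (10, 12), (12, 14)]
        for smi in random_smiles_pool(200, seed=11):
            g = featurize_graph(smi)
            for lo, hi in atom_blocks:
                assert np.all(g.atom_feats[:, lo:hi].sum(axis=1) == 1.0), (smi, lo)
            for lo, hi in bond_blocks:
                assert np.all(g.bond_feats[:, lo:hi].sum(axis=1) == 1.0), (smi, lo)
        assert ATOM_FEATURE_DIM == 37 and BOND_FEATURE_DIM == 14

    def test_matrix_invariants(self):
        for smi in random_smiles_pool(30, seed=12):
            g = featurize_graph(smi)
            assert np.array_equal(g.adjacency, g.adjacency.T)
            assert np.all(np.diag(g.adjacency) == 0)
            assert np.array_equal(g.topo_dist, g.topo_dist.T)
            assert np.allclose(g.coulomb, g.coulomb.T)
            n = g.n_atoms
            d = g.topo_dist
            tri = d[:, :, None] + d[None, :, :] >= d[:, None, :] - 1e-9
            assert tri.all()

    def test_topological_distance_matches_bfs_oracle(self):
        import networkx as nx

        for smi in random_smiles_pool(50, seed=13):
            g = featurize_graph(smi)
            G = nx.from_numpy_array(g.adjacency)
            lengths = dict(nx.all_pairs_shortest_path_length(G))
            for i in range(g.n_atoms):
                for j in range(g.n_atoms):
                    assert g.topo_dist[i, j] == lengths[i][j]


def reorder_smiles(smiles: str, seed: int) -> str:
    """A SMILES for the same molecule written in a shuffled atom order."""
    mol = Chem.MolFromSmiles(smiles)
    perm = np.random.default_rng(seed).permutation(mol.GetNumAtoms())
    return Chem.MolToSmiles(Chem.RenumberAtoms(mol, [int(i) for i in perm]),
                            canonical=False)


def _atom_permutation(smiles_a: str, smiles_b: str) -> np.ndarray:
    """perm[i] = index in molecule B of the atom matching atom i of A
    (up to graph automorphism, which preserves every featurization)."""
    ma, mb = Chem.MolFromSmiles(smiles_a), Chem.MolFromSmiles(smiles_b)
    ra = list(Chem.CanonicalRankAtoms(ma, breakTies=True))
    rb = list(Chem.CanonicalRankAtoms(mb, breakTies=True))
    return np.array([rb.index(r) for r in ra])


class TestPermutationCovariance:
    @pytest.mark.parametrize("smiles", ["CCOC(C)=O", "c1ccc(CN)cc1", "OCC(O)CO"])
    def test_matrices_permute_with_atom_order(self, smiles):
        alt = reorder_smiles(smiles, seed=5)
        perm = _atom_permutation(smiles, alt)
        ga, gb = featurize_graph(smiles), featurize_graph(alt)
        assert np.array_equal(ga.atom_feats, gb.atom_feats[perm])
        assert np.array_equal(ga.adjacency, gb.adjacency[np.ix_(perm, perm)])
        assert np.array_equal(ga.topo_dist, gb.topo_dist[np.ix_(perm, perm)])
        assert np.allclose(ga.coulomb, gb.coulomb[np.ix_(perm, perm)])

    def test_fingerprints_and_descriptors_invariant(self):
        a, b = "CCOC(C)=O", "O=C(OCC)C"
        for kind in featurize.FINGERPRINT_KINDS:
            assert np.array_equal(compute_fingerprint(a, kind).bits,
                                  compute_fingerprint(b, kind).bits)
        assert np.allclose(compute_descriptors(a).values,
                           compute_descriptors(b).values)


class TestCoulomb:
    def test_single_carbon_closed_form(self):
        m = coulomb_matrix("[C]")
        assert m.shape == (1, 1)
        assert m[0, 0] == pytest.approx(0.5 * 6 ** 2.4)

    def test_carbon_monoxide_off_diagonal(self):
        m = coulomb_matrix("[C-]#[O+]")
        assert m[0, 1] == pytest.approx(6 * 8 / 1.5)

    def test_embedded_mode_is_seeded_and_symmetric(self):
        a = coulomb_matrix("CCO", mode="embedded3d", seed=4)
        b = coulomb_matrix("CCO", mode="embedded3d", seed=4)
        assert np.array_equal(a, b)
        assert np.allclose(a, a.T)

    def test_unknown_mode_raises(self):
        with pytest.raises(ValueError):
            coulomb_matrix("CCO", mode="geodesic")


class TestDescriptors:
    def test_vector_matches_manifest(self):
        names = descriptor_manifest()
        vec = compute_descriptors("CCO")
        assert len(vec.values) == len(names) == len(vec.names)
        assert np.all(np.isfinite(vec.values))

    def test_ethanol_exact_weight(self):
        vec = compute_descriptors("CCO")
        idx = vec.names.index("ExactMolWt")
        assert vec.values[idx] == pytest.approx(46.0419, abs=1e-3)

    def test_benzene_ring_count(self):
        vec = compute_descriptors("c1ccccc1")
        assert vec.values[vec.names.index("RingCount")] == 1


class TestFingerprints:
    def test_methane_ecfp_single_environment(self):
        fp = compute_fingerprint("C", "ECFP4")
        assert fp.bits.sum() <= 2

    def test_lengths(self):
        assert len(compute_fingerprint("CCO", "ECFP4")) == 2048
        assert len(compute_fingerprint("CCO", "PATH")) == 2048
        assert len(compute_fingerprint("CCO", "MACCS")) == 167

    def test_empty_input_raises(self):
        with pytest.raises(InvalidStructureError):
            compute_fingerprint("", "ECFP4")
        with pytest.raises(ValueError):
            compute_fingerprint("CCO", "FCFP")
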