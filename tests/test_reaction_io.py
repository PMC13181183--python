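import numpy as np
import pytest

from rxnedit.reaction_io import (ATOM_FEATURE_DIM, BOND_FEATURE_DIM,
                                 MapValidationError, ReactionParseError,
                                 build_dual_graph, canonicalize_and_remap,
                                 parse_reaction, permute_reaction,
                                 reaction_to_smiles)
from tests.conftest import ESTERIFICATION


class TestParseReaction:
    def test_multi_component_counts(self):
        rxn = parse_reaction("CC(=O)O.OCC>>CC(=O)OCC")
        assert rxn.reactants.n_atoms == 7
        assert len(set(rxn.reactants.component_ids)) == 2
        assert rxn.product.n_atoms == 6
        assert rxn.atom_map is None

    def test_single_atom_identity(self):
        rxn = parse_reaction("C>>C")
        assert rxn.reactants.n_atoms == rxn.product.n_atoms == 1
        assert rxn.reactants.n_bonds == rxn.product.n_bonds == 0

    def test_atom_map_from_map_numbers(self):
        rxn = parse_reaction(ESTERIFICATION)
        assert rxn.atom_map is not None
        for p_idx, r_idx in rxn.atom_map.items():
            assert (rxn.product.atoms[p_idx].map_number
                    == rxn.reactants.atoms[r_idx].map_number)
        assert len(rxn.atom_map) == rxn.product.n_atoms
        assert len(set(rxn.atom_map.values())) == len(rxn.atom_map)

    @pytest.mark.parametrize("bad, match", [
        ("notasmiles>>C", "reactant"),
        ("C>>notasmiles", "product"),
        ("C>C", "separator"),
        ("C>>C>>C", "separator"),
    ])
    def test_parse_errors_name_the_side(self, bad, match):
        with pytest.raises(ReactionParseError, match=match):
            parse_reaction(bad)

    def test_duplicate_map_numbers_rejected(self):
        with pytest.raises(MapValidationError, match="duplicate"):
            parse_reaction("[CH3:1][CH3:1]>>CC")

    def test_orphan_product_maps_rejected(self):
        with pytest.raises(MapValidationError, match=r"\[7\]"):
            parse_reaction("[CH3:1][OH:2]>>[CH3:1][OH:7]")

    def test_partial_product_maps_give_no_map(self):
        rxn = parse_reaction("[CH3:1]O>>[CH3:1]O")
        assert rxn.atom_map is None


class TestFeaturize:
    def test_one_hot_block_structure(self):
        g = parse_reaction(">>CC").product
        # 6 one-hot blocks each with exactly one hot bit + 2 binary flags
        assert g.atom_features.shape == (2, ATOM_FEATURE_DIM)
        for row in g.atom_features:
            assert row.sum() == 6  # sp3 carbon, no aromatic/ring flags

    def test_aromatic_ring_bond(self):
        g = parse_reaction(">>c1ccccc1").product
        # every benzene bond: aromatic type one-hot + ring flag
        assert g.bond_features.shape == (6, BOND_FEATURE_DIM)
        for row, bond in zip(g.bond_features, g.bonds):
            assert bond.bond_type == "AROMATIC"
            assert row[3] == 1.0        # aromatic slot of the bond-type block
            assert row[-1] == 1.0       # ring flag

    def test_out_of_vocabulary_element_goes_to_other(self):
        g = parse_reaction(">>[AsH3]").product
        row = g.atom_features[0]
        assert row[16] == 1.0           # "other" bucket of the element block
        assert row[:16].sum() == 0.0

    def test_adjacency_row_sums_match_degrees(self, generated_batch):
        for item in generated_batch[:20]:
            for g in (item.reaction.reactants, item.reaction.product):
                degrees = np.array([a.degree for a in g.atoms])
                assert (g.adjacency.sum(axis=1) == degrees).all()


class TestDualGraph:
    def test_ethanol(self):
        dual = build_dual_graph(parse_reaction(">>CCO").product)
        assert dual.n_nodes == 2
        assert dual.dual_edges == [(0, 1)]

    def test_single_atom_degenerate(self):
        dual = build_dual_graph(parse_reaction(">>C").product)
        assert dual.n_nodes == 0
        assert dual.dual_edges == []

    def test_benzene_six_cycle(self):
        dual = build_dual_graph(parse_reaction(">>c1ccccc1").product)
        assert dual.n_nodes == 6
        degree = np.zeros(6, dtype=int)
        for u, v in dual.dual_edges:
            degree[u] += 1
            degree[v] += 1
        assert (degree == 2).all() and len(dual.dual_edges) == 6

    def test_matches_brute_force_shared_atom_relation(self, generated_batch):
        for item in generated_batch:
            product = item.reaction.product
            dual = build_dual_graph(product)
            assert dual.n_nodes == product.n_bonds
            expected = set()
            for u in range(product.n_bonds):
                for v in range(product.n_bonds):
                    if u < v:
                        bu = {product.bonds[u].i, product.bonds[u].j}
                        bv = {product.bonds[v].i, product.bonds[v].j}
                        if len(bu & bv) == 1:
                            expected.add((u, v))
            assert set(dual.dual_edges) == expected


class TestCanonicalize:
    def test_idempotent(self, esterification):
        c1 = canonicalize_and_remap(esterification)
        c2 = canonicalize_and_remap(c1)
        assert c1.raw_smiles == c2.raw_smiles

    def test_invariant_to_product_atom_order(self, esterification):
        base = canonicalize_and_remap(esterification).raw_smiles
        rng = np.random.default_rng(5)
        for _ in range(5):
            perm = list(rng.permutation(esterification.product.n_atoms))
            permuted = permute_reaction(esterification, perm_p=perm)
            assert canonicalize_and_remap(permuted).raw_smiles == base

    def test_map_stays_injective_and_total(self, esterification):
        out = canonicalize_and_remap(esterification)
        assert len(out.atom_map) == out.product.n_atoms
        assert len(set(out.atom_map.values())) == len(out.atom_map)

    def test_requires_map(self):
        with pytest.raises(MapValidationError):
            canonicalize_and_remap(parse_reaction("CCO>>CCO"))


def test_serialize_round_trip(esterification):
    rxn = parse_reaction(reaction_to_smiles(esterification))
    assert np.array_equal(rxn.product.atom_features,
                          esterification.product.atom_features)
    assert np.array_equal(rxn.reactants.atom_features,
                          esterification.reactants.atom_features)
    assert rxn.atom_map == esterification.atom_map
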