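import numpy as np
import pytest

from rxnedit.autodiff import Tensor
from rxnedit.model import EncoderConfig, ReactionModel
from rxnedit.reaction_io import (build_dual_graph, parse_reaction,
                                 permute_molgraph, permute_reaction)


def test_encoder_config_validation():
    with pytest.raises(ValueError):
        EncoderConfig(hidden_dim=30, num_heads=4)
    with pytest.raises(ValueError):
        EncoderConfig(num_layers=0)


class TestEncoder:
    def test_single_atom_graph(self, tiny_model):
        g = parse_reaction(">>C").product
        h = tiny_model.encode(g)
        assert h.shape == (1, 16)

    def test_empty_graph_errors(self, tiny_model):
        g = parse_reaction(">>C").product
        g.atoms = []
        g.adjacency = np.zeros((0, 0))
        with pytest.raises(ValueError):
            tiny_model.encode(g)

    def test_permutation_equivariance(self, tiny_model, generated_batch):
        rng = np.random.default_rng(0)
        g = generated_batch[0].reaction.reactants
        h = tiny_model.encode(g).data
        for _ in range(5):
            perm = list(rng.permutation(g.n_atoms))
            hp = tiny_model.encode(permute_molgraph(g, perm)).data
            assert np.allclose(hp, h[perm], atol=1e-10)

    def test_isomorphic_graphs_same_embedding_multiset(self, tiny_model):
        a = parse_reaction(">>CCO").product
        b = parse_reaction(">>OCC").product
        ha = np.sort(tiny_model.encode(a).data, axis=0)
        hb = np.sort(tiny_model.encode(b).data, axis=0)
        assert np.allclose(ha, hb, atol=1e-10)


class TestCrossAttention:
    def test_output_is_value_projection_of_counterpart(self, tiny_model):
        rng = np.random.default_rng(1)
        h_p = Tensor(rng.normal(size=(3, 16)))
        h_r = Tensor(rng.normal(size=(5, 16)))
        assign = np.array([4, 0, 2])
        out = tiny_model.cross_attend(h_p, h_r, assign)
        expected = h_r.data[assign] @ tiny_model.params["att_v_W"].data
        assert np.allclose(out.data, expected)

    def test_swapping_assignments_swaps_rows(self, tiny_model):
        rng = np.random.default_rng(2)
        h_p = Tensor(rng.normal(size=(2, 16)))
        h_r = Tensor(rng.normal(size=(4, 16)))
        a = tiny_model.cross_attend(h_p, h_r, [1, 3]).data
        b = tiny_model.cross_attend(h_p, h_r, [3, 1]).data
        assert np.allclose(a[[1, 0]], b)

    def test_attention_export_rows_normalized(self, tiny_model):
        rng = np.random.default_rng(3)
        att = tiny_model.attention_matrix(rng.normal(size=(3, 16)),
                                          rng.normal(size=(5, 16)))
        assert att.shape == (3, 5)
        assert np.allclose(att.sum(axis=1), 1.0)


class TestEnrich:
    def test_concatenation_layout(self, tiny_model):
        h = Tensor(np.ones((3, 16)))
        z = Tensor(np.zeros((3, 16)))
        out = tiny_model.enrich(h, z)
        assert out.shape == (3, 32)
        assert np.array_equal(out.data[:, :16], h.data)
        assert np.array_equal(out.data[:, 16:], z.data)

    def test_row_mismatch_errors(self, tiny_model):
        with pytest.raises(ValueError):
            tiny_model.enrich(Tensor(np.ones((3, 16))), Tensor(np.ones((2, 16))))


class TestDualEncoder:
    def test_empty_dual(self, tiny_model):
        dual = build_dual_graph(parse_reaction(">>C").product)
        assert tiny_model.encode_dual(dual).shape == (0, 16)

    def test_ethanol_two_rows(self, tiny_model):
        dual = build_dual_graph(parse_reaction(">>CCO").product)
        assert tiny_model.encode_dual(dual).shape == (2, 16)


class TestHeads:
    def test_zero_weight_heads_give_half(self, tiny_model):
        for name in ("atom1", "atom2", "bond1", "bond2"):
            tiny_model.params[f"{name}_W"].data[:] = 0.0
        rxn = parse_reaction(">>CCO")
        fw = tiny_model.forward(rxn, mode="products_only")
        assert np.allclose(fw.edit_scores.atom_scores, 0.5)
        assert np.allclose(fw.edit_scores.bond_scores, 0.5)

    def test_scores_in_open_unit_interval(self, tiny_model, generated_batch):
        rxn = generated_batch[0].reaction
        fw = tiny_model.forward(rxn, mode="full")
        for s in (fw.edit_scores.atom_scores, fw.edit_scores.bond_scores):
            assert ((s > 0) & (s < 1)).all()

    def test_class_probabilities_normalized(self, tiny_model, generated_batch):
        fw = tiny_model.forward(generated_batch[0].reaction, mode="full")
        p = fw.class_scores.probabilities
        assert p.shape == (10,)
        assert (p >= 0).all()
        assert p.sum() == pytest.approx(1.0)

    def test_bond_scores_orientation_invariant(self, tiny_model, generated_batch):
        """Permuting atom order (which may flip stored bond orientation)
        leaves per-bond scores unchanged."""
        item = generated_batch[0]
        rxn = item.reaction
        fw = tiny_model.forward(rxn, mode="full",
                                teacher_map=rxn.atom_map)
        base = {(b.i, b.j): s for b, s in zip(rxn.product.bonds,
                                              fw.edit_scores.bond_scores)}
        rng = np.random.default_rng(4)
        perm = list(rng.permutation(rxn.product.n_atoms))
        permuted = permute_reaction(rxn, perm_p=perm)
        fw2 = tiny_model.forward(permuted, mode="full",
                                 teacher_map=permuted.atom_map)
        for b, s in zip(permuted.product.bonds, fw2.edit_scores.bond_scores):
            oi, oj = perm[b.i], perm[b.j]
            if oi > oj:
                oi, oj = oj, oi
            assert s == pytest.approx(base[(oi, oj)], abs=1e-9)


class TestForward:
    def test_full_mode_returns_all_outputs(self, tiny_model, generated_batch):
        fw = tiny_model.forward(generated_batch[0].reaction, mode="full")
        assert fw.correspondence is not None
        assert fw.assignment is not None
        assert fw.attention is not None
        assert fw.edit_scores.atom_scores.size > 0

    def test_products_only_without_reactants(self, tiny_model):
        fw = tiny_model.forward(parse_reaction(">>CCO"), mode="products_only")
        assert fw.correspondence is None
        assert fw.assignment is None
        assert fw.class_scores.probabilities.size == 10

    def test_full_without_reactants_errors(self, tiny_model):
        with pytest.raises(ValueError):
            tiny_model.forward(parse_reaction(">>CCO"), mode="full")

    def test_deterministic(self, tiny_model, generated_batch):
        rxn = generated_batch[1].reaction
        a = tiny_model.forward(rxn, mode="full")
        b = tiny_model.forward(rxn, mode="full")
        assert np.array_equal(a.edit_scores.atom_scores, b.edit_scores.atom_scores)
        assert np.array_equal(a.correspondence.soft, b.correspondence.soft)
        assert np.array_equal(a.assignment, b.assignment)

    def test_teacher_and_predicted_paths_share_parameters(self, tiny_model,
                                                          generated_batch):
        """Teacher forcing only changes which assignment is gathered; when the
        predicted assignment happens to equal the truth, both paths give
        identical outputs."""
        rxn = generated_batch[2].reaction
        fw_pred = tiny_model.forward(rxn, mode="full")
        truth = np.array([rxn.atom_map[i] for i in range(rxn.product.n_atoms)])
        fw_teach = tiny_model.forward(rxn, mode="full", teacher_map=rxn.atom_map)
        if np.array_equal(fw_pred.assignment, truth):
            assert np.allclose(fw_pred.edit_scores.atom_scores,
                               fw_teach.edit_scores.atom_scores)
        # parameters are literally the same objects either way
        assert tiny_model.params is tiny_model.params


def test_checkpoint_round_trip(tmp_path, tiny_model, generated_batch):
    rxn = generated_batch[0].reaction
    before = tiny_model.forward(rxn, mode="full")
    path = tmp_path / "model.npz"
    tiny_model.save(path)
    loaded = ReactionModel.load(path)
    after = loaded.forward(rxn, mode="full")
    assert np.allclose(before.edit_scores.atom_scores,
                       after.edit_scores.atom_scores)
    assert np.allclose(before.class_scores.probabilities,
                       after.class_scores.probabilities)
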