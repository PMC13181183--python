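import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rxnedit.matching import (consistency_score, hard_assign, similarity,
                              sinkhorn, symmetry_aware_accuracy,
                              symmetry_refine, wl_partition)


class TestSimilarity:
    def test_identity_rows(self):
        h = np.eye(4)
        assert np.array_equal(similarity(h, h), np.eye(4))

    def test_orthogonal_rows_zero_off_diagonal(self):
        h = np.array([[1.0, 0.0], [0.0, 2.0]])
        raw = similarity(h, h)
        assert raw[0, 1] == raw[1, 0] == 0.0

    def test_rectangular_matches_brute_force(self):
        rng = np.random.default_rng(0)
        hp, hr = rng.normal(size=(3, 5)), rng.normal(size=(4, 5))
        raw = similarity(hp, hr)
        for i in range(3):
            for j in range(4):
                assert raw[i, j] == pytest.approx(hp[i] @ hr[j])

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            similarity(np.zeros((2, 3)), np.zeros((2, 4)))


class TestSinkhorn:
    def test_constant_input_gives_uniform(self):
        m = sinkhorn(np.zeros((5, 5)), iterations=1)
        assert np.allclose(m, 1 / 5, atol=1e-12)

    def test_diagonal_dominant_near_identity(self):
        raw = np.eye(6) * 10.0
        m = sinkhorn(raw, iterations=20, temperature=1.0)
        off = m - np.diag(np.diag(m))
        assert off.max() < 0.01

    def test_doubly_stochastic_on_squares(self):
        rng = np.random.default_rng(1)
        raw = rng.normal(size=(8, 8))
        m = sinkhorn(raw, iterations=50, temperature=1.0)
        assert np.abs(m.sum(axis=1) - 1).max() < 1e-4
        assert np.abs(m.sum(axis=0) - 1).max() < 1e-4

    def test_rectangular_rows_are_distributions(self):
        rng = np.random.default_rng(2)
        m = sinkhorn(rng.normal(size=(4, 7)), iterations=10)
        assert np.allclose(m.sum(axis=1), 1.0)
        assert (m >= 0).all()

    @settings(deadline=None, max_examples=20)
    @given(st.integers(min_value=2, max_value=8),
           st.floats(min_value=-5, max_value=5))
    def test_shift_invariance(self, n, shift):
        rng = np.random.default_rng(n)
        raw = rng.normal(size=(n, n))
        a = sinkhorn(raw, iterations=10)
        b = sinkhorn(raw + shift, iterations=10)
        assert np.allclose(a, b, atol=1e-9)

    def test_row_permutation_equivariance(self):
        rng = np.random.default_rng(3)
        raw = rng.normal(size=(5, 6))
        perm = rng.permutation(5)
        assert np.allclose(sinkhorn(raw, 10)[perm], sinkhorn(raw[perm], 10))

    def test_input_validation(self):
        with pytest.raises(ValueError):
            sinkhorn(np.array([[np.inf, 0.0], [0.0, 1.0]]))
        with pytest.raises(ValueError):
            sinkhorn(np.zeros((2, 2)), iterations=0)
        with pytest.raises(ValueError):
            sinkhorn(np.zeros((2, 2)), temperature=0.0)


class TestHardAssign:
    def test_identity(self):
        assert np.array_equal(hard_assign(np.eye(3)), [0, 1, 2])

    def test_uniform_row_tie_breaks_low(self):
        assert hard_assign(np.full((1, 4), 0.25))[0] == 0

    def test_diagonal_dominant(self):
        m = sinkhorn(np.eye(5) * 8, iterations=20, temperature=1.0)
        assert np.array_equal(hard_assign(m), np.arange(5))


class TestWLPartition:
    def test_benzene_single_class(self, mol_graphs):
        part = wl_partition(mol_graphs["benzene"])
        assert part.n_classes == 1
        assert len(part.classes[0]) == 6

    def test_ethanol_all_singletons(self, mol_graphs):
        part = wl_partition(mol_graphs["ethanol"])
        assert part.n_classes == 3

    def test_para_xylene_classes(self, mol_graphs):
        part = wl_partition(mol_graphs["para_xylene"])
        sizes = sorted(len(c) for c in part.classes)
        assert sizes == [2, 2, 4]

    def test_classes_partition_atoms(self, mol_graphs):
        for g in mol_graphs.values():
            part = wl_partition(g)
            atoms = sorted(a for c in part.classes for a in c)
            assert atoms == list(range(g.n_atoms))
            # atoms in one class share the element
            for c in part.classes:
                assert len({g.atoms[i].element for i in c}) == 1


class TestSymmetryRefine:
    def test_injective_assignment_untouched(self, mol_graphs):
        g = mol_graphs["benzene"]
        part = wl_partition(g)
        assign = np.arange(6)
        refined, unresolved = symmetry_refine(assign, part, part)
        assert np.array_equal(refined, assign)
        assert unresolved == []

    def test_collision_moved_within_class(self, mol_graphs):
        g = mol_graphs["benzene"]
        part = wl_partition(g)
        assign = np.array([0, 0, 2, 3, 4, 5])   # atoms 0 and 1 collide on 0
        refined, unresolved = symmetry_refine(assign, part, part)
        assert unresolved == []
        assert sorted(refined) == list(range(6))  # injective again
        assert refined[0] == 0                    # lowest index keeps its slot
        assert refined[1] == 1                    # moved to the free class member

    def test_singleton_class_collision_flagged(self, mol_graphs):
        # symmetric product atoms colliding on a reactant atom whose WL class
        # is a singleton cannot be repaired: left as-is and flagged
        p_part = wl_partition(mol_graphs["benzene"])
        r_part = wl_partition(mol_graphs["ethanol"])   # all singletons
        assign = np.array([0, 0, 1, 1, 2, 2])
        refined, unresolved = symmetry_refine(assign, p_part, r_part)
        assert np.array_equal(refined, assign)
        assert unresolved == [1, 3, 5]


class TestConsistencyScore:
    def test_identity_permutation_counts_directed_edges(self, mol_graphs):
        a = mol_graphs["benzene"].adjacency.astype(float)
        score = consistency_score(np.eye(6), a, a)
        assert score == pytest.approx(2 * 6)

    def test_uniform_matrix_closed_form(self):
        rng = np.random.default_rng(4)
        n = 5
        a_p = (rng.random((n, n)) < 0.4).astype(float)
        a_p = np.triu(a_p, 1)
        a_p = a_p + a_p.T
        a_r = np.copy(a_p)
        m = np.full((n, n), 1 / n)
        expected = a_p.sum() * a_r.sum() / n ** 2
        assert consistency_score(m, a_p, a_r) == pytest.approx(expected)

    def test_path_graph_brute_force(self):
        # 5-node path, relabeled; the planted permutation attains the maximum
        n = 5
        a_r = np.zeros((n, n))
        for i in range(n - 1):
            a_r[i, i + 1] = a_r[i + 1, i] = 1
        rng = np.random.default_rng(6)
        perm = rng.permutation(n)
        a_p = a_r[np.ix_(perm, perm)]
        best = -1.0
        best_perms = []
        for cand in itertools.permutations(range(n)):
            m = np.zeros((n, n))
            m[np.arange(n), list(cand)] = 1.0
            s = consistency_score(m, a_p, a_r)
            if s > best + 1e-12:
                best, best_perms = s, [cand]
            elif abs(s - best) < 1e-12:
                best_perms.append(cand)
        assert tuple(perm) in best_perms

    def test_hard_permutation_equals_preserved_edge_pairs(self):
        rng = np.random.default_rng(7)
        n = 6
        a_p = (rng.random((n, n)) < 0.5).astype(float)
        a_p = np.triu(a_p, 1); a_p = a_p + a_p.T
        a_r = (rng.random((n, n)) < 0.5).astype(float)
        a_r = np.triu(a_r, 1); a_r = a_r + a_r.T
        perm = rng.permutation(n)
        m = np.zeros((n, n)); m[np.arange(n), perm] = 1.0
        oracle = sum(a_p[i, j] * a_r[perm[i], perm[j]]
                     for i in range(n) for j in range(n))
        assert consistency_score(m, a_p, a_r) == pytest.approx(oracle)


class TestSymmetryAwareAccuracy:
    def test_exact_match(self, mol_graphs):
        part = wl_partition(mol_graphs["ethanol"])
        assert symmetry_aware_accuracy([0, 1, 2], [0, 1, 2], part) == 1.0

    def test_benzene_rotation_counts_correct(self, mol_graphs):
        part = wl_partition(mol_graphs["benzene"])
        truth = np.arange(6)
        rotated = np.roll(truth, 1)
        assert symmetry_aware_accuracy(rotated, truth, part) == 1.0

    def test_partial_mismatch(self):
        from rxnedit.reaction_io import parse_reaction
        g = parse_reaction(">>CCCCCCCCCC").product   # 10 distinct-ish atoms
        part = wl_partition(g)
        truth = np.arange(10)
        pred = truth.copy()
        pred[0] = 5   # move one atom outside its class (chain end vs middle)
        assert symmetry_aware_accuracy(pred, truth, part) == pytest.approx(0.9)
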