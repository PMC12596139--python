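import itertools

import numpy as np
import pytest

from treecohort.distances import (
    distance_matrix,
    exact_ordered_matching,
    greedy_ordered_matching,
    knn,
    mds_embed,
    tree_distance,
)
from treecohort.errors import CapabilityError
from treecohort.simulate import SimulationConfig, perturb_tree, simulate_cohort
from treecohort.treecore import DistanceMatrix, TreeCohort
from treecohort.treeops import assign_matching_labels

from .conftest import build_tree, labeled_chain, make_labeled_cohort
from .oracles import brute_force_max_matching, procrustes_error


def random_small_pair(seed: int):
    """A pair of related small trees (≤8 non-root nodes) from the simulator."""
    cfg = SimulationConfig(
        n_clusters=1, trees_per_cluster=2, nodes_min=3, nodes_max=6,
        planted_chain_length=2, perturbations_per_tree=2, seed=seed,
        gene_pool=[f"G{i:03d}" for i in range(1, 13)],  # small pool: label reuse
    )
    cohort, _ = simulate_cohort(cfg)
    a, b = (cohort.trees[s] for s in cohort.sample_ids()[:2])
    return a, b


def assert_valid_matching(A, B, m):
    a_side = [a for a, _ in m.pairs]
    b_side = [b for _, b in m.pairs]
    assert len(set(a_side)) == len(a_side) and len(set(b_side)) == len(b_side)
    for a, b in m.pairs:
        assert A.nodes[a].matching_label == B.nodes[b].matching_label
        assert a != A.root_id and b != B.root_id
    for (a, b), (a2, b2) in itertools.combinations(m.pairs, 2):
        assert A.is_proper_ancestor(a, a2) == B.is_proper_ancestor(b, b2)
        assert A.is_proper_ancestor(a2, a) == B.is_proper_ancestor(b2, b)


class TestMatching:
    def test_identical_unique_label_trees_match_fully(self):
        a = labeled_chain("a", ["x", "y", "z"])
        b = labeled_chain("b", ["x", "y", "z"])
        for m in (greedy_ordered_matching(a, b), exact_ordered_matching(a, b)):
            assert m.cardinality == 3
            assert_valid_matching(a, b, m)

    def test_single_shared_label(self):
        a = labeled_chain("a", ["x", "q"])
        b = labeled_chain("b", ["p", "x"])
        assert greedy_ordered_matching(a, b).cardinality == 1

    def test_swapped_chain_matches_one(self):
        a = labeled_chain("a", ["x", "y"])
        b = labeled_chain("b", ["y", "x"])
        # exhaustive: no order-isomorphic matching of size 2 exists
        assert brute_force_max_matching(a, b) == 1
        assert exact_ordered_matching(a, b).cardinality == 1
        assert greedy_ordered_matching(a, b).cardinality == 1

    def test_disjoint_labels_empty(self):
        a = labeled_chain("a", ["x"])
        b = labeled_chain("b", ["y"])
        assert exact_ordered_matching(a, b).cardinality == 0
        assert greedy_ordered_matching(a, b).pairs == ()

    def test_exact_refuses_large_trees(self):
        a = labeled_chain("a", [f"l{i}" for i in range(12)])
        with pytest.raises(CapabilityError):
            exact_ordered_matching(a, a)

    @pytest.mark.parametrize("seed", range(40))
    def test_greedy_bounded_by_exact_and_exact_matches_oracle(self, seed):
        A, B = random_small_pair(seed)
        g = greedy_ordered_matching(A, B)
        e = exact_ordered_matching(A, B)
        assert_valid_matching(A, B, g)
        assert_valid_matching(A, B, e)
        assert g.cardinality <= e.cardinality
        assert e.cardinality == brute_force_max_matching(A, B)

    def test_exact_monotone_under_node_deletion(self):
        # removing a matched node from B cannot decrease the distance
        A, B = random_small_pair(7)
        e = exact_ordered_matching(A, B)
        if not e.pairs:
            pytest.skip("no matched pair to delete")
        _, b_matched = e.pairs[0]
        # drop the matched node by pruning its subtree
        keep = [
            n for n in B.copy_nodes()
            if n.node_id != b_matched and b_matched not in B.ancestors(n.node_id)
        ]
        B2 = B.with_nodes(keep)
        assert tree_distance(A, B2, "exact") >= tree_distance(A, B, "exact")


class TestTreeDistance:
    def test_identical_trees_zero(self):
        a = labeled_chain("a", ["x", "y"])
        b = labeled_chain("b", ["x", "y"])
        assert tree_distance(a, b) == 0.0

    def test_disjoint_trees_one(self):
        assert tree_distance(labeled_chain("a", ["x"]),
                             labeled_chain("b", ["y"])) == 1.0

    def test_swapped_chain_half(self):
        a = labeled_chain("a", ["x", "y"])
        b = labeled_chain("b", ["y", "x"])
        assert tree_distance(a, b, "exact") == pytest.approx(0.5)
        assert tree_distance(a, b, "greedy") == pytest.approx(0.5)

    @pytest.mark.parametrize("seed", range(10))
    def test_symmetric_and_bounded(self, seed):
        A, B = random_small_pair(seed + 100)
        d1, d2 = tree_distance(A, B), tree_distance(B, A)
        assert d1 == pytest.approx(d2)
        assert 0.0 <= d1 <= 1.0


class TestDistanceMatrix:
    def test_single_tree(self):
        c = make_labeled_cohort([labeled_chain("s", ["x"])])
        dm = distance_matrix(c)
        assert dm.sample_ids == ["s"] and dm.values.shape == (1, 1)
        assert dm.values[0, 0] == 0.0

    def test_copies_all_zero(self):
        c = make_labeled_cohort(
            [labeled_chain(f"s{i}", ["x", "y", "z"]) for i in range(3)]
        )
        assert np.all(distance_matrix(c).values == 0.0)

    def test_matches_pairwise_calls(self, labeled_cohort):
        dm = distance_matrix(labeled_cohort)
        ids = dm.sample_ids
        for i, j in [(0, 1), (2, 5), (3, 7)]:
            expect = tree_distance(
                labeled_cohort.trees[ids[i]], labeled_cohort.trees[ids[j]]
            )
            assert dm.values[i, j] == pytest.approx(expect)
        assert np.allclose(dm.values, dm.values.T)
        assert np.all(np.diag(dm.values) == 0.0)


class TestKnn:
    def test_copy_is_nearest(self):
        c = make_labeled_cohort([
            labeled_chain("t", ["x", "y"]),
            labeled_chain("copy", ["x", "y"]),
            labeled_chain("far", ["p", "q"]),
        ])
        assert knn(c, "t", 1) == [("copy", 0.0)]

    def test_k_larger_than_cohort(self):
        c = make_labeled_cohort([
            labeled_chain("a", ["x"]), labeled_chain("b", ["x"]),
        ])
        assert knn(c, "a", 10) == [("b", 0.0)]

    def test_user_matrix_takes_precedence(self):
        trees = {t.sample_id: t for t in
                 [labeled_chain("a", ["x"]), labeled_chain("b", ["x"])]}
        dm = DistanceMatrix(["a", "b"], np.array([[0.0, 0.9], [0.9, 0.0]]))
        c = assign_matching_labels(TreeCohort(trees, distances=dm))
        assert knn(c, "a", 1) == [("b", 0.9)]

    def test_unknown_target(self, labeled_cohort):
        with pytest.raises(KeyError):
            knn(labeled_cohort, "ghost", 1)


class TestMds:
    def test_equilateral_triangle(self):
        dm = DistanceMatrix(["a", "b", "c"], np.ones((3, 3)) - np.eye(3))
        coords = mds_embed(dm)
        for s1, s2 in itertools.combinations("abc", 2):
            d = np.hypot(coords[s1][0] - coords[s2][0],
                         coords[s1][1] - coords[s2][1])
            assert d == pytest.approx(1.0, abs=1e-6)

    def test_two_samples_distance_preserved(self):
        dm = DistanceMatrix(["a", "b"], np.array([[0.0, 0.7], [0.7, 0.0]]))
        coords = mds_embed(dm)
        d = np.hypot(coords["a"][0] - coords["b"][0],
                     coords["a"][1] - coords["b"][1])
        assert d == pytest.approx(0.7, abs=1e-9)

    def test_planar_points_recovered(self):
        rng = np.random.default_rng(11)
        pts = rng.uniform(-5, 5, size=(10, 2))
        D = np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=-1)
        ids = [f"s{i}" for i in range(10)]
        coords = mds_embed(DistanceMatrix(ids, D))
        Y = np.array([coords[s] for s in ids])
        assert procrustes_error(pts, Y) < 1e-6

    def test_sign_convention_deterministic(self):
        rng = np.random.default_rng(2)
        pts = rng.uniform(0, 1, size=(6, 2))
        D = np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=-1)
        dm = DistanceMatrix([f"s{i}" for i in range(6)], D)
        assert mds_embed(dm) == mds_embed(dm)
        for axis in (0, 1):
            col = np.array([mds_embed(dm)[f"s{i}"][axis] for i in range(6)])
            assert col[np.argmax(np.abs(col))] >= 0

    def test_single_sample_rejected(self):
        with pytest.raises(CapabilityError):
            mds_embed(DistanceMatrix(["a"], np.zeros((1, 1))))
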