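import itertools
import random

import dendropy
import numpy as np
import pytest

from sugarminer.alignment import Alignment
from sugarminer.phylo import (
    DistanceMatrix,
    PhyloError,
    bipartitions,
    bootstrap_support,
    leaf_labels,
    neighbor_joining,
    neighborhood_lengths,
    p_distance_matrix,
    patristic_distances,
    pendant_lengths,
    root_tree,
)

from oracles import random_additive_tree


def _tree(newick: str) -> dendropy.Tree:
    return dendropy.Tree.get(data=newick, schema="newick",
                             preserve_underscores=True,
                             suppress_internal_node_taxa=True)


class TestDistanceMatrix:
    def test_asymmetric_rejected(self):
        with pytest.raises(PhyloError):
            DistanceMatrix(["a", "b"], np.array([[0.0, 1.0], [2.0, 0.0]]))

    def test_shape_checked(self):
        with pytest.raises(PhyloError):
            DistanceMatrix(["a", "b", "c"], np.zeros((2, 2)))


class TestPDistance:
    def test_pairwise_deletion_quarter(self):
        aln = Alignment(["a", "b"], ["ACDE", "ACDQ"])
        D = p_distance_matrix(aln, "pairwise_deletion")
        assert D.get("a", "b") == pytest.approx(0.25)

    def test_pairwise_deletion_skips_gap_site(self):
        aln = Alignment(["a", "b"], ["AC-E", "ACDE"])
        D = p_distance_matrix(aln, "pairwise_deletion")
        assert D.get("a", "b") == pytest.approx(0.0)

    def test_gaps_as_difference_counts_gap_site(self):
        aln = Alignment(["a", "b"], ["AC-E", "ACDE"])
        D = p_distance_matrix(aln, "gaps_as_difference")
        assert D.get("a", "b") == pytest.approx(0.25)

    def test_shared_gap_excluded_in_both_modes(self):
        aln = Alignment(["a", "b"], ["A-CE", "A-CQ"])
        for mode in ("gaps_as_difference", "pairwise_deletion"):
            D = p_distance_matrix(aln, mode)
            assert D.get("a", "b") == pytest.approx(1 / 3)

    def test_zero_comparable_sites_names_pair(self):
        aln = Alignment(["x", "y", "z"], ["A--", "-C-", "ACD"])
        with pytest.raises(PhyloError, match="'x' and 'y'"):
            p_distance_matrix(aln, "pairwise_deletion")

    def test_unknown_mode_rejected(self):
        aln = Alignment(["a", "b"], ["AC", "AC"])
        with pytest.raises(PhyloError):
            p_distance_matrix(aln, "bogus")


class TestNeighborJoining:
    def test_two_taxa_symmetric_split(self):
        D = DistanceMatrix(["a", "b"], np.array([[0.0, 0.4], [0.4, 0.0]]))
        tree = neighbor_joining(D)
        assert pendant_lengths(tree) == pytest.approx({"a": 0.2, "b": 0.2})

    def test_exact_on_random_additive_matrices(self):
        rng = random.Random(11)
        for _ in range(30):
            n = rng.randrange(4, 13)
            labels, D, true_bips = random_additive_tree(rng, n)
            tree = neighbor_joining(DistanceMatrix(labels, D))
            assert bipartitions(tree) == true_bips
            got = patristic_distances(tree)
            order = [got.ids.index(l) for l in labels]
            err = np.abs(got.values[np.ix_(order, order)] - D).max()
            assert err < 1e-9

    def test_four_leaf_least_squares_topology(self):
        # on a near-additive matrix, NJ's topology must coincide with the
        # least-squares best of the three possible quartet topologies
        rng = random.Random(5)
        labels = ["a", "b", "c", "d"]
        pair_idx = list(itertools.combinations(range(4), 2))

        def lstsq_ssq(D, split):
            # edges: 4 pendants + 1 internal; design over the 6 pairs
            rows = []
            for i, j in pair_idx:
                row = [0.0] * 5
                row[i] = row[j] = 1.0
                same = ({i, j} == set(split[0]) or {i, j} == set(split[1]))
                if not same:
                    row[4] = 1.0
                rows.append(row)
            A = np.array(rows)
            y = np.array([D[i, j] for i, j in pair_idx])
            x, *_ = np.linalg.lstsq(A, y, rcond=None)
            return float(((A @ x - y) ** 2).sum())

        splits = [((0, 1), (2, 3)), ((0, 2), (1, 3)), ((0, 3), (1, 2))]
        for _ in range(40):
            _, D, _ = random_additive_tree(rng, 4)
            D = D + rng.uniform(0, 1e-3)  # uniform offset keeps symmetry
            np.fill_diagonal(D, 0.0)
            tree = neighbor_joining(DistanceMatrix(labels, D))
            (bip,) = bipartitions(tree)
            nj_split = next(
                s for s in splits
                if {labels[i] for i in s[0]} in (set(bip),
                                                 set(labels) - set(bip)))
            ssqs = [lstsq_ssq(D, s) for s in splits]
            assert ssqs[splits.index(nj_split)] == pytest.approx(min(ssqs))

    def test_matches_scikit_bio(self):
        from skbio import DistanceMatrix as SkDM
        from skbio.tree import nj as sk_nj
        rng = random.Random(23)
        for _ in range(10):
            n = rng.randrange(4, 10)
            labels, D, _ = random_additive_tree(rng, n)
            ours = neighbor_joining(DistanceMatrix(labels, D))
            sk_tree = sk_nj(SkDM(D, labels))
            sk = dendropy.Tree.get(data=str(sk_tree), schema="newick",
                                   preserve_underscores=True,
                                   suppress_internal_node_taxa=True)
            assert bipartitions(ours) == bipartitions(sk)

    def test_leaf_order_invariance(self):
        rng = random.Random(3)
        labels, D, _ = random_additive_tree(rng, 8)
        base = bipartitions(neighbor_joining(DistanceMatrix(labels, D)))
        perm = list(range(8))
        rng.shuffle(perm)
        labs2 = [labels[i] for i in perm]
        D2 = D[np.ix_(perm, perm)]
        assert bipartitions(neighbor_joining(DistanceMatrix(labs2, D2))) == base

    def test_negative_lengths_clamped(self):
        # a strongly non-additive matrix forces negative estimates
        D = np.array([[0.0, 0.1, 0.9, 0.9],
                      [0.1, 0.0, 0.9, 0.1],
                      [0.9, 0.9, 0.0, 0.9],
                      [0.9, 0.1, 0.9, 0.0]])
        tree = neighbor_joining(DistanceMatrix(list("abcd"), D))
        for nd in tree.preorder_node_iter():
            if nd.edge.length is not None:
                assert nd.edge.length >= 0.0

    def test_single_taxon_rejected(self):
        with pytest.raises(PhyloError):
            neighbor_joining(DistanceMatrix(["a"], np.zeros((1, 1))))


def _signal_alignment() -> Alignment:
    # 4 taxa, clean synapomorphies: (a,b) share W-columns, (c,d) share Y
    block = 100
    a = "A" * block + "W" * block
    b = "C" * block + "W" * block
    c = "D" * block + "Y" * block
    d = "E" * block + "Y" * block
    return Alignment(["a", "b", "c", "d"], [a, b, c, d])


class TestBootstrap:
    def test_identical_signal_all_supports_100(self):
        tree = bootstrap_support(_signal_alignment(), n_reps=100, seed=1)
        sups = [float(nd.label) for nd in tree.preorder_internal_node_iter()
                if nd.label is not None]
        assert sups and all(s == 100.0 for s in sups)

    def test_seed_reproducible(self):
        rows = ["AWCD", "AWCE", "TYQD", "TYQE"]
        aln = Alignment(list("abcd"), rows)
        t1 = bootstrap_support(aln, n_reps=50, seed=9)
        t2 = bootstrap_support(aln, n_reps=50, seed=9)
        lab1 = sorted(nd.label for nd in t1.preorder_internal_node_iter()
                      if nd.label)
        lab2 = sorted(nd.label for nd in t2.preorder_internal_node_iter()
                      if nd.label)
        assert lab1 == lab2

    def test_focal_split_high_support(self):
        tree = bootstrap_support(_signal_alignment(), n_reps=100, seed=0)
        focal = frozenset({"a", "b"})
        for nd in tree.preorder_internal_node_iter():
            below = frozenset(lf.taxon.label for lf in nd.leaf_iter())
            if below == focal:
                assert float(nd.label) >= 95.0
                return
        pytest.fail("focal split (a,b) absent from the base tree")

    def test_input_order_invariance(self):
        aln = _signal_alignment()
        perm = Alignment([aln.ids[i] for i in (2, 0, 3, 1)],
                         [aln.rows[i] for i in (2, 0, 3, 1)])
        t1 = bootstrap_support(aln, n_reps=60, seed=4)
        t2 = bootstrap_support(perm, n_reps=60, seed=4)

        def support_map(t):
            out = {}
            for nd in t.preorder_internal_node_iter():
                if nd.label is None:
                    continue
                below = frozenset(lf.taxon.label for lf in nd.leaf_iter())
                out[below] = float(nd.label)
            return out

        assert support_map(t1) == support_map(t2)

    def test_bad_args_rejected(self):
        aln = _signal_alignment()
        with pytest.raises(PhyloError):
            bootstrap_support(aln, n_reps=0)
        small = Alignment(["a", "b"], ["AC", "AC"])
        with pytest.raises(PhyloError):
            bootstrap_support(small, n_reps=10)


class TestRootTree:
    def test_three_leaf_roots_on_outgroup_edge(self):
        tree = _tree("(A:0.1,B:0.2,O:0.6);")
        rooted = root_tree(tree, ["O"])
        kids = rooted.seed_node.child_nodes()
        sides = {frozenset(lf.taxon.label for lf in k.leaf_iter()) for k in kids}
        assert frozenset({"O"}) in sides
        og = next(k for k in kids if k.is_leaf() and k.taxon.label == "O")
        assert og.edge.length == pytest.approx(0.3)

    def test_missing_outgroup_is_error(self):
        with pytest.raises(PhyloError, match="absent"):
            root_tree(_tree("(A:1,B:1,C:1);"), ["Z"])

    def test_polyphyletic_outgroup_falls_back_to_midpoint(self):
        tree = _tree("((A:1,O1:1):1,(B:1,O2:1):1,C:1);")
        with pytest.warns(UserWarning, match="polyphyletic"):
            rooted = root_tree(tree, ["O1", "O2"])
        assert rooted.is_rooted

    def test_input_not_mutated(self):
        tree = _tree("(A:0.1,B:0.2,O:0.6);")
        before = tree.as_string(schema="newick")
        root_tree(tree, ["O"])
        assert tree.as_string(schema="newick") == before


class TestNeighborhood:
    def test_cherry_radius_one(self):
        tree = _tree("((A:0.1,B:0.3):0.2,C:0.4,D:0.5);")
        assert neighborhood_lengths(tree, "A", k=1) == [0.3]

    def test_unknown_leaf_rejected(self):
        with pytest.raises(PhyloError):
            neighborhood_lengths(_tree("(A:1,B:1,C:1);"), "Z")

    def test_matches_bruteforce_bfs(self):
        rng = random.Random(17)
        for _ in range(10):
            labels, D, _ = random_additive_tree(rng, 10)
            tree = neighbor_joining(DistanceMatrix(labels, D))
            # oracle: count internal nodes strictly between leaf pairs
            leaves = {lf.taxon.label: lf for lf in tree.leaf_node_iter()}

            def ancestors(node):
                out = []
                while node is not None:
                    out.append(node)
                    node = node.parent_node
                return out

            for query in labels:
                for k in (1, 2, 3):
                    want = []
                    qa = ancestors(leaves[query])
                    for other in labels:
                        if other == query:
                            continue
                        oa = ancestors(leaves[other])
                        common = next(n for n in qa if n in oa)
                        internal = (qa.index(common) - 1) + \
                            (oa.index(common) - 1) + 1
                        if internal <= k:
                            want.append(leaves[other].edge.length or 0.0)
                    got = neighborhood_lengths(tree, query, k)
                    assert sorted(got) == pytest.approx(sorted(want))


class TestPatristic:
    def test_hand_case(self):
        tree = _tree("((A:0.1,B:0.2):0.3,C:0.4);")
        D = patristic_distances(tree)
        assert D.get("A", "B") == pytest.approx(0.3)
        assert D.get("A", "C") == pytest.approx(0.8)
        assert D.get("B", "C") == pytest.approx(0.9)

    def test_pendant_lengths(self):
        tree = _tree("((A:0.1,B:0.2):0.3,C:0.4);")
        assert pendant_lengths(tree) == pytest.approx(
            {"A": 0.1, "B": 0.2, "C": 0.4})

    def test_leaf_labels(self):
        tree = _tree("((A:1,B:1):1,C:1);")
        assert sorted(leaf_labels(tree)) == ["A", "B", "C"]
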