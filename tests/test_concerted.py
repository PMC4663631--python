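import itertools
import random

import numpy as np
import pytest

from mitokaryo.concerted import (AlignedSeqSet, DistanceMatrix, TreeNode,
                                 bipartitions, bootstrap_support,
                                 classify_paralog_pattern, neighbor_joining,
                                 p_distance, paralog_difference, split_label)
from mitokaryo.simulate import simulate_paralog_pair


class TestPDistance:
    def test_identical_is_zero(self):
        assert p_distance("ACGT", "ACGT") == 0.0

    def test_one_in_four(self):
        assert p_distance("ACGT", "ACGA") == 0.25

    def test_pairwise_deletion(self):
        assert p_distance("AC-T", "ACGT") == 0.0  # 3 comparable sites
        assert p_distance("ACNT", "ACGA") == pytest.approx(1 / 3)

    def test_no_comparable_sites_errors(self):
        with pytest.raises(ValueError):
            p_distance("--", "AC")

    def test_unequal_length_errors(self):
        with pytest.raises(ValueError):
            p_distance("ACG", "AC")

    def test_symmetry_property(self):
        rng = random.Random(5)
        for _ in range(20):
            a = "".join(rng.choice("ACGT-N") for _ in range(40))
            b = "".join(rng.choice("ACGT-N") for _ in range(40))
            try:
                assert p_distance(a, b) == p_distance(b, a)
            except ValueError:
                pass


class TestDistanceMatrix:
    def test_asymmetric_rejected(self):
        with pytest.raises(ValueError):
            DistanceMatrix(("a", "b"), np.array([[0.0, 1.0], [0.5, 0.0]]))

    def test_from_alignment(self):
        seqs = AlignedSeqSet({"a|L1": "ACGT", "b|L1": "ACGA"})
        dm = DistanceMatrix.from_alignment(seqs)
        assert dm.values[0, 1] == 0.25


def leaf_distances(node, acc=0.0):
    """Path lengths from this node to every leaf below it."""
    if not node.children:
        return {node.label: acc}
    out = {}
    for child, bl in node.children:
        out.update(leaf_distances(child, acc + bl))
    return out


def tree_distance_matrix(tree):
    """All pairwise leaf path lengths of an unrooted TreeNode (oracle)."""
    labels = sorted(tree.leaves())
    # distances via shared-path subtraction from the top trifurcation
    dists = {}

    def collect(node, path):
        if not node.children:
            dists[node.label] = path
            return
        for child, bl in node.children:
            collect(child, path + [(id(node), bl)])

    # encode path as list of (node_id, edge_len) to compute pairwise distance
    paths = {}

    def walk(node, acc):
        if not node.children:
            paths[node.label] = acc
            return
        for child, bl in node.children:
            walk(child, acc + [(id(child), bl)])

    walk(tree, [])
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            pa, pb = paths[labels[i]], paths[labels[j]]
            sa, sb = dict(pa), dict(pb)
            shared = sum(l for nid, l in pa if nid in sb) \
                + sum(l for nid, l in pb if nid in sa)
            total = sum(l for _, l in pa) + sum(l for _, l in pb)
            d[i, j] = d[j, i] = total - shared
    return DistanceMatrix(tuple(labels), d)


def random_additive_tree(rng, n_taxa):
    """Random unrooted binary tree with positive branch lengths."""
    nodes = [TreeNode(label=f"t{i + 1:02d}") for i in range(n_taxa)]
    while len(nodes) > 3:
        i, j = sorted(rng.sample(range(len(nodes)), 2), reverse=True)
        a, b = nodes.pop(i), nodes.pop(j)
        nodes.append(TreeNode(children=[(a, rng.uniform(0.1, 1.0)),
                                        (b, rng.uniform(0.1, 1.0))]))
    return TreeNode(children=[(n, rng.uniform(0.1, 1.0)) for n in nodes])


class TestNeighborJoining:
    def test_four_taxa_exact_recovery(self):
        # ((A:1,B:2):1,(C:3,D:4)) => additive distances
        labels = ("A", "B", "C", "D")
        d = np.array([[0, 3, 5, 6],
                      [3, 0, 6, 7],
                      [5, 6, 0, 7],
                      [6, 7, 7, 0]], dtype=float)
        tree = neighbor_joining(DistanceMatrix(labels, d))
        assert bipartitions(tree) == {frozenset({"C", "D"})}
        # branch lengths recovered exactly
        dm = tree_distance_matrix(tree)
        np.testing.assert_allclose(dm.values, d)

    def test_three_taxa_closed_form(self):
        labels = ("a", "b", "c")
        d = np.array([[0, 2, 3], [2, 0, 5], [3, 5, 0]], dtype=float)
        tree = neighbor_joining(DistanceMatrix(labels, d))
        lengths = dict((child.label, bl) for child, bl in tree.children)
        assert lengths == {"a": 0.0, "b": 2.0, "c": 3.0}

    def test_fewer_than_three_taxa_errors(self):
        with pytest.raises(ValueError):
            neighbor_joining(DistanceMatrix(("a", "b"),
                                            np.array([[0., 1.], [1., 0.]])))

    def test_additive_recovery_random_trees(self):
        """NJ is consistent: exact topology back from additive distances."""
        rng = random.Random(17)
        for _ in range(100):
            n = rng.randint(4, 10)
            true = random_additive_tree(rng, n)
            dm = tree_distance_matrix(true)
            est = neighbor_joining(dm)
            assert bipartitions(est) == bipartitions(true)

    def test_agrees_with_skbio_on_additive_matrix(self):
        """Independent implementation cross-check."""
        skbio = pytest.importorskip("skbio")
        rng = random.Random(23)
        true = random_additive_tree(rng, 7)
        dm = tree_distance_matrix(true)
        sk_dm = skbio.DistanceMatrix(dm.values, ids=list(dm.labels))
        sk_tree = skbio.tree.nj(sk_dm)
        sk_splits = set()
        all_leaves = frozenset(dm.labels)
        ref = min(all_leaves)
        for node in sk_tree.non_tips(include_self=False):
            below = frozenset(t.name for t in node.tips())
            if 2 <= len(below) <= len(all_leaves) - 2:
                sk_splits.add(below if ref not in below
                              else all_leaves - below)
        assert bipartitions(neighbor_joining(dm)) == sk_splits


class TestBootstrap:
    def test_identical_clades_full_support(self):
        seqs = AlignedSeqSet({
            "a|L1": "ACGTACGTACGTACGTACGT", "b|L1": "ACGTACGTACGTACGTACGT",
            "a|L2": "TGCATGCATGCATGCATGCA", "b|L2": "TGCATGCATGCATGCATGCA"})
        sup = bootstrap_support(seqs, n_reps=50, seed=1)
        split = frozenset({"b|L2", "a|L2"})  # side excluding min leaf a|L1
        assert sup[split] == 1.0

    def test_fixed_seed_reproducible(self):
        seqs, _ = simulate_paralog_pair(4, "independent", seed=2)
        assert bootstrap_support(seqs, 30, seed=9) == \
            bootstrap_support(seqs, 30, seed=9)

    def test_long_internal_branch_high_support(self):
        """The deep paralog split dominates resampling at 200 replicates."""
        seqs, _ = simulate_paralog_pair(4, "independent", seed=3)
        sup = bootstrap_support(seqs, n_reps=200, seed=11)
        l1 = frozenset(n for n in seqs.names if n.endswith("|L1"))
        ref = min(seqs.names)
        canon = l1 if ref not in l1 else frozenset(seqs.names) - l1
        assert sup.get(canon, 0.0) >= 0.95


class TestClassification:
    def test_independent_paralog_clades(self):
        labels = ("Hs|L1", "Ha|L1", "Hs|L2", "Ha|L2")
        d = np.array([[0.0, 0.1, 0.6, 0.6],
                      [0.1, 0.0, 0.6, 0.6],
                      [0.6, 0.6, 0.0, 0.1],
                      [0.6, 0.6, 0.1, 0.0]])
        tree = neighbor_joining(DistanceMatrix(labels, d))
        for sp in ("Hs", "Ha"):
            assert classify_paralog_pattern(tree, sp).pattern == "independent"

    def test_concerted_cherry(self):
        labels = ("El|L1", "El|L2", "Hs|L1", "Hs|L2", "Pa|L1")
        d = np.full((5, 5), 0.5)
        np.fill_diagonal(d, 0.0)
        d[0, 1] = d[1, 0] = 0.04  # El pair nearly identical
        d[2, 3] = d[3, 2] = 0.45
        tree = neighbor_joining(DistanceMatrix(labels, d))
        assert classify_paralog_pattern(tree, "El").pattern == "concerted"

    def test_missing_paralog_errors(self):
        tree = TreeNode(children=[(TreeNode(label="a|L1"), 1.0),
                                  (TreeNode(label="a|L2"), 1.0),
                                  (TreeNode(label="b|L1"), 1.0)])
        with pytest.raises(ValueError):
            classify_paralog_pattern(tree, "b")

    def test_single_species_unresolved(self):
        tree = TreeNode(children=[(TreeNode(label="a|L1"), 1.0),
                                  (TreeNode(label="a|L2"), 1.0)])
        assert classify_paralog_pattern(tree, "a").pattern == "unresolved"

    def test_split_label_convention(self):
        assert split_label("Pediculus humanus|L2") == \
            ("Pediculus humanus", "L2")
        with pytest.raises(ValueError):
            split_label("no_paralog_tag")


class TestWindowedClassification:
    def test_part_gene_conversion_splits_verdicts(self):
        """Conversion restricted to the first half of the gene gives a
        concerted verdict there and independent beyond it."""
        from mitokaryo.concerted import classify_paralog_windows
        seqs, _ = simulate_paralog_pair(4, "concerted", seed=2,
                                        conversion_tract=(0, 36))
        windows = classify_paralog_windows(seqs, "sp01", window=36)
        assert windows == [(1, 36, "concerted"), (37, 72, "independent")]

    def test_full_conversion_concerted_throughout(self):
        from mitokaryo.concerted import classify_paralog_windows
        seqs, _ = simulate_paralog_pair(4, "concerted", seed=2,
                                        conversion_tract="full")
        patterns = {p for _, _, p in
                    classify_paralog_windows(seqs, "sp01", window=36)}
        assert patterns == {"concerted"}

    def test_bad_window_rejected(self):
        from mitokaryo.concerted import classify_paralog_windows
        seqs, _ = simulate_paralog_pair(3, "independent", seed=1)
        with pytest.raises(ValueError):
            classify_paralog_windows(seqs, "sp01", window=2)


class TestParalogDifference:
    def test_identical(self):
        assert paralog_difference("ACGT", "ACGT") == (0, ())

    def test_positions_are_one_based(self):
        a = "A" * 40
        b = "A" * 34 + "CCC" + "A" * 3
        assert paralog_difference(a, b) == (3, (35, 36, 37))

    def test_unequal_length_errors(self):
        with pytest.raises(ValueError):
            paralog_difference("ACG", "AC")

    def test_converted_paralogs_differ_at_anticodon_only(self):
        seqs, truth = simulate_paralog_pair(3, "concerted", seed=4,
                                            conversion_tract="full")
        for sp in ("sp01", "sp02", "sp03"):
            n, pos = paralog_difference(seqs.records[f"{sp}|L1"],
                                        seqs.records[f"{sp}|L2"])
            assert n == 3
            assert pos == truth["anticodon_positions"]
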