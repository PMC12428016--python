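import io
import math
import random

import dendropy
import numpy as np
import pytest

import helpers
from mitoray import simulate
from mitoray.phylogeny import (
    DistanceMatrix,
    PhylogenyError,
    PhyloTree,
    bootstrap_support,
    is_monophyletic,
    neighbor_joining,
    pairwise_distances,
)


class TestPairwiseDistances:
    def test_identical_pair_is_zero(self):
        dm = pairwise_distances({"a": "ACGTACGT", "b": "ACGTACGT"}, model="p")
        assert dm.matrix[0, 1] == 0.0

    def test_p_distance_direct_count(self):
        dm = pairwise_distances({"a": "ACGT", "b": "ACGA"}, model="p")
        assert dm.matrix[0, 1] == pytest.approx(0.25)

    def test_k2p_matches_closed_form(self):
        """A constructed pair with P = 0.1 transitions, Q = 0.05
        transversions reproduces Kimura's closed form."""
        n = 200
        a = list("ACGT" * 50)
        b = list(a)
        for i in range(20):  # transitions: A<->G at A positions
            b[4 * i] = "G"
        for i in range(10):  # transversions: C->A
            b[4 * i + 1] = "A"
        dm = pairwise_distances({"x": "".join(a), "y": "".join(b)}, model="k2p")
        P, Q = 20 / n, 10 / n
        expected = -0.5 * math.log(1 - 2 * P - Q) - 0.25 * math.log(1 - 2 * Q)
        assert dm.matrix[0, 1] == pytest.approx(expected)

    def test_gap_and_n_columns_pairwise_deleted(self):
        dm = pairwise_distances({"a": "ACGTNN", "b": "ACCA--"}, model="p")
        assert dm.matrix[0, 1] == pytest.approx(2 / 4)

    def test_no_comparable_columns_is_an_error(self):
        with pytest.raises(PhylogenyError):
            pairwise_distances({"a": "NNNN", "b": "ACGT"}, model="p")

    def test_saturated_k2p_pair_marked_undefined(self):
        dm = pairwise_distances({"a": "AAAA" * 5, "b": "GGGG" * 5}, model="k2p")
        assert dm.undefined_pairs == [("a", "b")]
        assert not dm.complete
        with pytest.raises(PhylogenyError):
            neighbor_joining(DistanceMatrix(["a", "b", "c"],
                                            np.array([[0, np.nan, 1], [np.nan, 0, 1], [1, 1, 0.0]]),
                                            "k2p", [("a", "b")]))


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        dm = DistanceMatrix(["a", "b", "c"], np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0.0]]), "p", [])
        tree = neighbor_joining(dm)
        lengths = {lf.taxon.label: lf.edge.length for lf in tree.tree.leaf_node_iter()}
        assert lengths == pytest.approx({"a": 1.0, "b": 2.0, "c": 3.0})

    def test_additive_four_taxon_matrix_recovered_exactly(self):
        # tree ((A:2,B:3):1,(C:4,D:5)) as an additive matrix
        D = np.array([[0, 5, 7, 8], [5, 0, 8, 9], [7, 8, 0, 9], [8, 9, 9, 0.0]])
        tree = neighbor_joining(DistanceMatrix(["A", "B", "C", "D"], D, "p", []))
        assert tree.bipartitions() == {frozenset({"C", "D"})}
        lengths = {lf.taxon.label: lf.edge.length for lf in tree.tree.leaf_node_iter()}
        assert lengths == pytest.approx({"A": 2.0, "B": 3.0, "C": 4.0, "D": 5.0})

    def test_ultrametric_hierarchy_recovered(self):
        labels = ["a", "b", "c", "d", "e"]
        # ((a,b) with (c,d)), e as the deepest split
        D = np.array(
            [
                [0, 2, 6, 6, 10],
                [2, 0, 6, 6, 10],
                [6, 6, 0, 2, 10],
                [6, 6, 2, 0, 10],
                [10, 10, 10, 10, 0],
            ],
            float,
        )
        tree = neighbor_joining(DistanceMatrix(labels, D, "p", []))
        assert frozenset({"a", "b"}) in tree.bipartitions() or \
               frozenset({"c", "d"}) in tree.bipartitions()

    def test_random_additive_trees_recovered(self):
        """NJ is exact on additive matrices: topology and branch lengths
        match the generating tree for random trees up to 8 taxa."""
        rng = random.Random(77)
        for trial in range(25):
            n = rng.randint(4, 8)
            newick, labels, dists = helpers.random_additive_tree(rng, n)
            D = np.zeros((n, n))
            for (x, y), d in dists.items():
                i, j = labels.index(x), labels.index(y)
                D[i, j] = D[j, i] = d
            tree = neighbor_joining(DistanceMatrix(labels, D, "p", []))
            truth = PhyloTree.from_newick(newick)
            assert tree.bipartitions() == truth.bipartitions()
            # NJ on additive input also reproduces the path lengths
            pdm = tree.tree.phylogenetic_distance_matrix()
            for (x, y), d in dists.items():
                tx = tree.tree.taxon_namespace.get_taxon(x)
                ty = tree.tree.taxon_namespace.get_taxon(y)
                assert pdm.distance(tx, ty) == pytest.approx(d, abs=1e-6)

    def test_agrees_with_dendropy_nj_on_random_matrices(self):
        """Cross-check against DendroPy's independent NJ implementation."""
        rng = np.random.default_rng(123)
        for _ in range(5):
            n = 6
            labels = [f"t{i}" for i in range(n)]
            base = rng.uniform(0.05, 1.0, size=(n, n))
            D = (base + base.T) / 2
            np.fill_diagonal(D, 0.0)
            ours = neighbor_joining(DistanceMatrix(labels, D, "p", []))
            csv = "," + ",".join(labels) + "\n" + "\n".join(
                labels[i] + "," + ",".join(str(D[i, j]) for j in range(n)) for i in range(n)
            )
            pdm = dendropy.PhylogeneticDistanceMatrix.from_csv(
                src=io.StringIO(csv), delimiter=","
            )
            theirs = PhyloTree(pdm.nj_tree())
            assert ours.bipartitions() == theirs.bipartitions()

    def test_too_few_taxa_rejected(self):
        with pytest.raises(PhylogenyError):
            neighbor_joining(DistanceMatrix(["a", "b"], np.zeros((2, 2)), "p", []))


class TestBootstrap:
    def _family(self, seed=0, sites=2000):
        newick = "(((A:0.03,B:0.03):0.05,(C:0.03,D:0.03):0.05):0.05,E:0.1);"
        rng = np.random.default_rng(seed)
        root = simulate.random_sequence(sites, [0.25] * 4, rng)
        return simulate.evolve_nucleotide_family(root, newick, kappa=2.0, seed=seed)

    def test_clear_clades_reach_high_support(self):
        fam = self._family(seed=4)
        tree = bootstrap_support(fam, model="k2p", replicates=200, seed=11)
        supports = {}
        leaves = tree.leaf_labels
        ref = min(leaves)
        for node in tree.tree.preorder_node_iter():
            if node.is_leaf() or node.parent_node is None or node.label is None:
                continue
            side = frozenset(lf.taxon.label for lf in node.leaf_iter())
            if ref in side:
                side = frozenset(leaves - side)
            supports[side] = float(node.label)
        assert supports[frozenset({"C", "D"})] >= 0.95

    def test_single_replicate_gives_binary_support(self):
        fam = self._family(seed=5, sites=500)
        tree = bootstrap_support(fam, model="p", replicates=1, seed=2)
        values = [float(n.label) for n in tree.tree.preorder_node_iter()
                  if not n.is_leaf() and n.parent_node is not None and n.label]
        assert values and all(v in (0.0, 1.0) for v in values)

    def test_column_permutation_leaves_supports_unchanged(self):
        fam = self._family(seed=6, sites=600)
        rng = np.random.default_rng(0)
        perm = rng.permutation(600)
        shuffled = {k: "".join(s[i] for i in perm) for k, s in fam.items()}
        t1 = bootstrap_support(fam, model="p", replicates=50, seed=9)
        t2 = bootstrap_support(shuffled, model="p", replicates=50, seed=9)
        def labels(t):
            return sorted(n.label for n in t.tree.preorder_node_iter()
                          if not n.is_leaf() and n.parent_node is not None and n.label)
        assert labels(t1) == labels(t2)


class TestMonophyly:
    def _tree(self):
        return PhyloTree.from_newick("(((A:1,B:1):1,(C:1,D:1):1):1,OUT:3);")

    def test_singleton_and_complement_are_trivially_monophyletic(self):
        tree = self._tree()
        assert is_monophyletic(tree, {"A"}, "OUT")[0]
        assert is_monophyletic(tree, {"A", "B", "C", "D"}, "OUT")[0]

    def test_clade_detected_and_mixture_rejected(self):
        tree = self._tree()
        ok, clade = is_monophyletic(tree, {"A", "B"}, "OUT")
        assert ok and clade == frozenset({"A", "B"})
        bad, clade = is_monophyletic(tree, {"A", "C"}, "OUT")
        assert not bad and clade == frozenset({"A", "B", "C", "D"})

    def test_unknown_labels_rejected(self):
        with pytest.raises(PhylogenyError):
            is_monophyletic(self._tree(), {"A", "Z"}, "OUT")
        with pytest.raises(PhylogenyError):
            is_monophyletic(self._tree(), {"A", "OUT"}, "OUT")

    def test_newick_round_trip_preserves_leaves_and_bipartitions(self):
        tree = self._tree()
        again = PhyloTree.from_newick(tree.to_newick())
        assert again.leaf_labels == tree.leaf_labels
        assert again.bipartitions() == tree.bipartitions()
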