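"""Distances, neighbor joining, bootstrap and Newick round-trips."""

import numpy as np
import pytest
import dendropy
from dendropy.calculate import treecompare

from abc_structevol import (
    Alignment,
    DistanceMatrix,
    SaturationError,
    bootstrap_support,
    correct_distance,
    correct_matrix,
    evolve_sequence,
    neighbor_joining,
    p_distance,
    patristic_matrix,
    read_newick,
    write_newick,
)
from abc_structevol.simulate import random_sequence


class TestDistances:
    def test_p_distance_examples(self):
        aln = Alignment(["a", "b"], ["ACDE", "ACDF"])
        dm = p_distance(aln)
        assert dm.values[0, 1] == pytest.approx(0.25)
        assert dm.values[0, 0] == 0.0
        assert np.allclose(dm.values, dm.values.T)

    def test_no_comparable_pair_flagged_missing(self):
        aln = Alignment(["a", "b", "c"], ["A--", "-C-", "AC-"])
        dm = p_distance(aln)
        assert ("a", "b") in dm.missing_pairs()

    def test_correction_closed_form(self):
        assert correct_distance(0.0) == 0.0
        assert correct_distance(0.5) == pytest.approx(0.70985, abs=1e-4)

    def test_correction_rejects_saturation(self):
        with pytest.raises(SaturationError):
            correct_distance(0.95)
        dm = DistanceMatrix(["a", "b"], np.array([[0.0, 0.96], [0.96, 0.0]]))
        with pytest.raises(SaturationError, match="a.*b"):
            correct_matrix(dm)

    def test_monte_carlo_inversion_recovers_branch_length(self):
        """E[p] at branch length t inverts back to ~t through the correction."""
        rng = np.random.default_rng(5)
        t = 0.6
        seq = random_sequence(30_000, rng)
        out = evolve_sequence(seq, t, rng)
        p = sum(a != b for a, b in zip(seq, out)) / len(seq)
        assert correct_distance(p) == pytest.approx(t, rel=0.05)


def _random_binary_tree(n_taxa, rng):
    """Random unrooted binary tree with branch lengths in [0.05, 1.0],
    built by random sequential joining."""
    labels = [f"T{i}" for i in range(n_taxa)]
    ns = dendropy.TaxonNamespace(labels)
    nodes = []
    for lab in labels:
        nd = dendropy.Node()
        nd.taxon = ns.get_taxon(lab)
        nd.edge.length = rng.uniform(0.05, 1.0)
        nodes.append(nd)
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        parent = dendropy.Node()
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        parent.edge.length = rng.uniform(0.05, 1.0)
        nodes = [nd for k, nd in enumerate(nodes) if k not in (i, j)] + [parent]
    tree = dendropy.Tree(taxon_namespace=ns)
    for nd in nodes:
        tree.seed_node.add_child(nd)
    tree.is_rooted = False
    return tree


class TestNeighborJoining:
    def test_three_taxon_closed_form(self):
        d_ab, d_ac, d_bc = 0.4, 0.7, 0.9
        dm = DistanceMatrix(
            ["A", "B", "C"],
            np.array([[0, d_ab, d_ac], [d_ab, 0, d_bc], [d_ac, d_bc, 0]]),
        )
        tree = neighbor_joining(dm)
        lengths = {
            lf.taxon.label: lf.edge.length for lf in tree.leaf_node_iter()
        }
        assert lengths["A"] == pytest.approx((d_ab + d_ac - d_bc) / 2)
        assert lengths["B"] == pytest.approx((d_ab + d_bc - d_ac) / 2)
        assert lengths["C"] == pytest.approx((d_ac + d_bc - d_ab) / 2)

    def test_additive_four_taxon_recovery(self):
        """Distances from ((A:1,B:2):1,(C:3,D:4)) recover the {A,B}|{C,D}
        split with exact branch lengths (four-point condition)."""
        ids = ["A", "B", "C", "D"]
        d = {
            ("A", "B"): 3, ("A", "C"): 5, ("A", "D"): 6,
            ("B", "C"): 6, ("B", "D"): 7, ("C", "D"): 7,
        }
        values = np.zeros((4, 4))
        for (x, y), v in d.items():
            i, j = ids.index(x), ids.index(y)
            values[i, j] = values[j, i] = v
        tree = neighbor_joining(DistanceMatrix(ids, values))
        pat = patristic_matrix(tree)
        for (x, y), v in d.items():
            assert pat.values[pat.ids.index(x), pat.ids.index(y)] == pytest.approx(v, abs=1e-9)
        # A and B must be siblings
        a = next(lf for lf in tree.leaf_node_iter() if lf.taxon.label == "A")
        sibs = {lf.taxon.label for lf in a.parent_node.leaf_nodes()}
        assert sibs == {"A", "B"}
        lengths = {lf.taxon.label: lf.edge.length for lf in tree.leaf_node_iter()}
        assert lengths["A"] == pytest.approx(1.0) and lengths["D"] == pytest.approx(4.0)

    def test_equal_distances_tie_break_is_lexicographic(self):
        dm = DistanceMatrix(["D", "C", "B", "A"], np.ones((4, 4)) - np.eye(4))
        tree = neighbor_joining(dm)
        a = next(lf for lf in tree.leaf_node_iter() if lf.taxon.label == "A")
        sibs = {lf.taxon.label for lf in a.parent_node.leaf_nodes()}
        assert sibs == {"A", "B"}  # smallest tip-id pair joined first

    def test_missing_cell_rejected(self):
        values = np.zeros((3, 3))
        values[0, 1] = values[1, 0] = np.nan
        with pytest.raises(ValueError, match="missing"):
            neighbor_joining(DistanceMatrix(["a", "b", "c"], values))

    def test_consistency_on_random_trees(self):
        """NJ on the exact patristic matrix of a random 8-taxon binary tree
        recovers its unrooted topology and reproduces the distances."""
        rng = np.random.default_rng(17)
        for _ in range(20):
            true = _random_binary_tree(8, rng)
            dm = patristic_matrix(true)
            est = neighbor_joining(dm, taxon_namespace=true.taxon_namespace)
            true.encode_bipartitions()
            est.encode_bipartitions()
            assert treecompare.symmetric_difference(true, est) == 0
            back = patristic_matrix(est)
            assert np.allclose(back.values, dm.values, atol=1e-9)

    def test_independent_library_cross_check(self):
        """Agreement with scikit-bio's independent NJ implementation on a
        non-trivial random distance matrix."""
        import skbio

        rng = np.random.default_rng(3)
        true = _random_binary_tree(7, rng)
        dm = patristic_matrix(true)
        ours = neighbor_joining(dm, taxon_namespace=true.taxon_namespace)
        sk_tree = skbio.tree.nj(skbio.DistanceMatrix(dm.values, ids=dm.ids))
        sk_dendro = read_newick(str(sk_tree).strip(),
                                taxon_namespace=true.taxon_namespace)
        ours.encode_bipartitions()
        sk_dendro.encode_bipartitions()
        assert treecompare.symmetric_difference(ours, sk_dendro) == 0


class TestBootstrap:
    def _two_cluster_alignment(self, rng, n_per=3, length=300, within=0.05):
        anc1 = random_sequence(length, rng)
        anc2 = evolve_sequence(anc1, 1.5, rng)  # deep but sub-saturation split
        ids, rows = [], []
        for g, anc in (("x", anc1), ("y", anc2)):
            for i in range(n_per):
                ids.append(f"{g}{i}")
                rows.append(evolve_sequence(anc, within, rng))
        return Alignment(ids, rows)

    def test_strong_split_has_high_support(self):
        rng = np.random.default_rng(21)
        aln = self._two_cluster_alignment(rng)
        tree = bootstrap_support(aln, n_replicates=100, seed=4)
        supports = [
            nd.support for nd in tree.preorder_node_iter()
            if not nd.is_leaf() and nd is not tree.seed_node
        ]
        # the x|y bipartition is the deepest split; at least one internal
        # edge must carry it with overwhelming support
        assert max(supports) >= 0.95

    def test_same_seed_reproducible(self):
        rng = np.random.default_rng(22)
        aln = self._two_cluster_alignment(rng)
        t1 = bootstrap_support(aln, n_replicates=50, seed=9)
        t2 = bootstrap_support(aln, n_replicates=50, seed=9)
        assert write_newick(t1) == write_newick(t2)

    def test_star_like_data_has_low_mean_support(self):
        rng = np.random.default_rng(23)
        anc = random_sequence(200, rng)
        ids, rows = [], []
        for i in range(8):
            ids.append(f"s{i}")
            rows.append(evolve_sequence(anc, 0.8, rng))
        tree = bootstrap_support(Alignment(ids, rows), n_replicates=100, seed=1)
        supports = [
            nd.support for nd in tree.preorder_node_iter()
            if not nd.is_leaf() and nd is not tree.seed_node
        ]
        assert np.mean(supports) < 0.5

    def test_invalid_replicate_count(self):
        rng = np.random.default_rng(0)
        aln = self._two_cluster_alignment(rng, n_per=2)
        with pytest.raises(ValueError):
            bootstrap_support(aln, n_replicates=0)


class TestNewick:
    def test_round_trip_byte_stable_under_rotation(self):
        text = "((A:1,B:2):1,C:3);"
        t1 = read_newick(text)
        rotated = read_newick("(C:3,(B:2,A:1):1);")
        assert write_newick(t1) == write_newick(rotated)
        assert len(t1.leaf_nodes()) == 3

    def test_write_read_write_fixed_point(self):
        text = write_newick(read_newick("((A:1,B:2):0.5,(C:3,D:1):0.5);"))
        assert write_newick(read_newick(text)) == text

    def test_malformed_input_raises_with_position(self):
        with pytest.raises(ValueError, match="parse error"):
            read_newick("((A,B;")

    def test_support_labels_preserved(self):
        tree = read_newick("((A:1,B:2)0.97:1,(C:3,D:1)0.55:1);")
        labels = {nd.label for nd in tree.internal_nodes() if nd.label}
        assert labels == {"0.97", "0.55"}
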