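"""Kernel distances, neighbour joining (with an additive-tree oracle),
Newick round-trips, spectral clustering, and motif/clade annotation."""

import numpy as np
import pytest

from bundlekit.alignment import MSA, builtin_alphabets
from bundlekit.errors import ConfigurationError, InputError, NewickParseError
from bundlekit.phylo import (
    CladeStatus,
    DistanceMatrix,
    PhyloTree,
    TreeNode,
    kernel_matrix,
    kernel_to_distance,
    motif_clade_status,
    neighbor_joining,
    parse_newick,
    read_newick,
    spectral_clustering,
    tree_to_newick,
    triangle_violations,
    write_newick,
)

_PROT = builtin_alphabets()["protein"]
_DNA = builtin_alphabets()["dna"]


class TestKernel:
    def test_blosum62_diagonal_pair(self):
        m = MSA(["x", "y"], ["AR", "AR"], _PROT)
        sim = kernel_matrix(m)
        assert sim[0, 0] == pytest.approx((4 + 5) / 2)  # A/A=4, R/R=5

    def test_blosum62_cross_pair_distance(self):
        m = MSA(["x", "y"], ["AR", "AK"], _PROT)
        sim = kernel_matrix(m)
        assert sim[0, 1] == pytest.approx((4 + 2) / 2)  # A/A=4, R/K=2
        d = kernel_to_distance(sim, m.labels)
        assert d.data[0, 1] == pytest.approx(4.5 + 4.5 - 2 * 3)

    def test_symmetry_on_random_rows(self):
        rng = np.random.default_rng(0)
        syms = _PROT.symbols + ("-",)
        rows = ["".join(rng.choice(syms, 10)) for _ in range(6)]
        m = MSA([f"s{i}" for i in range(6)], rows, _PROT)
        sim = kernel_matrix(m)
        np.testing.assert_allclose(sim, sim.T, atol=1e-12)

    def test_gap_scoring(self):
        m = MSA(["x", "y"], ["--", "--"], _PROT)
        sim = kernel_matrix(m, gap_gap_score=0.0)
        assert sim[0, 1] == 0.0
        m2 = MSA(["x", "y"], ["A-", "AA"], _PROT)
        sim2 = kernel_matrix(m2, gap_score=-4.0)
        assert sim2[0, 1] == pytest.approx((4 - 4) / 2)

    def test_dna_falls_back_to_identity(self):
        m = MSA(["x", "y"], ["ACGT", "ACGA"], _DNA)
        sim = kernel_matrix(m)  # BLOSUM62 does not cover DNA: identity scores
        assert sim[0, 1] == pytest.approx(3 / 4)
        assert sim[0, 0] == 1.0

    def test_unknown_matrix_name(self):
        m = MSA(["x", "y"], ["AR", "AK"], _PROT)
        with pytest.raises(ConfigurationError):
            kernel_matrix(m, "NOSUCH99")

    def test_identical_rows_zero_distance(self):
        m = MSA(["x", "y"], ["ARND", "ARND"], _PROT)
        d = kernel_to_distance(kernel_matrix(m), m.labels)
        assert d.data[0, 1] == 0.0

    def test_distance_invariants_hold(self):
        rng = np.random.default_rng(3)
        syms = _PROT.symbols + ("-",)
        rows = ["".join(rng.choice(syms, 8)) for _ in range(7)]
        m = MSA([f"s{i}" for i in range(7)], rows, _PROT)
        d = kernel_to_distance(kernel_matrix(m), m.labels)
        assert np.all(d.data >= 0)
        assert np.all(np.diag(d.data) == 0)
        np.testing.assert_allclose(d.data, d.data.T, atol=1e-12)
        assert triangle_violations(d) >= 0  # counted, permitted


def _random_additive_tree(rng, n_leaves):
    """Random binary topology with branch lengths in [0.1, 2]; returns the
    dendropy-independent (labels, path-length matrix, newick) triple."""
    nodes = [TreeNode(f"L{i}") for i in range(n_leaves)]
    for node in nodes:
        node.branch_length = rng.uniform(0.1, 2.0)
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), 2, replace=False))
        parent = TreeNode(branch_length=rng.uniform(0.1, 2.0))
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [parent]
    root = TreeNode()
    for n in nodes:
        root.add_child(n)
    tree = PhyloTree(root)
    labels, mat = tree.path_length_matrix()
    return tree, labels, mat


def _rf_distance(newick1, newick2):
    import dendropy

    tns = dendropy.TaxonNamespace()
    t1 = dendropy.Tree.get(data=newick1, schema="newick", taxon_namespace=tns)
    t2 = dendropy.Tree.get(data=newick2, schema="newick", taxon_namespace=tns)
    t1.encode_bipartitions()
    t2.encode_bipartitions()
    return dendropy.calculate.treecompare.symmetric_difference(t1, t2)


class TestNeighborJoining:
    def test_two_taxa_single_edge(self):
        d = DistanceMatrix(["a", "b"], np.array([[0.0, 5.0], [5.0, 0.0]]))
        tree = neighbor_joining(d)
        lengths = [leaf.branch_length for leaf in tree.leaves()]
        assert sum(lengths) == pytest.approx(5.0)

    def test_three_taxa_three_point_formulas(self):
        d = DistanceMatrix(
            ["A", "B", "C"],
            np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], dtype=float),
        )
        tree = neighbor_joining(d)
        bl = {leaf.label: leaf.branch_length for leaf in tree.leaves()}
        assert bl["A"] == pytest.approx((3 + 4 - 5) / 2)
        assert bl["B"] == pytest.approx((3 + 5 - 4) / 2)
        assert bl["C"] == pytest.approx((4 + 5 - 3) / 2)

    def test_additive_matrices_recovered_exactly(self):
        rng = np.random.default_rng(7)
        for trial in range(30):
            n = int(rng.integers(6, 11))
            true_tree, labels, mat = _random_additive_tree(rng, n)
            nj = neighbor_joining(DistanceMatrix(labels, mat))
            assert _rf_distance(tree_to_newick(true_tree), tree_to_newick(nj)) == 0
            _, recovered = nj.path_length_matrix()
            np.testing.assert_allclose(recovered, mat, atol=1e-9)

    def test_deterministic_tie_break(self):
        # fully symmetric distances: lexicographically smallest pair joins first
        d = DistanceMatrix(
            ["c", "a", "d", "b"], np.ones((4, 4)) - np.eye(4)
        )
        t1 = tree_to_newick(neighbor_joining(d))
        t2 = tree_to_newick(neighbor_joining(d))
        assert t1 == t2
        assert "(a:0.5,b:0.5)" in t1

    def test_singleton_rejected(self):
        with pytest.raises(InputError):
            neighbor_joining(DistanceMatrix(["a"], np.zeros((1, 1))))

    def test_negative_estimates_clamped(self):
        d = DistanceMatrix(
            ["a", "b", "c", "d"],
            np.array(
                [[0, 1, 1, 10], [1, 0, 1, 10], [1, 1, 0, 10], [10, 10, 10, 0]],
                dtype=float,
            ),
        )
        tree = neighbor_joining(d)
        for node in tree.root.walk():
            if node.branch_length is not None:
                assert node.branch_length >= 0


class TestNewick:
    def test_three_leaf_round_trip(self):
        t = parse_newick("((a:1,b:2):0.5,c:3);")
        assert tree_to_newick(t) == "((a:1,b:2):0.5,c:3);"
        assert t.leaf_labels() == {"a", "b", "c"}

    def test_unlabeled_internal_nodes_tolerated(self):
        t = parse_newick("((a:1,b:1):1,(c:1,d:1):1);")
        assert len(t.leaves()) == 4

    def test_internal_labels_kept(self):
        t = parse_newick("((a:1,b:1)AB:1,c:2);")
        assert "AB" in {n.label for n in t.root.walk()}

    def test_malformed_reports_position(self):
        with pytest.raises(NewickParseError) as err:
            parse_newick("((a:1,b:2:0.5,c:3);")
        assert err.value.position == 1  # the inner unclosed '('
        with pytest.raises(NewickParseError):
            parse_newick("(a:1,b:2)")  # missing semicolon

    def test_random_trees_round_trip(self, tmp_path):
        rng = np.random.default_rng(5)
        for trial in range(10):
            tree, _, mat = _random_additive_tree(rng, int(rng.integers(4, 9)))
            path = tmp_path / f"t{trial}.nwk"
            write_newick(tree, path)
            back = read_newick(path)
            assert tree_to_newick(back) == tree_to_newick(tree)
            _, mat2 = back.path_length_matrix()
            np.testing.assert_allclose(mat2, mat, atol=1e-9)

    def test_matches_dendropy_parse(self):
        import dendropy

        text = "((a:1.5,b:2.25):0.5,(c:3,d:0.125):1,e:2);"
        ours = parse_newick(text)
        theirs = dendropy.Tree.get(data=text, schema="newick")
        assert ours.leaf_labels() == {
            t.label for t in theirs.taxon_namespace
        }
        assert tree_to_newick(ours) == text


class TestSpectralClustering:
    def _block_matrix(self, sizes, within=0.1, between=10.0):
        n = sum(sizes)
        d = np.full((n, n), between)
        start = 0
        for s in sizes:
            d[start:start + s, start:start + s] = within
            start += s
        np.fill_diagonal(d, 0.0)
        return DistanceMatrix([f"s{i}" for i in range(n)], d)

    def test_two_blocks_recovered_exactly(self):
        d = self._block_matrix([6, 6])
        ga = spectral_clustering(d, 2, seed=0)
        first = {ga.membership[i] for i in range(1, 7)}
        second = {ga.membership[i] for i in range(7, 13)}
        assert len(first) == 1 and len(second) == 1 and first != second

    def test_seed_determinism(self):
        d = self._block_matrix([5, 5, 5])
        a = spectral_clustering(d, 3, seed=42)
        b = spectral_clustering(d, 3, seed=42)
        assert a.membership == b.membership

    def test_k_one_single_group(self):
        d = self._block_matrix([4, 4])
        ga = spectral_clustering(d, 1, seed=0)
        assert set(ga.membership.values()) == {"cluster1"}

    def test_k_equals_n_singletons(self):
        d = self._block_matrix([2, 2])
        ga = spectral_clustering(d, 4, seed=0)
        assert len(set(ga.membership.values())) == 4

    def test_k_out_of_range(self):
        d = self._block_matrix([2, 2])
        with pytest.raises(InputError):
            spectral_clustering(d, 5, seed=0)


class TestMotifCladeStatus:
    @pytest.fixture
    def square_tree(self):
        return parse_newick("((a:1,b:1):1,(c:1,d:1):1);")

    @pytest.fixture
    def square_msa(self, dna):
        return MSA(["a", "b", "c", "d"], ["AAAA", "AAAA", "TTTT", "TTAT"], dna)

    def test_synapomorphy(self, square_tree, square_msa):
        status, carriers, clade = motif_clade_status(square_tree, square_msa, {(1, "A")})
        assert status is CladeStatus.SYNAPOMORPHY
        assert carriers == {"a", "b"}
        assert clade.leaf_labels() == {"a", "b"}

    def test_homoplasy_across_the_root(self, square_msa):
        # carriers a and c sit on opposite sides with non-carriers between
        tree = parse_newick("((a:1,b:1):1,(c:1,d:1):1);")
        msa = MSA(["a", "b", "c", "d"], ["ATTA", "TTTT", "AAAA", "TTTT"],
                  square_msa.alphabet)
        status, carriers, clade = motif_clade_status(tree, msa, {(1, "A")})
        assert status is CladeStatus.HOMOPLASY
        assert carriers == {"a", "c"}
        assert clade.leaf_labels() == {"a", "b", "c", "d"}

    def test_absent_and_universal(self, square_tree, square_msa):
        status, carriers, clade = motif_clade_status(square_tree, square_msa, {(1, "C")})
        assert status is CladeStatus.ABSENT and clade is None
        uniform = MSA(["a", "b", "c", "d"], ["A", "A", "A", "A"],
                      square_msa.alphabet)
        status, _, _ = motif_clade_status(square_tree, uniform, {(1, "A")})
        assert status is CladeStatus.UNIVERSAL

    def test_complement_side_counts_as_clade(self, square_tree, square_msa):
        # carriers = everyone but d: complement of a single-leaf bipartition
        msa = MSA(["a", "b", "c", "d"], ["A", "A", "A", "T"], square_msa.alphabet)
        status, carriers, _ = motif_clade_status(square_tree, msa, {(1, "A")})
        assert status is CladeStatus.SYNAPOMORPHY
        assert carriers == {"a", "b", "c"}

    def test_agrees_with_edge_cut_oracle(self):
        """Brute force: carriers form a clade iff deleting some edge splits
        the leaves into carriers vs the rest (networkx connectivity)."""
        import networkx as nx

        rng = np.random.default_rng(13)
        for trial in range(60):
            n = int(rng.integers(4, 13))
            tree, labels, _ = _random_additive_tree(rng, n)
            # random motif: pick a random subset of leaves as carriers
            carrier_set = {l for l in labels if rng.random() < 0.4}
            rows = ["A" if l in carrier_set else "T" for l in labels]
            msa = MSA(labels, rows, _DNA)
            status, carriers, _ = motif_clade_status(tree, msa, {(1, "A")})
            assert carriers == frozenset(carrier_set)
            if not carrier_set or carrier_set == set(labels):
                continue
            # oracle via edge removal on the tree graph
            g = nx.Graph()
            for node in tree.root.walk():
                for child in node.children:
                    g.add_edge(id(node), id(child))
            leaf_of = {id(node): node.label for node in tree.root.walk()
                       if node.is_leaf}
            is_clade = False
            for u, v in list(g.edges):
                g.remove_edge(u, v)
                comp = nx.node_connected_component(g, u)
                side = {leaf_of[x] for x in comp if x in leaf_of}
                if side == carrier_set or (set(labels) - side) == carrier_set:
                    is_clade = True
                g.add_edge(u, v)
            expected = (
                CladeStatus.SYNAPOMORPHY if is_clade else CladeStatus.HOMOPLASY
            )
            assert status is expected, f"trial {trial}"
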