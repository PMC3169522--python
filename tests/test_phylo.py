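"""Masking, distances, neighbor joining, bootstrap, RF and displacement."""

import dendropy
import numpy as np
import pytest

from clustevo.core import AlignmentBlock
from clustevo.io import read_newick
from clustevo.phylo import (
    DistanceMatrix,
    SupportedTree,
    bootstrap_support,
    clade_partition,
    displacement_test,
    label_internal_nodes,
    mask_columns,
    neighbor_joining,
    pairwise_distance,
    robinson_foulds,
)
from clustevo.simulate import evolve_sequences, simulate_species_tree


def random_additive_tree(n_leaves, rng):
    tree = simulate_species_tree(n_leaves, int(rng.integers(2**31)))
    for edge in tree.preorder_edge_iter():
        if edge.head_node is not tree.seed_node:
            edge.length = float(rng.uniform(0.05, 1.0))
    return tree


def additive_matrix(tree):
    pdm = tree.phylogenetic_distance_matrix()
    labels = sorted(t.label for t in tree.taxon_namespace)
    n = len(labels)
    m = np.zeros((n, n))
    for i, a in enumerate(labels):
        for j, b in enumerate(labels):
            if i < j:
                d = pdm.distance(
                    tree.taxon_namespace.get_taxon(a), tree.taxon_namespace.get_taxon(b)
                )
                m[i, j] = m[j, i] = d
    return DistanceMatrix(tuple(labels), m)


class TestMask:
    def test_gapless_unchanged(self):
        aln = AlignmentBlock(("a", "b"), ("MKLV", "MKIV"))
        assert mask_columns(aln, 0.5).rows == aln.rows

    def test_gappy_column_removed(self):
        aln = AlignmentBlock(("a", "b", "c", "d", "e"), ("M-", "K-", "L-", "VA", "CA"))
        out = mask_columns(aln, 0.5)
        assert out.n_positions == 1 and out.rows == ("M", "K", "L", "V", "C")

    def test_empty_alignment_is_error(self):
        with pytest.raises(ValueError, match="empty"):
            mask_columns(AlignmentBlock((), ()), 0.5)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_per_column_oracle(self, seed):
        rng = np.random.default_rng(seed)
        nrow, ncol = 6, 40
        chars = np.array(list("ACDX-"))
        rows = ["".join(rng.choice(chars, size=ncol)) for _ in range(nrow)]
        aln = AlignmentBlock(tuple(f"r{i}" for i in range(nrow)), tuple(rows))
        max_missing = float(rng.choice([0.0, 0.3, 0.5, 0.9]))
        keep = [
            j
            for j in range(ncol)
            if sum(r[j] in "-X" for r in rows) / nrow <= max_missing
        ]
        expect = tuple("".join(r[j] for j in keep) for r in rows)
        assert mask_columns(aln, max_missing).rows == expect


class TestDistances:
    def test_identical_rows_distance_zero(self):
        aln = AlignmentBlock(("a", "b"), ("MKLV", "MKLV"))
        for model in ("p", "poisson", "gamma"):
            assert pairwise_distance(aln, model).get("a", "b") == 0.0

    def test_pairwise_deletion(self):
        aln = AlignmentBlock(("a", "b"), ("MK-V", "MKL-"))
        assert pairwise_distance(aln, "p").get("a", "b") == 0.0

    def test_no_shared_columns_is_error(self):
        aln = AlignmentBlock(("a", "b"), ("M-", "-K"))
        with pytest.raises(ValueError, match="share no aligned columns"):
            pairwise_distance(aln, "p")

    def test_poisson_consistent_with_simulator(self):
        # two tips separated by total path 0.5 under the 20-state model
        tree = read_newick("(A:0.25,B:0.25);")
        aln = evolve_sequences(tree, 50000, 1.0, seed=7)
        d = pairwise_distance(aln, "poisson").get("A", "B")
        p = pairwise_distance(aln, "p").get("A", "B")
        se = np.sqrt(p * (1 - p) / 50000) / (1 - (20 / 19) * p)
        assert abs(d - 0.5) < 3 * se


class TestNeighborJoining:
    def test_three_taxon_closed_form(self):
        m = DistanceMatrix(("A", "B", "C"), np.array([[0, 2, 3], [2, 0, 3], [3, 3, 0]], float))
        tree = neighbor_joining(m)
        lengths = {
            l.taxon.label: l.edge.length for l in tree.leaf_node_iter()
        }
        assert lengths == pytest.approx({"A": 1.0, "B": 1.0, "C": 2.0})

    @pytest.mark.parametrize("seed", range(8))
    def test_exact_on_additive_matrices(self, seed):
        rng = np.random.default_rng(seed)
        tree = random_additive_tree(8, rng)
        recovered = neighbor_joining(additive_matrix(tree))
        assert robinson_foulds(tree, recovered) == 0

    def test_matches_scikit_bio(self):
        import io as _io

        from skbio import DistanceMatrix as SkbioDM
        from skbio.tree import nj as skbio_nj

        rng = np.random.default_rng(3)
        tree = random_additive_tree(7, rng)
        dm = additive_matrix(tree)
        ours = neighbor_joining(dm)
        sk = skbio_nj(SkbioDM(dm.matrix, ids=list(dm.labels)))
        sk_newick = sk.write(_io.StringIO(), format="newick").getvalue() if hasattr(sk, "write") else str(sk)
        theirs = read_newick(sk_newick)
        assert robinson_foulds(ours, theirs) == 0

    def test_deterministic_tie_break(self):
        # four equidistant taxa: every Q is tied; lexicographically smallest
        # pair (A, B) must be joined first
        m = DistanceMatrix(tuple("ABCD"), np.ones((4, 4)) - np.eye(4))
        tree = neighbor_joining(m)
        sets = {
            frozenset(l.taxon.label for l in n.leaf_iter())
            for n in tree.preorder_node_iter()
            if not n.is_leaf()
        }
        assert {"A", "B"} in sets

    def test_asymmetric_matrix_is_error(self):
        m = np.array([[0, 1.0, 2], [1.5, 0, 1], [2, 1, 0]])
        with pytest.raises(ValueError, match="symmetric"):
            DistanceMatrix(("a", "b", "c"), m)


class TestBootstrap:
    def test_strong_signal_supports_true_edges(self):
        # clean signal: every internal edge long enough to accumulate changes
        tree = random_additive_tree(8, np.random.default_rng(5))
        aln = evolve_sequences(tree, 5000, 0.3, seed=5)
        st = bootstrap_support(aln, n_reps=100, seed=1)
        assert robinson_foulds(st.tree, tree) == 0
        assert all(v >= 95.0 for v in st.support.values())

    def test_single_replicate_supports_binary(self):
        tree = simulate_species_tree(6, seed=2)
        aln = evolve_sequences(tree, 200, 0.3, seed=2)
        st = bootstrap_support(aln, n_reps=1, seed=0)
        assert set(st.support.values()) <= {0.0, 100.0}

    def test_same_seed_same_supports(self):
        tree = simulate_species_tree(6, seed=3)
        aln = evolve_sequences(tree, 300, 0.4, seed=3)
        a = bootstrap_support(aln, n_reps=30, seed=9)
        b = bootstrap_support(aln, n_reps=30, seed=9)
        assert a.support == b.support


class TestRobinsonFoulds:
    def test_identical_trees(self):
        t = read_newick("((A,B),(C,(D,E)));")
        u = read_newick("((A,B),(C,(D,E)));")
        assert robinson_foulds(t, u) == 0

    def test_single_nni_differs_by_two(self):
        t = read_newick("(((A,B),C),(D,E));")
        u = read_newick("(((A,C),B),(D,E));")
        assert robinson_foulds(t, u) == 2

    @pytest.mark.parametrize("n", [5, 7, 9])
    def test_caterpillar_vs_reversed_hits_bound(self, n):
        labels = [f"T{i}" for i in range(n)]

        def caterpillar(ls):
            s = f"({ls[0]},{ls[1]})"
            for x in ls[2:]:
                s = f"({s},{x})"
            return s + ";"

        t = read_newick(caterpillar(labels))
        # interleave so no internal bipartition is shared
        u = read_newick(caterpillar(labels[::2] + labels[1::2]))
        assert robinson_foulds(t, u) == 2 * (n - 3)

    def test_mismatched_leaves_is_error(self):
        t = read_newick("((A,B),C);")
        u = read_newick("((A,B),D);")
        with pytest.raises(ValueError, match="leaf sets differ"):
            robinson_foulds(t, u)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_dendropy(self, seed):
        rng = np.random.default_rng(seed)
        tns = dendropy.TaxonNamespace([f"T{i}" for i in range(8)])
        t1 = dendropy.simulate.treesim.birth_death_tree(
            1.0, 0.0, num_extant_tips=8, taxon_namespace=tns, rng=__import__("random").Random(seed)
        )
        t2 = dendropy.simulate.treesim.birth_death_tree(
            1.0, 0.0, num_extant_tips=8, taxon_namespace=tns, rng=__import__("random").Random(seed + 100)
        )
        for t in (t1, t2):
            t.is_rooted = False
            t.update_bipartitions()
        expected = dendropy.calculate.treecompare.symmetric_difference(t1, t2)
        assert robinson_foulds(t1, t2) == expected


class TestDisplacement:
    def species(self):
        return read_newick("(((A:1,B:1):1,C:2):1,((D:1,E:1):1,F:2):1);")

    def clade_map(self):
        return {"A": "X", "B": "X", "C": "X", "D": "Y", "E": "Y", "F": "Y"}

    def supported(self, newick):
        tree = read_newick(newick)
        tree.is_rooted = True
        from clustevo.phylo import bipartitions

        support = {side: 100.0 for side in bipartitions(tree)}
        return SupportedTree(tree, support)

    def test_congruent_tree_reports_nothing(self):
        st = self.supported("(((A:1,B:1):1,C:2):1,((D:1,E:1):1,F:2):1);")
        assert displacement_test(st, self.clade_map(), 70.0, species_tree=self.species()) == ()

    def test_transferred_taxon_reported_with_source(self):
        # F's copy nests inside the (A,B) clade, far from its own clade
        st = self.supported("((((A:1,F:0.2):0.8,B:1):1,C:2):1,(D:1,E:1):2);")
        reports = displacement_test(st, self.clade_map(), 70.0, species_tree=self.species())
        assert [r.taxon for r in reports] == ["F"]
        assert reports[0].observed_clade == "X"

    def test_vacuous_support_threshold(self):
        st = self.supported("((((A:1,F:0.2):0.8,B:1):1,C:2):1,(D:1,E:1):2);")
        assert displacement_test(st, self.clade_map(), 101.0, species_tree=self.species()) == ()

    def test_unmapped_leaf_is_error(self):
        st = self.supported("((A:1,B:1):1,(C:1,Z:1):1);")
        with pytest.raises(ValueError, match="Z"):
            displacement_test(st, {"A": "X", "B": "X", "C": "X"}, 70.0)


class TestCladePartition:
    def test_no_singleton_clades(self):
        tree = simulate_species_tree(17, seed=4)
        cm = clade_partition(tree, max_size=3)
        sizes = {}
        for clade in cm.values():
            sizes[clade] = sizes.get(clade, 0) + 1
        assert min(sizes.values()) >= 2
        assert set(cm) == {l.taxon.label for l in tree.leaf_node_iter()}
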