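"""Simulator contracts: species trees, gene content, sequences, assembly,
features, and the truth-log accounting invariant."""

import numpy as np
import pytest
from scipy import stats

from clustevo.core import LocusFeatures
from clustevo.io import write_newick
from clustevo.phylo import branch_leaf_sets, label_internal_nodes, node_name, robinson_foulds
from clustevo.simulate import (
    BranchTable,
    EvolutionParams,
    SimulationConfig,
    annotate_features,
    assemble_genomes,
    copy_family,
    evolve_gene_content,
    evolve_sequences,
    simulate_dataset,
    simulate_species_tree,
)


class TestSpeciesTree:
    def test_three_taxa_shape(self):
        tree = simulate_species_tree(3, seed=0)
        assert sum(1 for _ in tree.leaf_node_iter()) == 3
        assert sum(1 for n in tree.preorder_node_iter() if not n.is_leaf()) == 2

    @pytest.mark.parametrize("n", [3, 8, 25])
    def test_ultrametric_depth_one(self, n):
        tree = simulate_species_tree(n, seed=n)
        for leaf in tree.leaf_node_iter():
            depth = 0.0
            node = leaf
            while node.parent_node is not None:
                depth += node.edge.length
                node = node.parent_node
            assert depth == pytest.approx(1.0, abs=1e-9)

    def test_same_seed_identical_newick(self):
        a = write_newick(simulate_species_tree(12, seed=7))
        b = write_newick(simulate_species_tree(12, seed=7))
        assert a == b

    def test_too_few_taxa_is_error(self):
        with pytest.raises(ValueError):
            simulate_species_tree(2, seed=0)


class TestGeneContent:
    def test_zero_rates_single_copy_below_origin(self):
        tree = simulate_species_tree(8, seed=1)
        branches = BranchTable(tree)
        # pick an internal branch as origin
        origin = next(
            b for b in branches.names() if not branches.is_leaf(b) and b != branches.root_name
        )
        params = [EvolutionParams("f", origin)]
        counts, trees, log = evolve_gene_content(tree, params, seed=0)
        below = branch_leaf_sets(tree)[origin]
        for taxon in counts.columns:
            assert counts.loc["f", taxon] == (1 if taxon in below else 0)

    def test_unknown_origin_branch_is_error(self):
        tree = simulate_species_tree(4, seed=1)
        with pytest.raises(ValueError, match="origin branch"):
            evolve_gene_content(tree, [EvolutionParams("f", "nope")], seed=0)

    def test_vertical_gene_tree_congruent_with_species_tree(self):
        tree = simulate_species_tree(10, seed=3)
        root = node_name(tree.seed_node)
        counts, trees, log = evolve_gene_content(
            tree, [EvolutionParams("f", root)], seed=0
        )
        gt = trees["f"].clone(depth=1)
        for leaf in gt.leaf_node_iter():
            # copy id ends with the tip branch name
            leaf.taxon = gt.taxon_namespace.new_taxon(leaf.taxon.label.split("-")[-1])
        gt.is_rooted = False
        assert robinson_foulds(gt, tree) == 0

    def test_replay_reproduces_tip_counts(self):
        tree = simulate_species_tree(10, seed=4)
        root = node_name(tree.seed_node)
        params = [
            EvolutionParams("f1", root, dup_rate=0.4, loss_rate=0.2, transfer_rate=0.3),
            EvolutionParams("f2", root, dup_rate=0.1, loss_rate=0.05, transfer_rate=0.1),
        ]
        counts, _, log = evolve_gene_content(tree, params, seed=11)
        replay = log.replay_tip_counts(BranchTable(tree))
        assert replay.equals(counts.loc[replay.index, replay.columns])

    def test_transfer_count_grows_with_rate(self):
        tree = simulate_species_tree(10, seed=5)
        root = node_name(tree.seed_node)
        totals = []
        for tau in (0.1, 0.4, 1.2):
            n = 0
            for rep in range(60):
                _, _, log = evolve_gene_content(
                    tree, [EvolutionParams("f", root, transfer_rate=tau)], seed=rep
                )
                n += len(log.of_type("transfer"))
            totals.append(n)
        assert totals[0] < totals[1] < totals[2]
        # roughly linear growth: quadrupling tau at least triples the count
        assert totals[1] >= 2 * totals[0] and totals[2] >= 2 * totals[1]


class TestSequences:
    def test_zero_rate_identical_rows(self):
        tree = simulate_species_tree(5, seed=0)
        aln = evolve_sequences(tree, 100, 0.0, seed=1)
        assert len(set(aln.rows)) == 1

    def test_divergence_matches_closed_form(self):
        from clustevo.io import read_newick

        d = 0.8
        tree = read_newick(f"(A:{d / 2},B:{d / 2});")
        L = 10000
        aln = evolve_sequences(tree, L, 1.0, seed=2)
        p_obs = sum(x != y for x, y in zip(aln.row("A"), aln.row("B"))) / L
        p_exp = (19 / 20) * (1 - np.exp(-(20 / 19) * d))
        se = np.sqrt(p_exp * (1 - p_exp) / L)
        assert abs(p_obs - p_exp) < 3 * se

    def test_same_seed_identical(self):
        tree = simulate_species_tree(5, seed=3)
        a = evolve_sequences(tree, 50, 0.5, seed=9)
        b = evolve_sequences(tree, 50, 0.5, seed=9)
        assert a == b

    def test_bad_length_is_error(self):
        tree = simulate_species_tree(3, seed=0)
        with pytest.raises(ValueError):
            evolve_sequences(tree, 0, 0.1, seed=0)


class TestAssembly:
    CLADES = {"T1": ("X",), "T2": ("X",)}

    def test_full_linkage_places_module_contiguously(self):
        copies = {
            "T1": {"a": ["a__c0"], "b": ["b__c0"], "c": ["c__c0"]},
            "T2": {"a": ["a__c1"], "b": ["b__c1"], "c": ["c__c1"]},
        }
        genomes = assemble_genomes(
            copies, {"m": ("a", "b", "c")}, self.CLADES, p_linkage=1.0, n_background=30, seed=0
        )
        for g in genomes:
            idx = sorted(
                l.ordinal_index for l in g.loci if l.family_id is not None
            )
            assert idx == list(range(idx[0], idx[0] + 3))

    def test_no_copies_only_filler(self):
        genomes = assemble_genomes(
            {"T1": {}, "T2": {}}, {}, self.CLADES, p_linkage=1.0, n_background=7, seed=0
        )
        for g in genomes:
            assert len(g.loci) == 7
            assert all(l.family_id is None for l in g.loci)

    def test_unlinked_placement_is_uniformish(self):
        # with p_linkage=0 the three module loci should be adjacent no more
        # often than a uniform-placement binomial allows
        n_adj = 0
        reps = 200
        n_bg = 60
        for rep in range(reps):
            copies = {"T1": {"a": ["a__c0"], "b": ["b__c0"], "c": ["c__c0"]}}
            (g,) = assemble_genomes(
                copies, {"m": ("a", "b", "c")}, {"T1": ("X",)}, 0.0, n_bg, seed=rep
            )
            idx = sorted(l.ordinal_index for l in g.loci if l.family_id)
            if idx[2] - idx[0] == 2:
                n_adj += 1
        # P(all three adjacent) under uniform order of 63 items ~ 3!*61/ C(63,3)...
        # conservative bound: expected << reps * 0.01; test at alpha=1e-4
        bound = stats.binom.ppf(0.9999, reps, 0.01)
        assert n_adj <= bound

    def test_bad_linkage_probability_is_error(self):
        with pytest.raises(ValueError):
            assemble_genomes({}, {}, {}, p_linkage=1.5, n_background=1, seed=0)


class TestFeatures:
    def _genome(self, n, fam=None):
        from .conftest import make_genome

        fams = {f"L{i}": fam for i in range(n)} if fam else {}
        return make_genome("g", [(f"L{i}", i) for i in range(n)], families=fams)

    def test_zero_noise_copies_template(self):
        tpl = {"f": LocusFeatures(signal_peptide=True, tm_count=2, length_aa=99)}
        table = annotate_features([self._genome(5, "f")], tpl, 0.0, seed=0)
        for i in range(5):
            f = table.get("g", f"L{i}")
            assert (f.signal_peptide, f.tm_count, f.length_aa) == (True, 2, 99)

    def test_flip_fraction_matches_noise(self):
        n = 10000
        tpl = {"f": LocusFeatures(signal_peptide=True)}
        table = annotate_features([self._genome(n, "f")], tpl, 0.1, seed=1)
        flipped = sum(
            not table.get("g", f"L{i}").signal_peptide for i in range(n)
        )
        se = np.sqrt(0.1 * 0.9 / n)
        assert abs(flipped / n - 0.1) < 3 * se

    def test_tm_count_never_negative(self):
        tpl = {"f": LocusFeatures(tm_count=1)}
        table = annotate_features([self._genome(500, "f")], tpl, 0.4, seed=2)
        assert all(table.get("g", f"L{i}").tm_count >= 0 for i in range(500))


class TestDataset:
    def test_deterministic(self):
        cfg = SimulationConfig(n_taxa=8, seq_length=120, seed=42, n_background=5)
        a = simulate_dataset(cfg)
        b = simulate_dataset(cfg)
        assert a.sequences == b.sequences
        assert [g.loci for g in a.genomes] == [g.loci for g in b.genomes]
        assert a.truth.events == b.truth.events

    def test_every_copy_has_sequence_and_leaf(self):
        ds = simulate_dataset(SimulationConfig(n_taxa=8, seq_length=80, seed=3, n_background=4))
        for cp in ds.truth.tip_copies:
            assert cp in ds.sequences
            fam = copy_family(cp)
            leaves = {l.taxon.label for l in ds.gene_trees[fam].leaf_node_iter()}
            assert cp in leaves

    def test_machinery_present_in_focal_clade(self):
        ds = simulate_dataset(SimulationConfig(n_taxa=10, seq_length=60, seed=17, n_background=4))
        focal_taxa = branch_leaf_sets(ds.species_tree)[ds.focal_clade]
        by_fam = {}
        for cp, taxon in ds.truth.tip_copies.items():
            if taxon in focal_taxa:
                by_fam.setdefault(copy_family(cp), []).append(cp)
        assert set(by_fam) == set(ds.params)
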