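"""Dollo/Fitch reconstruction, duplication and transfer inference, and
recovery-metric arithmetic."""

import itertools

import numpy as np
import pytest

from clustevo import datasets
from clustevo.io import read_newick
from clustevo.phylo import SupportedTree, bipartitions, displacement_test
from clustevo.scenario import (
    FamilyScenario,
    TransferEvent,
    assemble_scenario,
    dollo_reconstruct,
    fitch_count,
    infer_duplications,
    infer_transfers,
    score_events,
)
from clustevo.simulate import Event, TrueEventLog, simulate_species_tree


class TestDollo:
    def test_two_sister_tips(self, four_taxon_tree):
        origin, losses = dollo_reconstruct({"A": 1, "B": 1, "C": 0, "D": 0}, four_taxon_tree)
        assert origin == "X" and losses == frozenset()

    def test_staged_origins_on_curated_profile(self):
        # the clade-restricted machinery families appear at nested ancestors
        tree = read_newick(datasets.SPECIES_NEWICK)
        profile = datasets.taxonomic_profile()
        expected = {
            "gltA": "MyxoBdello",
            "gltI": "Myxococcales",
            "gltJ": "Myxococcales",
            "gltH": "Cystobacterineae",
            "gltK": "Cystobacterineae",
            "gltD": "Root",
        }
        for fam, want in expected.items():
            origin, losses = dollo_reconstruct(profile.loc[fam].to_dict(), tree)
            assert origin == want, fam
            assert losses == frozenset()

    def test_all_absent_is_error(self, four_taxon_tree):
        with pytest.raises(ValueError, match="all-absent"):
            dollo_reconstruct({"A": 0, "B": 0, "C": 0, "D": 0}, four_taxon_tree)

    @pytest.mark.parametrize("seed", range(5))
    def test_loss_count_matches_exhaustive_oracle(self, seed):
        from .oracles import exhaustive_dollo_losses

        tree = simulate_species_tree(6, seed=seed)
        taxa = sorted(l.taxon.label for l in tree.leaf_node_iter())
        for bits in itertools.product([0, 1], repeat=6):
            if not any(bits):
                continue
            presence = dict(zip(taxa, bits))
            _, losses = dollo_reconstruct(presence, tree)
            assert len(losses) == exhaustive_dollo_losses(presence, tree)


class TestFitch:
    def test_constant_row_zero_changes(self, four_taxon_tree):
        assert fitch_count({"A": 1, "B": 1, "C": 1, "D": 1}, four_taxon_tree) == 0

    def test_alternating_profile_on_balanced_tree(self, four_taxon_tree):
        assert fitch_count({"A": 1, "B": 0, "C": 1, "D": 0}, four_taxon_tree) == 2

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_enumeration_and_dominates_dollo(self, seed):
        from .oracles import exhaustive_fitch_changes

        tree = simulate_species_tree(6, seed=seed + 50)
        taxa = sorted(l.taxon.label for l in tree.leaf_node_iter())
        for bits in itertools.product([0, 1], repeat=6):
            presence = dict(zip(taxa, bits))
            fc = fitch_count(presence, tree)
            assert fc == exhaustive_fitch_changes(presence, tree)
            if any(bits):
                _, losses = dollo_reconstruct(presence, tree)
                assert fc <= len(losses) + 1


class TestDuplications:
    def test_parallel_copies_flag_duplication(self, four_taxon_tree):
        # two full paralogous clades over the same species set
        gt = read_newick("(((A1:1,B1:1):1,(A2:1,B2:1):1):1,(C1:1,D1:1):2);")
        gt.is_rooted = True
        l2t = {"A1": "A", "A2": "A", "B1": "B", "B2": "B", "C1": "C", "D1": "D"}
        dups = infer_duplications(gt, l2t, four_taxon_tree)
        assert [b for _, b in dups] == ["X"]

    def test_congruent_single_copy_no_duplications(self, four_taxon_tree):
        gt = read_newick("((A:1,B:1):1,(C:1,D:1):1);")
        gt.is_rooted = True
        assert infer_duplications(gt, {t: t for t in "ABCD"}, four_taxon_tree) == ()

    def test_unmapped_leaf_is_error(self, four_taxon_tree):
        gt = read_newick("((A:1,B:1):1,(C:1,D:1):1);")
        gt.is_rooted = True
        with pytest.raises((KeyError, ValueError)):
            infer_duplications(gt, {"A": "A"}, four_taxon_tree)


class TestTransfers:
    def test_no_reports_no_events(self, four_taxon_tree):
        assert infer_transfers((), four_taxon_tree) == ()

    def test_block_maps_to_mrca_branch(self, six_taxon_tree):
        from clustevo.phylo import DisplacementReport

        reports = (
            DisplacementReport(
                leaf="d1",
                taxon="D",
                expected_clade="DE",
                observed_clade="AB",
                support=98.0,
                clade_leaves=frozenset({"a1", "b1", "d1", "e1"}),
                block_leaves=frozenset({"d1", "e1"}),
                taxa=frozenset({"D", "E"}),
            ),
        )
        events = infer_transfers(reports, six_taxon_tree)
        assert len(events) == 1
        assert events[0].recipient_branch == "DE"
        assert events[0].source_clade == "AB"


class TestAssembleAndMetrics:
    def test_vertical_single_copy_scenario(self, four_taxon_tree):
        gt = read_newick("((A:1,B:1):1,(C:1,D:1):1);")
        gt.is_rooted = True
        scenarios, metrics = assemble_scenario(
            {"f": {"A": 1, "B": 1, "C": 1, "D": 1}},
            four_taxon_tree,
            {"f": gt},
            {"f": {t: t for t in "ABCD"}},
            {"f": ()},
        )
        (s,) = scenarios
        assert s.origin_branch == "R"
        assert s.loss_branches == frozenset()
        assert s.duplications == () and s.transfers == ()

    def test_transfer_excluded_from_dollo_presence(self, six_taxon_tree):
        # F's only copy is transfer-derived; Dollo origin excludes F
        species = six_taxon_tree
        gt = read_newick("((((A:1,Fc:0.2):0.8,B:1):1,C:2):1,(D:1,E:1):2);")
        gt.is_rooted = True
        support = {side: 100.0 for side in bipartitions(gt)}
        l2t = {"A": "A", "B": "B", "C": "C", "D": "D", "E": "E", "Fc": "F"}
        clade_map = {"A": "X", "B": "X", "C": "X", "D": "Y", "E": "Y", "F": "Y"}
        reports = displacement_test(
            SupportedTree(gt, support), clade_map, 70.0,
            leaf_to_taxon=lambda l: l2t[l], species_tree=species,
        )
        scenarios, _ = assemble_scenario(
            {"f": {"A": 1, "B": 1, "C": 1, "D": 1, "E": 1, "F": 1}},
            species,
            {"f": gt},
            {"f": l2t},
            {"f": reports},
        )
        (s,) = scenarios
        assert [t.recipient_branch for t in s.transfers] == ["F"]
        # with F's copy excluded, the vertical origin covers only A-E
        assert s.origin_branch == "R"
        assert "F" not in s.loss_branches or s.loss_branches == frozenset({"F"})

    def test_metrics_equal_brute_force_set_arithmetic(self):
        rng = np.random.default_rng(0)
        branches = [f"b{i}" for i in range(6)]
        for _ in range(20):
            true_events = [
                Event("duplication", "f", rng.choice(branches), 0.1, f"c{i}", (f"c{i}a", f"c{i}b"))
                for i in range(rng.integers(0, 5))
            ]
            tips = {}
            for e in true_events:
                tips[e.children[0] + "-x"] = "T1"
                tips[e.children[1] + "-y"] = "T2"
            truth = TrueEventLog(true_events, tips)
            inferred = [
                ("f", rng.choice(branches)) for _ in range(rng.integers(0, 5))
            ]
            scen = [
                FamilyScenario("f", None, frozenset(), tuple(("n", b) for _, b in inferred), ())
            ]
            m = score_events(scen, truth)
            t_set = [(e.family_id, e.branch) for e in true_events]
            from collections import Counter

            tp = sum((Counter(t_set) & Counter(inferred)).values())
            p, r, f1, nt, ni = m.per_type["duplication"]
            assert nt == len(t_set) and ni == len(inferred)
            assert p == pytest.approx(tp / ni if ni else 1.0)
            assert r == pytest.approx(tp / nt if nt else 1.0)

    def test_empty_inferred_vs_nonempty_truth_zero_recall(self):
        e = Event("duplication", "f", "b1", 0.1, "c", ("ca", "cb"))
        truth = TrueEventLog([e], {"ca-t": "T1", "cb-t": "T2"})
        m = score_events([FamilyScenario("f", None, frozenset(), (), ())], truth)
        assert m.recall("duplication") == 0.0
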