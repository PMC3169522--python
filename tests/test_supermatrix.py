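"""Congruence grouping, paralogue linkage and concatenation bookkeeping."""

import numpy as np
import pytest

from clustevo.clusters import detect_clusters
from clustevo.core import AlignmentBlock
from clustevo.io import read_newick
from clustevo.supermatrix import (
    LinkedTuple,
    concatenate,
    congruence_groups,
    link_paralogues,
)

from .conftest import make_genome


def tree_for(fam, topo="((({f}A:1,{f}B:1):1,{f}C:2):1,({f}D:1,{f}E:1):2);"):
    return read_newick(topo.format(f=fam + "_"))


def l2t(fams):
    return {
        f: {f"{f}_{t}": t for t in "ABCDE"} for f in fams
    }


class TestCongruenceGroups:
    def test_colocated_congruent_families_group(self):
        trees = {"f1": tree_for("f1"), "f2": tree_for("f2")}
        groups = congruence_groups(
            trees, l2t(["f1", "f2"]), [frozenset({"f1", "f2"})], rf_max=2, min_shared_taxa=4
        )
        assert groups == (frozenset({"f1", "f2"}),)

    def test_never_colocated_stay_separate(self):
        # identical histories are not enough without physical linkage
        trees = {"f1": tree_for("f1"), "f2": tree_for("f2")}
        groups = congruence_groups(trees, l2t(["f1", "f2"]), [], rf_max=2)
        assert groups == (frozenset({"f1"}), frozenset({"f2"}))

    def test_incongruent_families_stay_separate(self):
        other = "((({f}A:1,{f}D:1):1,{f}C:2):1,({f}B:1,{f}E:1):2);"
        trees = {"f1": tree_for("f1"), "f2": tree_for("f2", other)}
        groups = congruence_groups(
            trees, l2t(["f1", "f2"]), [frozenset({"f1", "f2"})], rf_max=0
        )
        assert groups == (frozenset({"f1"}), frozenset({"f2"}))

    def test_single_family_singleton_group(self):
        groups = congruence_groups({"f1": tree_for("f1")}, l2t(["f1"]), [])
        assert groups == (frozenset({"f1"}),)

    def test_missing_tree_is_error(self):
        with pytest.raises(ValueError, match="no gene tree"):
            congruence_groups({"f1": None}, None, [])


class TestLinkParalogues:
    def _motor_genome(self):
        # two linked motor-cluster copies, aglRQS-style: one at 100-102 and a
        # diverged second cluster at 300-302 in reversed gene order
        tags = [
            ("r1", 100), ("q1", 101), ("s1", 102),
            ("s2", 300), ("q2", 301), ("r2", 302),
        ]
        fams = {"r1": "R", "q1": "Q", "s1": "S", "r2": "R", "q2": "Q", "s2": "S"}
        return make_genome("MX", tags, families=fams)

    def test_two_cluster_copies_give_two_tuples(self):
        genome = self._motor_genome()
        clusters = detect_clusters([l for l in genome.loci], max_gap=3)
        tuples, unassigned = link_paralogues(genome, ["Q", "R", "S"], clusters)
        assert unassigned == ()
        assert {t.copies for t in tuples} == {("q1", "r1", "s1"), ("q2", "r2", "s2")}

    def test_single_copy_genome_one_tuple_without_linkage(self):
        genome = make_genome(
            "G", [("a", 0), ("b", 50)], families={"a": "R", "b": "Q"}
        )
        tuples, unassigned = link_paralogues(genome, ["Q", "R"], ())
        assert len(tuples) == 1 and tuples[0].copies == ("b", "a")
        assert unassigned == ()

    def test_orphan_copy_reported_unassigned(self):
        genome = make_genome("G", [("a", 0)], families={"a": "R"})
        tuples, unassigned = link_paralogues(genome, ["Q", "R"], ())
        assert tuples == () and unassigned == ("a",)


class TestConcatenate:
    def _alignments(self, widths):
        out = {}
        rng = np.random.default_rng(0)
        for fam, w in widths.items():
            rows = {}
            for g in ("G1", "G2", "G3"):
                rows[f"{fam}_{g}"] = "".join(rng.choice(list("ACDE"), size=w))
            out[fam] = AlignmentBlock(tuple(rows), tuple(rows.values()))
        return out

    def _tuples(self, fams):
        return [
            LinkedTuple(g, tuple(f"{f}_{g}" for f in fams)) for g in ("G1", "G2", "G3")
        ]

    def test_positions_sum_and_partitions_tile(self):
        widths = {"fa": 200, "fb": 186, "fc": 200}
        sm = concatenate(self._tuples(sorted(widths)), sorted(widths), self._alignments(widths))
        assert sm.n_sequences == 3 and sm.n_positions == 586
        assert sm.partitions == (("fa", 0, 200), ("fb", 200, 386), ("fc", 386, 586))

    def test_single_family_equals_alignment(self):
        alns = self._alignments({"fa": 50})
        sm = concatenate(self._tuples(["fa"]), ["fa"], alns)
        assert sm.alignment.rows == alns["fa"].rows

    def test_deconcatenation_is_lossless(self):
        widths = {"fa": 30, "fb": 44}
        alns = self._alignments(widths)
        sm = concatenate(self._tuples(["fa", "fb"]), ["fa", "fb"], alns)
        for fam in widths:
            block = sm.family_block(fam)
            for row_id, rt in zip(sm.alignment.row_ids, sm.row_tuples):
                member = dict(zip(["fa", "fb"], rt.copies))[fam]
                assert block.row(row_id) == alns[fam].row(member)

    def test_missing_member_is_error(self):
        alns = self._alignments({"fa": 10})
        bad = [LinkedTuple("G9", ("fa_G9",))]
        with pytest.raises(KeyError):
            concatenate(bad, ["fa"], alns)
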