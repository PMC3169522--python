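"""Local-alignment scoring, family expansion, profiles and classification."""

import itertools

import numpy as np
import pytest

from clustevo.homology import (
    ABSENT,
    GROUP_A,
    GROUP_B,
    ScoringScheme,
    build_profile,
    classify_distribution,
    find_homologues,
    local_align_score,
)
from clustevo.simulate import SimulationConfig, copy_family, simulate_dataset

from .conftest import make_genome
from .oracles import brute_force_local_score

AA = "ACDEFGHIKLMNPQRSTVWY"


class TestLocalAlignScore:
    def test_identical_sequences_normalize_to_one(self):
        raw, norm = local_align_score("MKLVAD", "MKLVAD")
        assert norm == pytest.approx(1.0)

    def test_symmetric(self):
        a, b = "MKWWLV", "KWLVAD"
        assert local_align_score(a, b) == local_align_score(b, a)

    def test_empty_sequence_is_error(self):
        with pytest.raises(ValueError, match="empty"):
            local_align_score("", "MK")

    def test_unknown_residue_is_error(self):
        with pytest.raises(ValueError, match="J"):
            local_align_score("MJK", "MKK")

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_brute_force_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        scheme = ScoringScheme()
        for _ in range(25):
            la, lb = rng.integers(1, 6, size=2)
            a = "".join(rng.choice(list("AWRC"), size=la))
            b = "".join(rng.choice(list("AWRC"), size=lb))
            raw, _ = local_align_score(a, b, scheme)
            assert raw == pytest.approx(brute_force_local_score(a, b))

    def test_unrelated_sequences_score_low(self):
        rng = np.random.default_rng(0)
        low = 0
        n = 200
        for _ in range(n):
            a = "".join(rng.choice(list(AA), size=200))
            b = "".join(rng.choice(list(AA), size=200))
            _, norm = local_align_score(a, b)
            low += norm < 0.3
        assert low / n >= 0.95


class TestFindHomologues:
    def _dataset(self, seed):
        return simulate_dataset(
            SimulationConfig(n_taxa=8, seq_length=400, seed=seed, n_background=6)
        )

    @pytest.mark.parametrize("seed", [1, 5])
    def test_recovers_true_family_exactly(self, seed):
        ds = self._dataset(seed)
        seqs = dict(ds.sequences)
        truth = {}
        for cp in ds.truth.tip_copies:
            truth.setdefault(copy_family(cp), set()).add(cp)
        for fam_id, members in sorted(truth.items()):
            seed_copy = sorted(members)[0]
            fam = find_homologues(fam_id, [seed_copy], seqs, threshold=0.3)
            assert fam.members == frozenset(members)

    def test_threshold_one_with_distinct_sequences(self):
        seqs = {"a": "MKLV" * 10, "b": "WWCH" * 10, "c": "ADEF" * 10}
        fam = find_homologues("f", ["a"], seqs, threshold=1.0)
        assert fam.members == frozenset({"a"})

    def test_monotone_in_threshold(self):
        ds = self._dataset(2)
        seqs = dict(ds.sequences)
        seed_copy = sorted(ds.truth.tip_copies)[0]
        prev = None
        for thr in (0.9, 0.5, 0.2):
            fam = find_homologues("f", [seed_copy], seqs, threshold=thr)
            if prev is not None:
                assert prev <= fam.members
            prev = fam.members

    @pytest.mark.parametrize("seed", range(6))
    def test_no_cross_family_contamination(self, seed):
        ds = self._dataset(seed + 10)
        seqs = dict(ds.sequences)
        for cp in sorted(ds.truth.tip_copies)[:3]:
            fam = find_homologues("f", [cp], seqs, threshold=0.3)
            fams_hit = {copy_family(m) for m in fam.members if "__" in m}
            assert fams_hit == {copy_family(cp)}

    def test_empty_seed_set_is_error(self):
        with pytest.raises(ValueError, match="empty seed"):
            find_homologues("f", [], {"a": "MK"})

    def test_word_filter_preserves_strong_signal_result(self):
        ds = self._dataset(3)
        seqs = dict(ds.sequences)
        seed_copy = sorted(ds.truth.tip_copies)[0]
        exact = find_homologues("f", [seed_copy], seqs, threshold=0.3)
        filtered = find_homologues("f", [seed_copy], seqs, threshold=0.3, word_size=7)
        assert exact.members == filtered.members


class TestProfileAndClassification:
    def test_copy_counts_and_conservation(self):
        from clustevo.homology import HomologyFamily

        g1 = make_genome("G1", [("a1", 0), ("a2", 5)])
        g2 = make_genome("G2", [("b1", 0)])
        fam = HomologyFamily("f", frozenset({"a1"}), frozenset({"a1", "a2", "b1"}))
        prof = build_profile([fam], [g1, g2], {"a1": "G1", "a2": "G1", "b1": "G2"})
        assert prof.loc["f", "G1"] == 2 and prof.loc["f", "G2"] == 1
        assert prof.values.sum() == len(fam.members)

    def test_unknown_genome_is_error(self):
        from clustevo.homology import HomologyFamily

        g1 = make_genome("G1", [("a1", 0)])
        fam = HomologyFamily("f", frozenset({"a1"}), frozenset({"a1"}))
        with pytest.raises(ValueError, match="unknown genome"):
            build_profile([fam], [g1], {"a1": "nope"})

    def test_focal_only_family_is_group_a(self):
        clades = {"m1": ("Delta", "Myxococcales"), "b1": ("Delta", "Bdellovibrionales"), "e1": ("Gamma",)}
        row = {"m1": 2, "b1": 1, "e1": 0}
        assert classify_distribution(row, clades, {"Myxococcales", "Bdellovibrionales"}) == GROUP_A

    def test_broad_family_is_group_b(self):
        clades = {"m1": ("Delta", "Myxococcales"), "e1": ("Gamma",)}
        row = {"m1": 1, "e1": 3}
        assert classify_distribution(row, clades, {"Myxococcales"}) == GROUP_B

    def test_all_zero_row_absent(self):
        assert classify_distribution({"a": 0}, {"a": ("X",)}, {"X"}) == ABSENT
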