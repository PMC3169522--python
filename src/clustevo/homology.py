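"""Homologue detection by iterative local-similarity expansion.

A deterministic, database-size-independent stand-in for iterative protein
similarity search: pairwise similarity is the Smith-Waterman optimal local
alignment score with affine gaps (BLOSUM62 by default), normalized by the
smaller self-score so that identical sequences score 1.0. A family grows by
symmetric single-linkage from its seeds - any proteome sequence whose
normalized score against a current member reaches the threshold joins, and
the newly joined sequences act as fresh seeds - until a fixed point (or
``max_iters``). An optional exact k-mer word prefilter mirrors the word
seeding of heuristic local search tools and is a pure speed device.

Families are summarized as a phyletic profile (family x genome copy-count
matrix) and classified by taxonomic breadth: clade-restricted families
(present only inside the focal clades) versus broadly distributed ones.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

from .core import AMINO_ACIDS, GenomeRecord

log = logging.getLogger("clustevo")


@dataclass(frozen=True)
class ScoringScheme:
    """Affine-gap local alignment parameters (BLOSUM62, -11/-1 by default)."""

    matrix_name: str = "BLOSUM62"
    gap_open: int = -11
    gap_extend: int = -1

    def __post_init__(self) -> None:
        if self.gap_open >= 0 or self.gap_extend >= 0:
            raise ValueError("gap penalties must be negative")

    def aligner(self) -> Align.PairwiseAligner:
        aligner = Align.PairwiseAligner()
        aligner.mode = "local"
        aligner.substitution_matrix = substitution_matrices.load(self.matrix_name)
        aligner.open_gap_score = float(self.gap_open)
        aligner.extend_gap_score = float(self.gap_extend)
        return aligner


def _check_sequence(seq: str, scheme: ScoringScheme) -> None:
    if not seq:
        raise ValueError("empty sequence")
    alphabet = set(str(substitution_matrices.load(scheme.matrix_name).alphabet))
    bad = set(seq) - alphabet
    if bad:
        raise ValueError(f"unknown residue symbol(s): {sorted(bad)}")


def self_score(seq: str, scheme: ScoringScheme) -> float:
    mat = substitution_matrices.load(scheme.matrix_name)
    return float(sum(mat[c, c] for c in seq))


def local_align_score(
    a: str, b: str, scheme: ScoringScheme = ScoringScheme()
) -> tuple[float, float]:
    """(raw Smith-Waterman score, score normalized by the smaller self-score)."""
    _check_sequence(a, scheme)
    _check_sequence(b, scheme)
    raw = float(scheme.aligner().score(a, b))
    norm = raw / min(self_score(a, scheme), self_score(b, scheme))
    return raw, max(norm, 0.0)


class _Scorer:
    """Caches self-scores, k-mer sets and pair scores during family expansion."""

    def __init__(self, sequences: Mapping[str, str], scheme: ScoringScheme, word_size: int):
        self.sequences = dict(sequences)
        self.scheme = scheme
        self.word_size = word_size
        self.aligner = scheme.aligner()
        self._self: dict[str, float] = {}
        self._words: dict[str, frozenset[str]] = {}
        self._pair: dict[tuple[str, str], float] = {}

    def selfscore(self, key: str) -> float:
        if key not in self._self:
            self._self[key] = self_score(self.sequences[key], self.scheme)
        return self._self[key]

    def words(self, key: str) -> frozenset[str]:
        if key not in self._words:
            s = self.sequences[key]
            k = self.word_size
            self._words[key] = frozenset(s[i : i + k] for i in range(len(s) - k + 1))
        return self._words[key]

    def normalized(self, a: str, b: str) -> float:
        key = (a, b) if a <= b else (b, a)
        if key not in self._pair:
            if self.word_size > 0 and self.words(a).isdisjoint(self.words(b)):
                self._pair[key] = 0.0
            else:
                raw = float(self.aligner.score(self.sequences[a], self.sequences[b]))
                self._pair[key] = raw / min(self.selfscore(a), self.selfscore(b))
        return self._pair[key]


@dataclass(frozen=True)
class HomologyFamily:
    family_id: str
    seeds: frozenset[str]
    members: frozenset[str]
    scores: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.seeds <= self.members:
            raise ValueError("seeds must be a subset of members")


def find_homologues(
    family_id: str,
    seeds: Iterable[str],
    proteomes: Mapping[str, str],
    scheme: ScoringScheme = ScoringScheme(),
    threshold: float = 0.3,
    max_iters: int = 10,
    word_size: int = 0,
    scorer: Optional[_Scorer] = None,
) -> HomologyFamily:
    """Grow a family from seed sequence ids by single-linkage expansion.

    ``proteomes`` maps sequence id -> residue sequence (the searchable
    universe). Candidates are processed in sorted id order, so the result is
    independent of input ordering. Lowering ``threshold`` can only enlarge
    the resulting family (monotonicity).
    """
    seeds = frozenset(seeds)
    if not seeds:
        raise ValueError("empty seed set")
    missing = seeds - set(proteomes)
    if missing:
        raise ValueError(f"seed(s) not in proteomes: {sorted(missing)}")
    if not (0.0 < threshold <= 1.0):
        raise ValueError("threshold must be in (0, 1]")
    if max_iters < 1:
        raise ValueError("max_iters must be >= 1")
    sc = scorer or _Scorer(proteomes, scheme, word_size)

    members = set(seeds)
    scores = {s: 1.0 for s in seeds}
    frontier = sorted(seeds)
    for _ in range(max_iters):
        if not frontier:
            break
        added = []
        for cand in sorted(set(proteomes) - members):
            best = max((sc.normalized(cand, m) for m in frontier), default=0.0)
            if best >= threshold:
                added.append(cand)
                scores[cand] = max(best, scores.get(cand, 0.0))
        members.update(added)
        frontier = added
    return HomologyFamily(family_id, seeds, frozenset(members), scores)


def build_profile(
    families: Sequence[HomologyFamily],
    genomes: Sequence[GenomeRecord],
    member_genome: Mapping[str, str],
) -> pd.DataFrame:
    """Family x genome copy-count matrix (phyletic profile).

    ``member_genome`` maps a member sequence id to its genome id; every
    member must resolve to a known genome.
    """
    genome_ids = [g.genome_id for g in genomes]
    counts = pd.DataFrame(
        0, index=[f.family_id for f in families], columns=genome_ids, dtype=int
    )
    for fam in families:
        for member in fam.members:
            if member not in member_genome:
                raise ValueError(f"member {member!r} has no genome assignment")
            g = member_genome[member]
            if g not in counts.columns:
                raise ValueError(f"member {member!r} references unknown genome {g!r}")
            counts.loc[fam.family_id, g] += 1
    return counts


GROUP_A = "GroupA"
GROUP_B = "GroupB"
ABSENT = "absent"


def classify_distribution(
    profile_row: Mapping[str, int],
    clade_paths: Mapping[str, Sequence[str]],
    focal_clades: Iterable[str],
) -> str:
    """Classify a family's taxonomic breadth.

    ``GroupA``: every genome carrying the family lies inside a focal clade
    (clade-restricted, recently emerged). ``GroupB``: at least one carrier
    lies outside all focal clades (broad, ancient). ``absent``: no carriers.
    """
    focal = set(focal_clades)
    if not focal:
        raise ValueError("focal_clades must be non-empty")
    carriers = [g for g, n in profile_row.items() if n >= 1]
    if not carriers:
        return ABSENT
    for g in carriers:
        if not focal & set(clade_paths[g]):
            return GROUP_B
    return GROUP_A
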