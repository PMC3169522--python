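"""Candidate screening for envelope-spanning machinery genes.

Motility-machinery components must cross or decorate the cell envelope, so
the screen keeps every gene whose product is predicted to be exported
(signal peptide or lipoprotein signal), membrane-integral (>= 1 transmembrane
segment), or to carry a protein-protein interaction motif (TPR or
coiled-coil, treated as one boolean since the screen never distinguishes
them). It also merges independent mutant-screen gene lists and flags polar
effects in relative-expression tables.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd

from .core import FeatureTable

#: reason codes, in reporting order
REASONS = ("signal_peptide", "lipoprotein_signal", "transmembrane", "interaction_motif")


@dataclass(frozen=True)
class ScreenResult:
    candidates: frozenset[tuple[str, str]]
    reasons: Mapping[tuple[str, str], tuple[str, ...]]

    def __len__(self) -> int:
        return len(self.candidates)

    def tags(self) -> frozenset[str]:
        return frozenset(t for _, t in self.candidates)


def screen_candidates(
    features: FeatureTable, universe: Iterable[tuple[str, str]]
) -> ScreenResult:
    """Keep each locus satisfying any envelope/interaction clause.

    ``universe`` is the set of (genome_id, locus_tag) pairs under
    consideration (e.g. the merged mutant-screen gene lists); every one must
    be present in the feature table.
    """
    candidates = set()
    reasons: dict[tuple[str, str], tuple[str, ...]] = {}
    for key in sorted(set(universe)):
        genome_id, locus_tag = key
        f = features.get(genome_id, locus_tag)  # raises KeyError naming the locus
        codes = []
        if f.signal_peptide:
            codes.append("signal_peptide")
        if f.lipoprotein_signal:
            codes.append("lipoprotein_signal")
        if f.tm_count >= 1:
            codes.append("transmembrane")
        if f.interaction_motif:
            codes.append("interaction_motif")
        if codes:
            candidates.add(key)
            reasons[key] = tuple(codes)
    return ScreenResult(frozenset(candidates), reasons)


@dataclass(frozen=True)
class MergedLists:
    union: frozenset[str]
    intersection: frozenset[str]
    n_a: int
    n_b: int
    n_intersection: int
    n_union: int


def merge_screen_lists(list_a: Iterable[str], list_b: Iterable[str]) -> MergedLists:
    """Union/intersection bookkeeping for two mutant-screen gene lists.

    Identifiers are normalized (strip + case-fold) before comparison, and
    inclusion-exclusion |A u B| = |A| + |B| - |A n B| holds exactly.
    """
    a = frozenset(x.strip().upper() for x in list_a)
    b = frozenset(x.strip().upper() for x in list_b)
    return MergedLists(
        union=a | b,
        intersection=a & b,
        n_a=len(a),
        n_b=len(b),
        n_intersection=len(a & b),
        n_union=len(a | b),
    )


#: marker for the deleted gene itself in an expression table
ND = "ND"


@dataclass(frozen=True)
class PolarFlag:
    strain: str
    gene: str
    value: float


@dataclass(frozen=True)
class PolarScreenResult:
    flags: tuple[PolarFlag, ...]
    table_max: float


def polar_effect_screen(
    expression: pd.DataFrame, low: float = 0.4, high: float = 2.0
) -> PolarScreenResult:
    """Flag expression fold-changes outside (low, high) in deletion strains.

    ``expression`` has strains as rows and genes as columns; cells hold
    relative expression versus wild type, or the marker ``"ND"`` for the
    deleted gene itself (skipped). Flagging uses strict inequalities, so a
    cell exactly at a bound is accepted.
    """
    if not (0 < low < 1 < high):
        raise ValueError(f"bounds must satisfy 0 < low < 1 < high, got {low}, {high}")
    flags: list[PolarFlag] = []
    table_max = float("-inf")
    for strain, row in expression.iterrows():
        for gene, cell in row.items():
            if isinstance(cell, str) and cell.strip().upper() == ND:
                continue
            value = float(str(cell).replace(",", "."))
            if value <= 0:
                raise ValueError(
                    f"non-positive expression value {value} at ({strain}, {gene})"
                )
            table_max = max(table_max, value)
            if value < low or value > high:
                flags.append(PolarFlag(str(strain), str(gene), value))
    return PolarScreenResult(tuple(flags), table_max)
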