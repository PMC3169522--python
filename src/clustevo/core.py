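"""Shared domain types for the cluster-evolution pipeline.

The pipeline reasons about bacterial genomes as *ordered sequences of gene
loci* (ordinal chromosome coordinates, not base pairs), about per-locus
envelope/interaction features as produced by external annotation tools, and
about protein alignments over the standard 20-letter amino-acid alphabet.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
GAP = "-"
UNKNOWN = "X"

#: integer codes: 0..19 residues, 20 = gap/unknown sentinel
_CODE = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
_CODE[GAP] = 20
_CODE[UNKNOWN] = 20
MISSING_CODE = 20


def encode_sequence(seq: str) -> np.ndarray:
    """Encode a residue string as uint8 codes (gap/unknown -> 20)."""
    try:
        return np.fromiter((_CODE[c] for c in seq.upper()), dtype=np.uint8, count=len(seq))
    except KeyError as exc:  # pragma: no cover - message detail
        raise ValueError(f"unknown residue symbol {exc.args[0]!r}") from None


@dataclass(frozen=True, order=True)
class GeneLocus:
    """One gene on one chromosome, addressed by 0-based ordinal position."""

    genome_id: str
    locus_tag: str
    ordinal_index: int
    strand: str = "?"
    family_id: Optional[str] = None
    product: Optional[str] = None

    def __post_init__(self) -> None:
        if self.ordinal_index < 0:
            raise ValueError(f"ordinal_index must be >= 0, got {self.ordinal_index}")
        if self.strand not in {"+", "-", "?"}:
            raise ValueError(f"strand must be one of '+', '-', '?', got {self.strand!r}")


@dataclass(frozen=True)
class GenomeRecord:
    """An ordered gene complement for one genome, with its taxonomic path.

    ``clade_path`` lists clade labels from the root down (e.g.
    ``("Deltaproteobacteria", "Myxococcales")``); clade membership throughout
    the pipeline is tested by simple label containment, no taxonomy database
    is consulted.
    """

    genome_id: str
    taxon_name: str
    clade_path: tuple[str, ...]
    loci: tuple[GeneLocus, ...]

    def __post_init__(self) -> None:
        if not self.clade_path:
            raise ValueError(f"{self.genome_id}: clade_path must be non-empty")
        idx = [l.ordinal_index for l in self.loci]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise ValueError(f"{self.genome_id}: loci must be strictly sorted by ordinal_index")
        tags = [l.locus_tag for l in self.loci]
        if len(set(tags)) != len(tags):
            dup = sorted({t for t in tags if tags.count(t) > 1})
            raise ValueError(f"{self.genome_id}: duplicate locus_tag(s) {dup}")
        for l in self.loci:
            if l.genome_id != self.genome_id:
                raise ValueError(
                    f"locus {l.locus_tag} belongs to {l.genome_id}, not {self.genome_id}"
                )

    def locus(self, locus_tag: str) -> GeneLocus:
        for l in self.loci:
            if l.locus_tag == locus_tag:
                return l
        raise KeyError(f"{self.genome_id}: no locus {locus_tag!r}")

    def in_span(self, start: int, end: int) -> tuple[GeneLocus, ...]:
        """Loci with ordinal_index in the half-open range [start, end)."""
        return tuple(l for l in self.loci if start <= l.ordinal_index < end)


@dataclass(frozen=True)
class LocusFeatures:
    """Envelope/interaction features for one locus (annotation-tool output)."""

    signal_peptide: bool = False
    lipoprotein_signal: bool = False
    tm_count: int = 0
    interaction_motif: bool = False
    domain_names: frozenset[str] = frozenset()
    length_aa: int = 1

    def __post_init__(self) -> None:
        if self.tm_count < 0:
            raise ValueError("tm_count must be >= 0")
        if self.length_aa < 1:
            raise ValueError("length_aa must be >= 1")


class FeatureTable:
    """Per-locus feature map keyed by (genome_id, locus_tag)."""

    def __init__(self, features: Mapping[tuple[str, str], LocusFeatures] | None = None):
        self._features: dict[tuple[str, str], LocusFeatures] = dict(features or {})

    def __len__(self) -> int:
        return len(self._features)

    def __contains__(self, key: tuple[str, str]) -> bool:
        return key in self._features

    def __iter__(self):
        return iter(self._features.items())

    def get(self, genome_id: str, locus_tag: str) -> LocusFeatures:
        key = (genome_id, locus_tag)
        if key not in self._features:
            raise KeyError(f"no features for locus {locus_tag!r} in genome {genome_id!r}")
        return self._features[key]

    def set(self, genome_id: str, locus_tag: str, feats: LocusFeatures) -> None:
        self._features[(genome_id, locus_tag)] = feats

    def validate_against(self, genomes: Iterable[GenomeRecord]) -> None:
        known = {(g.genome_id, l.locus_tag) for g in genomes for l in g.loci}
        orphans = sorted(set(self._features) - known)
        if orphans:
            raise ValueError(f"feature table references unknown loci: {orphans[:5]}")


@dataclass(frozen=True)
class AlignmentBlock:
    """A gap-aware residue alignment: equal-length rows over AA + gap/unknown."""

    row_ids: tuple[str, ...]
    rows: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.row_ids) != len(self.rows):
            raise ValueError("row_ids and rows must have equal length")
        if len(set(self.row_ids)) != len(self.row_ids):
            raise ValueError("row_ids must be unique")
        if self.rows:
            n = len(self.rows[0])
            if any(len(r) != n for r in self.rows):
                raise ValueError("all alignment rows must have equal length")

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @property
    def n_positions(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def to_codes(self) -> np.ndarray:
        """uint8 matrix (n_rows, n_positions); 20 marks gap/unknown."""
        if not self.rows:
            return np.zeros((0, 0), dtype=np.uint8)
        return np.vstack([encode_sequence(r) for r in self.rows])

    def row(self, row_id: str) -> str:
        try:
            return self.rows[self.row_ids.index(row_id)]
        except ValueError:
            raise KeyError(f"no alignment row {row_id!r}") from None

    def select_rows(self, row_ids: Sequence[str]) -> "AlignmentBlock":
        return AlignmentBlock(tuple(row_ids), tuple(self.row(r) for r in row_ids))

    def select_columns(self, keep: Sequence[int]) -> "AlignmentBlock":
        keep = list(keep)
        return AlignmentBlock(
            self.row_ids, tuple("".join(r[j] for j in keep) for r in self.rows)
        )


@dataclass(frozen=True)
class PipelineConfig:
    """Free parameters of the pipeline, with desk-scale defaults.

    max_gap
        Maximum number of intervening (non-hit) loci tolerated between two
        candidate hits that still count as chromosomally clustered.
    sim_score_threshold
        Normalized local-alignment score (raw / min self-score) above which a
        sequence joins a homologue family.
    word_size
        Exact k-mer prefilter for homologue search (0 disables); a pair is
        aligned only if it shares at least one length-k word, mirroring
        word-seeded local search heuristics.
    distance_model
        'p' (raw mismatch fraction), 'poisson' (20-state multiple-hit
        correction matching the simulator) or 'gamma' (rate-heterogeneous
        variant with shape gamma_alpha).
    support_min
        Bootstrap percentage an edge needs before it can witness a taxon
        displacement (HGT signal).
    merge_rules / discard
        Data-driven pseudogene handling for cluster extension: locus-tag
        groups fused into one putative gene, and locus tags dropped outright.
    """

    max_gap: int = 3
    sim_score_threshold: float = 0.3
    max_iters: int = 10
    word_size: int = 0
    distance_model: str = "poisson"
    gamma_alpha: float = 1.0
    distance_cap: float = 10.0
    mask_max_missing: float = 0.5
    n_bootstrap: int = 100
    support_min: float = 70.0
    rf_congruence_max: int = 2
    min_shared_taxa: int = 4
    focal_clades: frozenset[str] = frozenset()
    random_seed: int = 0
    merge_rules: tuple[tuple[str, ...], ...] = ()
    discard: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.max_gap < 0:
            raise ValueError("max_gap must be >= 0")
        if not (0.0 < self.sim_score_threshold <= 1.0):
            raise ValueError("sim_score_threshold must be in (0, 1]")
        if self.max_iters < 1:
            raise ValueError("max_iters must be >= 1")
        if self.distance_model not in {"p", "poisson", "gamma"}:
            raise ValueError(f"unknown distance_model {self.distance_model!r}")
        if self.gamma_alpha <= 0:
            raise ValueError("gamma_alpha must be > 0")
        if not (0.0 <= self.mask_max_missing <= 1.0):
            raise ValueError("mask_max_missing must be in [0, 1]")
        if self.n_bootstrap < 1:
            raise ValueError("n_bootstrap must be >= 1")
        if not (0.0 <= self.support_min <= 101.0):
            raise ValueError("support_min must be a percentage")

    def with_(self, **kwargs) -> "PipelineConfig":
        return replace(self, **kwargs)
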