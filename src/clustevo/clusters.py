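"""Chromosomal clustering of candidate genes by ordinal adjacency.

Two candidate hits are chromosomal neighbours when at most ``max_gap``
non-hit loci intervene between them; clusters are the connected components of
that neighbour relation. A detected cluster can then be *extended* to the
full contiguous gene run between its extreme hits, with data-driven
pseudogene handling (fusing locus pairs into one putative gene, or dropping
listed tags).

Chromosomes are treated as linear; ordinal indices, not base-pair
coordinates, define adjacency.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .core import GeneLocus, GenomeRecord


@dataclass(frozen=True)
class GenomicCluster:
    """A run of loci on one chromosome; ``hits`` marks the screened members."""

    genome_id: str
    members: tuple[GeneLocus, ...]
    hit_tags: frozenset[str]

    def __post_init__(self) -> None:
        idx = [l.ordinal_index for l in self.members]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise ValueError("cluster members must be sorted by ordinal_index")

    @property
    def span(self) -> tuple[int, int]:
        """Half-open [min_index, max_index + 1) ordinal range."""
        return (self.members[0].ordinal_index, self.members[-1].ordinal_index + 1)

    @property
    def n_hits(self) -> int:
        return sum(1 for l in self.members if l.locus_tag in self.hit_tags)

    @property
    def n_members(self) -> int:
        return len(self.members)

    def member_tags(self) -> tuple[str, ...]:
        return tuple(l.locus_tag for l in self.members)


def detect_clusters(hits: Iterable[GeneLocus], max_gap: int) -> tuple[GenomicCluster, ...]:
    """Partition hits of one genome into adjacency clusters.

    Consecutive hits (by ordinal index) with at most ``max_gap`` intervening
    loci chain into the same cluster; singletons are clusters of size one.
    Because the neighbour graph is an interval graph on a line, chaining
    sorted neighbours yields exactly the connected components.
    """
    hits = sorted(set(hits), key=lambda l: l.ordinal_index)
    if not hits:
        return ()
    if max_gap < 0:
        raise ValueError("max_gap must be >= 0")
    genomes = {l.genome_id for l in hits}
    if len(genomes) > 1:
        raise ValueError(f"hits span multiple genomes: {sorted(genomes)}")
    clusters: list[list[GeneLocus]] = [[hits[0]]]
    for prev, cur in zip(hits, hits[1:]):
        if cur.ordinal_index - prev.ordinal_index - 1 <= max_gap:
            clusters[-1].append(cur)
        else:
            clusters.append([cur])
    return tuple(
        GenomicCluster(
            genome_id=members[0].genome_id,
            members=tuple(members),
            hit_tags=frozenset(l.locus_tag for l in members),
        )
        for members in clusters
    )


def extend_cluster(
    cluster: GenomicCluster,
    genome: GenomeRecord,
    merge_rules: Sequence[Sequence[str]] = (),
    discard: Sequence[str] = (),
) -> GenomicCluster:
    """Extend a cluster to every locus between its extreme hits, then apply
    pseudogene rules.

    ``merge_rules`` lists locus-tag groups fused into one putative gene (the
    fused unit keeps the first tag and counts once); ``discard`` lists tags
    dropped outright. Rules naming loci outside the extended span are errors.
    Extension is idempotent: re-extending an extended cluster is a no-op.
    """
    for tag in cluster.member_tags():
        genome.locus(tag)  # raises if absent
    start, end = cluster.span
    members = list(genome.in_span(start, end))
    member_tags = {l.locus_tag for l in members}

    applied: list[GeneLocus] = []
    merged_away: set[str] = set()
    merged_repr: dict[str, tuple[str, ...]] = {}
    for rule in merge_rules:
        rule = tuple(rule)
        inside = [t for t in rule if t in member_tags]
        if inside and len(inside) != len(rule):
            missing = [t for t in rule if t not in member_tags]
            raise ValueError(f"merge rule {rule} references loci outside the span: {missing}")
        if inside:
            merged_repr[rule[0]] = rule
            merged_away.update(rule[1:])
    merged_away.update(t for t in discard if t in member_tags)
    for locus in members:
        if locus.locus_tag not in merged_away:
            applied.append(locus)
    return GenomicCluster(
        genome_id=cluster.genome_id,
        members=tuple(applied),
        hit_tags=cluster.hit_tags,
    )


def clusters_for_genome(
    genome: GenomeRecord, hit_tags: Iterable[str], max_gap: int
) -> tuple[GenomicCluster, ...]:
    """Detect clusters among the loci of ``genome`` named by ``hit_tags``."""
    tags = set(hit_tags)
    hits = [l for l in genome.loci if l.locus_tag in tags]
    return detect_clusters(hits, max_gap)
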