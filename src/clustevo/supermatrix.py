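"""Supermatrix construction with synteny-resolved paralogue assignment.

Families are concatenated only when they plausibly share one evolutionary
history: they must co-occur in a detected chromosomal cluster in at least
one genome *and* their gene trees must agree (small Robinson-Foulds
distance) on a sufficient set of shared single-copy taxa. When a genome
carries several copies of the group's families, copies residing in the same
genomic cluster are combined into one supermatrix row (physical linkage
resolves paralogy); genomes lacking a complete linked set contribute no row.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import dendropy

from .core import AlignmentBlock
from .clusters import GenomicCluster
from .core import GenomeRecord
from .phylo import SupportedTree, robinson_foulds

log = logging.getLogger("clustevo")


def _as_tree(t) -> dendropy.Tree:
    return t.tree if isinstance(t, SupportedTree) else t


def restrict_and_relabel(
    tree: dendropy.Tree, keep: Mapping[str, str]
) -> dendropy.Tree:
    """Copy of ``tree`` keeping only leaves in ``keep``, relabeled by it."""
    clone = tree.extract_tree_with_taxa_labels(list(keep))
    ns = dendropy.TaxonNamespace(sorted(set(keep.values())))
    for leaf in clone.leaf_node_iter():
        leaf.taxon = ns.get_taxon(keep[leaf.taxon.label])
    clone.taxon_namespace = ns
    return clone


def congruence_groups(
    gene_trees: Mapping[str, SupportedTree | dendropy.Tree],
    leaf_to_taxon: Mapping[str, dict[str, str]] | None,
    colocated: Iterable[frozenset[str]],
    rf_max: int = 2,
    min_shared_taxa: int = 4,
) -> tuple[frozenset[str], ...]:
    """Partition families into shared-history groups (transitive closure).

    ``leaf_to_taxon`` maps family -> {gene-tree leaf -> taxon}; ``colocated``
    lists family pairs/sets observed together in a chromosomal cluster.
    Two families join when co-located and congruent on their shared
    single-copy taxa; groups are connected components of that relation.
    """
    families = sorted(gene_trees)
    for fam in families:
        if gene_trees[fam] is None:
            raise ValueError(f"family {fam!r} has no gene tree")
    pair_colocated = set()
    for group in colocated:
        for a in group:
            for b in group:
                if a < b:
                    pair_colocated.add((a, b))

    def taxon_map(fam: str) -> dict[str, str]:
        tree = _as_tree(gene_trees[fam])
        leaves = [lf.taxon.label for lf in tree.leaf_node_iter()]
        if leaf_to_taxon is None:
            return {l: l for l in leaves}
        return {l: leaf_to_taxon[fam][l] for l in leaves}

    def congruent(a: str, b: str) -> bool:
        ma, mb = taxon_map(a), taxon_map(b)

        def single_copy(m: dict[str, str]) -> dict[str, str]:
            counts: dict[str, int] = {}
            for t in m.values():
                counts[t] = counts.get(t, 0) + 1
            return {l: t for l, t in m.items() if counts[t] == 1}

        sa, sb = single_copy(ma), single_copy(mb)
        shared = sorted(set(sa.values()) & set(sb.values()))
        if len(shared) < min_shared_taxa:
            return False
        ka = {l: t for l, t in sa.items() if t in shared}
        kb = {l: t for l, t in sb.items() if t in shared}
        ta = restrict_and_relabel(_as_tree(gene_trees[a]), ka)
        tb = restrict_and_relabel(_as_tree(gene_trees[b]), kb)
        return robinson_foulds(ta, tb) <= rf_max

    parent = {f: f for f in families}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a, b in sorted(pair_colocated):
        if a in parent and b in parent and congruent(a, b):
            parent[find(a)] = find(b)
    groups: dict[str, set[str]] = {}
    for f in families:
        groups.setdefault(find(f), set()).add(f)
    return tuple(sorted((frozenset(g) for g in groups.values()), key=sorted))


@dataclass(frozen=True)
class LinkedTuple:
    """One supermatrix row precursor: one copy per family, physically linked."""

    genome_id: str
    copies: tuple[str, ...]  # locus tags / copy ids, in group family order


def link_paralogues(
    genome: GenomeRecord,
    group_families: Sequence[str],
    clusters: Sequence[GenomicCluster],
) -> tuple[tuple[LinkedTuple, ...], tuple[str, ...]]:
    """Combine a genome's copies of the group families into linked tuples.

    A genome with exactly one copy of every family yields one tuple
    directly. Multi-copy genomes are resolved by chromosomal linkage: each
    detected cluster containing exactly one copy of every family becomes a
    tuple; copies not in any complete cluster are reported unassigned.
    """
    fams = list(group_families)
    by_family: dict[str, list[str]] = {f: [] for f in fams}
    for locus in genome.loci:
        if locus.family_id in by_family:
            by_family[locus.family_id].append(locus.locus_tag)
    counts = {f: len(v) for f, v in by_family.items()}
    all_copies = [tag for f in fams for tag in by_family[f]]
    if any(c == 0 for c in counts.values()):
        return (), tuple(sorted(all_copies))
    if all(c == 1 for c in counts.values()):
        return (LinkedTuple(genome.genome_id, tuple(by_family[f][0] for f in fams)),), ()

    tuples: list[LinkedTuple] = []
    assigned: set[str] = set()
    for cluster in clusters:
        members = {l.locus_tag: l.family_id for l in cluster.members}
        picks = {}
        for f in fams:
            here = [t for t, fam in members.items() if fam == f and t not in assigned]
            if len(here) == 1:
                picks[f] = here[0]
        if len(picks) == len(fams):
            chosen = tuple(picks[f] for f in fams)
            if assigned & set(chosen):
                raise RuntimeError("copy assigned to two tuples")  # must be impossible
            tuples.append(LinkedTuple(genome.genome_id, chosen))
            assigned.update(chosen)
    unassigned = tuple(sorted(set(all_copies) - assigned))
    return tuple(tuples), unassigned


@dataclass(frozen=True)
class Supermatrix:
    """Concatenated multi-family alignment with partition bookkeeping."""

    alignment: AlignmentBlock
    partitions: tuple[tuple[str, int, int], ...]  # (family, start, end) half-open
    row_tuples: tuple[LinkedTuple, ...]

    def __post_init__(self) -> None:
        pos = 0
        for fam, start, end in self.partitions:
            if start != pos or end < start:
                raise ValueError("partitions must tile [0, n_positions) in order")
            pos = end
        if self.alignment.rows and pos != self.alignment.n_positions:
            raise ValueError("partitions do not cover the alignment")
        if len(self.row_tuples) != self.alignment.n_rows:
            raise ValueError("one row per linked tuple required")

    @property
    def n_sequences(self) -> int:
        return self.alignment.n_rows

    @property
    def n_positions(self) -> int:
        return self.alignment.n_positions

    def family_block(self, family_id: str) -> AlignmentBlock:
        """De-concatenate one family's partition (lossless bookkeeping)."""
        for fam, start, end in self.partitions:
            if fam == family_id:
                return AlignmentBlock(
                    self.alignment.row_ids,
                    tuple(r[start:end] for r in self.alignment.rows),
                )
        raise KeyError(f"no partition for family {family_id!r}")

    def row_genome(self, row_id: str) -> str:
        for rt, rid in zip(self.row_tuples, self.alignment.row_ids):
            if rid == row_id:
                return rt.genome_id
        raise KeyError(row_id)


def concatenate(
    tuples: Sequence[LinkedTuple],
    family_order: Sequence[str],
    family_alignments: Mapping[str, AlignmentBlock],
) -> Supermatrix:
    """Concatenate per-family alignment rows along each linked tuple."""
    fams = list(family_order)
    widths = {}
    for f in fams:
        aln = family_alignments[f]
        widths[f] = aln.n_positions
    row_ids = []
    rows = []
    seen: dict[str, int] = {}
    for lt in tuples:
        if len(lt.copies) != len(fams):
            raise ValueError(f"tuple {lt} does not match family order {fams}")
        k = seen.get(lt.genome_id, 0)
        seen[lt.genome_id] = k + 1
        row_id = lt.genome_id if k == 0 else f"{lt.genome_id}.{k + 1}"
        parts = []
        for f, copy in zip(fams, lt.copies):
            row = family_alignments[f].row(copy)  # KeyError if absent
            if len(row) != widths[f]:
                raise ValueError(f"inconsistent alignment width for family {f!r}")
            parts.append(row)
        row_ids.append(row_id)
        rows.append("".join(parts))
    partitions = []
    pos = 0
    for f in fams:
        partitions.append((f, pos, pos + widths[f]))
        pos += widths[f]
    return Supermatrix(
        AlignmentBlock(tuple(row_ids), tuple(rows)),
        tuple(partitions),
        tuple(tuples),
    )


def write_phylip(sm: Supermatrix, path) -> None:
    """Relaxed PHYLIP with a sidecar partitions table."""
    from pathlib import Path

    lines = [f" {sm.n_sequences} {sm.n_positions}"]
    for rid, row in zip(sm.alignment.row_ids, sm.alignment.rows):
        lines.append(f"{rid}  {row}")
    Path(path).write_text("\n".join(lines) + "\n")
    part_path = Path(path).with_suffix(".partitions.tsv")
    plines = ["family\tstart\tend"]
    for fam, start, end in sm.partitions:
        plines.append(f"{fam}\t{start}\t{end}")
    part_path.write_text("\n".join(plines) + "\n")
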