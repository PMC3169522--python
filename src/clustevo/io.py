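"""Readers and writers for the plain-text formats the pipeline exchanges.

FASTA (protein), newick (trees; bootstrap support as internal node labels),
and tab-separated gene/feature/profile tables with fixed documented headers.
All readers are inverses of the corresponding writers on valid data, and no
reader silently drops records.
"""

from __future__ import annotations

import logging
import sys
from pathlib import Path
from typing import Iterable, Mapping

import dendropy
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .core import FeatureTable, GeneLocus, GenomeRecord, LocusFeatures, PipelineConfig

log = logging.getLogger("clustevo")

GENE_TABLE_COLUMNS = ["genome_id", "locus_tag", "ordinal_index", "strand", "clade_path"]
FEATURE_TABLE_COLUMNS = [
    "genome_id",
    "locus_tag",
    "signal_peptide",
    "lipoprotein_signal",
    "tm_count",
    "interaction_motif",
    "domain_names",
    "length_aa",
]


def configure_logging(quiet: bool = False) -> None:
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    log.handlers[:] = [handler]
    log.setLevel(logging.ERROR if quiet else logging.INFO)


# ---------------------------------------------------------------- FASTA


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a protein FASTA into an ordered id -> uppercase sequence map."""
    path = Path(path)
    records: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise ValueError(f"{path}: duplicate FASTA identifier {rec.id!r}")
        records[rec.id] = str(rec.seq).upper()
    if not records:
        raise ValueError(f"{path}: empty FASTA file")
    return records


def write_fasta(records: Mapping[str, str], path: str | Path) -> None:
    seqs = [SeqRecord(Seq(s), id=name, description="") for name, s in records.items()]
    SeqIO.write(seqs, str(path), "fasta")


# ---------------------------------------------------------------- newick


def read_newick(path_or_text: str | Path) -> dendropy.Tree:
    """Read a newick tree; absent branch lengths default to 1.0.

    Rootedness is taken from the ``[&R]``/``[&U]`` hint when present and
    recorded on the returned tree. Internal node labels (e.g. bootstrap
    supports) are preserved as node labels.
    """
    text = str(path_or_text)
    if not text.lstrip().startswith("(") and Path(text).exists():
        text = Path(text).read_text()
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:
        raise ValueError(f"newick parse error: {exc}") from exc
    for edge in tree.preorder_edge_iter():
        if edge.head_node is not tree.seed_node and edge.length is None:
            edge.length = 1.0
    return tree


def write_newick(tree: dendropy.Tree, path: str | Path | None = None) -> str:
    text = tree.as_string(schema="newick", suppress_rooting=False, unquoted_underscores=True)
    if path is not None:
        Path(path).write_text(text)
    return text


# ---------------------------------------------------------------- gene table


def _records_from_rows(rows: list[tuple[str, str, int, str, str]]) -> tuple[GenomeRecord, ...]:
    by_genome: dict[str, list[tuple[int, GeneLocus, str]]] = {}
    for genome_id, locus_tag, idx, strand, clade in rows:
        locus = GeneLocus(genome_id, locus_tag, idx, strand)
        by_genome.setdefault(genome_id, []).append((idx, locus, clade))
    records = []
    for genome_id in sorted(by_genome):
        entries = by_genome[genome_id]
        seen: dict[int, str] = {}
        for idx, locus, _ in entries:
            if idx in seen:
                raise ValueError(
                    f"{genome_id}: duplicate ordinal_index {idx} "
                    f"({seen[idx]!r} vs {locus.locus_tag!r})"
                )
            seen[idx] = locus.locus_tag
        entries.sort(key=lambda e: e[0])
        clade_path = tuple(entries[0][2].split("/"))
        records.append(
            GenomeRecord(
                genome_id=genome_id,
                taxon_name=genome_id,
                clade_path=clade_path,
                loci=tuple(e[1] for e in entries),
            )
        )
    return tuple(records)


def read_gene_table(path: str | Path) -> tuple[GenomeRecord, ...]:
    """Read a TSV of genome_id / locus_tag / ordinal_index / strand / clade_path."""
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines:
        raise ValueError(f"{path}: empty gene table")
    header = lines[0].rstrip("\n").split("\t")
    if header != GENE_TABLE_COLUMNS:
        raise ValueError(f"{path}: expected header {GENE_TABLE_COLUMNS}, got {header}")
    rows = []
    for ln, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != 5:
            raise ValueError(f"{path}:{ln}: expected 5 columns, got {len(parts)}")
        genome_id, locus_tag, idx_s, strand, clade = parts
        try:
            idx = int(idx_s)
        except ValueError:
            raise ValueError(f"{path}:{ln}: non-integer ordinal_index {idx_s!r}") from None
        rows.append((genome_id, locus_tag, idx, strand, clade))
    return _records_from_rows(rows)


def write_gene_table(genomes: Iterable[GenomeRecord], path: str | Path) -> None:
    lines = ["\t".join(GENE_TABLE_COLUMNS)]
    for g in genomes:
        clade = "/".join(g.clade_path)
        for l in g.loci:
            lines.append(f"{g.genome_id}\t{l.locus_tag}\t{l.ordinal_index}\t{l.strand}\t{clade}")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------- feature table


def read_feature_table(path: str | Path) -> FeatureTable:
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines or lines[0].split("\t") != FEATURE_TABLE_COLUMNS:
        raise ValueError(f"{path}: expected header {FEATURE_TABLE_COLUMNS}")
    table = FeatureTable()
    for ln, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        p = line.split("\t")
        if len(p) != len(FEATURE_TABLE_COLUMNS):
            raise ValueError(f"{path}:{ln}: malformed row")
        domains = frozenset(d for d in p[6].split(";") if d)
        table.set(
            p[0],
            p[1],
            LocusFeatures(
                signal_peptide=p[2] == "1",
                lipoprotein_signal=p[3] == "1",
                tm_count=int(p[4]),
                interaction_motif=p[5] == "1",
                domain_names=domains,
                length_aa=int(p[7]),
            ),
        )
    return table


def write_feature_table(table: FeatureTable, path: str | Path) -> None:
    lines = ["\t".join(FEATURE_TABLE_COLUMNS)]
    for (genome_id, locus_tag), f in sorted(table):
        lines.append(
            "\t".join(
                [
                    genome_id,
                    locus_tag,
                    "1" if f.signal_peptide else "0",
                    "1" if f.lipoprotein_signal else "0",
                    str(f.tm_count),
                    "1" if f.interaction_motif else "0",
                    ";".join(sorted(f.domain_names)),
                    str(f.length_aa),
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------- config


def read_config(path: str | Path) -> PipelineConfig:
    data = yaml.safe_load(Path(path).read_text()) or {}
    if "focal_clades" in data:
        data["focal_clades"] = frozenset(data["focal_clades"])
    if "merge_rules" in data:
        data["merge_rules"] = tuple(tuple(rule) for rule in data["merge_rules"])
    if "discard" in data:
        data["discard"] = tuple(data["discard"])
    return PipelineConfig(**data)


def write_config(config: PipelineConfig, path: str | Path) -> None:
    data = {
        k: (sorted(v) if isinstance(v, frozenset) else list(map(list, v)) if k == "merge_rules" else list(v) if isinstance(v, tuple) else v)
        for k, v in vars(config).items()
    }
    Path(path).write_text(yaml.safe_dump(data, sort_keys=True))


def locus_order_from_tags(tags: Iterable[str]) -> dict[str, int]:
    """Derive ordinal indices from the numeric suffix rank of locus tags.

    Fallback for real-mode inputs lacking explicit coordinates: tags such as
    MXAN_4862 sort by their trailing integer, which encodes chromosomal order
    in most bacterial locus-tag schemes.
    """

    def suffix(tag: str) -> int:
        digits = ""
        for ch in reversed(tag):
            if ch.isdigit():
                digits = ch + digits
            else:
                break
        if not digits:
            raise ValueError(f"locus tag {tag!r} has no numeric suffix")
        return int(digits)

    ordered = sorted(set(tags), key=lambda t: (suffix(t), t))
    return {tag: i for i, tag in enumerate(ordered)}
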