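"""End-to-end orchestration: screen -> cluster -> homology -> trees ->
supermatrix -> scenario, in synthetic (simulator-backed, with recovery
scoring) or real (user-supplied inputs) mode, plus the curated
worked-example analysis of the M. xanthus gliding-machinery system.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import dendropy
import numpy as np
import pandas as pd

from . import datasets
from .clusters import GenomicCluster, clusters_for_genome, detect_clusters, extend_cluster
from .core import AlignmentBlock, FeatureTable, GenomeRecord, PipelineConfig
from .homology import (
    GROUP_A,
    GROUP_B,
    HomologyFamily,
    ScoringScheme,
    _Scorer,
    build_profile,
    classify_distribution,
    find_homologues,
)
from .io import read_newick, write_newick
from .phylo import (
    SupportedTree,
    bootstrap_support,
    clade_partition,
    displacement_test,
    label_internal_nodes,
    mask_columns,
)
from .scenario import FamilyScenario, RecoveryMetrics, assemble_scenario, score_events
from .screen import merge_screen_lists, polar_effect_screen, screen_candidates
from .simulate import (
    FAMILY_SEP,
    SimulatedDataset,
    SimulationConfig,
    copy_family,
    simulate_dataset,
)
from .supermatrix import Supermatrix, concatenate, congruence_groups, link_paralogues

log = logging.getLogger("clustevo")


# ---------------------------------------------------------------- curated worked example


def analyze_curated(
    low: float = 0.4, high: float = 2.0, max_gap: int = 3
) -> dict:
    """Recompute the worked-example numbers of the gliding-machinery system.

    Runs the feature screen over the merged mutant-screen lists, detects and
    extends the chromosomal clusters (with the pseudogene merge rule),
    classifies the 14 machinery families by taxonomic breadth, places their
    origins by Dollo parsimony on the representative species tree, and
    screens the expression tables for polar effects. Every number is
    computed, not quoted.
    """
    from .scenario import dollo_reconstruct

    genome = datasets.gliding_gene_table()
    features = datasets.gliding_feature_table()
    list_a, list_b = datasets.transposon_screen_lists()
    merged = merge_screen_lists(list_a, list_b)
    universe = {(datasets.GENOME_ID, tag) for tag in merged.union}
    screen = screen_candidates(features, universe)
    hit_tags = screen.tags()
    clusters = clusters_for_genome(genome, hit_tags, max_gap)
    multi = [c for c in clusters if c.n_hits >= 2]
    extended = [
        extend_cluster(c, genome, merge_rules=datasets.MERGE_RULES) for c in multi
    ]
    tolpal = [c for c in extended if set(c.member_tags()) & set(datasets.TOLPAL_TAGS)]
    machinery = [c for c in extended if c not in tolpal]
    per_cluster = {}
    for c in machinery:
        if "MXAN_4870" in c.member_tags():
            per_cluster["G1"] = c
        elif "MXAN_2541" in c.member_tags():
            per_cluster["G2"] = c
        elif "MXAN_6862" in c.member_tags():
            per_cluster["M1"] = c

    profile = datasets.taxonomic_profile()
    tree = read_newick(datasets.SPECIES_NEWICK)
    labels = {}
    origins = {}
    for fam in profile.index:
        row = profile.loc[fam].to_dict()
        labels[fam] = classify_distribution(
            row, datasets.TAXA_CLADES, datasets.FOCAL_CLADES
        )
        origin, losses = dollo_reconstruct(row, tree)
        origins[fam] = {"origin": origin, "n_losses": len(losses)}

    t2, t3 = datasets.expression_tables()
    polar2 = polar_effect_screen(t2, low, high)
    polar3 = polar_effect_screen(t3, low, high)

    return {
        "n_screen_input": merged.n_union,
        "n_list_a": merged.n_a,
        "n_list_b": merged.n_b,
        "n_overlap": merged.n_intersection,
        "n_candidates": len(screen),
        "n_clusters_multi": len(multi),
        "n_clustered_candidates": sum(c.n_hits for c in multi),
        "cluster_gene_counts": {k: c.n_members for k, c in sorted(per_cluster.items())},
        "n_machinery_genes": sum(c.n_members for c in machinery),
        "n_machinery_hits": sum(c.n_hits for c in machinery),
        "n_group_a": sum(1 for v in labels.values() if v == GROUP_A),
        "n_group_b": sum(1 for v in labels.values() if v == GROUP_B),
        "group_labels": labels,
        "origins": origins,
        "polar_flags": [
            (f.strain, f.gene, f.value) for f in polar2.flags + polar3.flags
        ],
        "polar_table_max": max(polar2.table_max, polar3.table_max),
    }


# ---------------------------------------------------------------- synthetic / real


@dataclass
class PipelineResult:
    config: PipelineConfig
    genomes: tuple[GenomeRecord, ...]
    candidates: frozenset[tuple[str, str]]
    candidate_clusters: dict[str, tuple[GenomicCluster, ...]]
    families: tuple[HomologyFamily, ...]
    profile: pd.DataFrame
    group_labels: dict[str, str]
    family_trees: dict[str, SupportedTree]
    displacement: dict[str, tuple]
    groups: tuple[frozenset[str], ...]
    supermatrices: dict[str, Supermatrix]
    supermatrix_trees: dict[str, SupportedTree]
    scenarios: tuple[FamilyScenario, ...]
    metrics: Optional[RecoveryMetrics]
    family_membership: Optional[dict]
    dataset: Optional[SimulatedDataset]
    report: dict = field(default_factory=dict)


def _seed_for(base: int, *key: int) -> int:
    return int(np.random.SeedSequence([base, *key]).generate_state(1)[0] % 2**31)


def _infer_families(
    seeds: Sequence[str],
    sequences: Mapping[str, str],
    config: PipelineConfig,
    scheme: ScoringScheme,
) -> tuple[HomologyFamily, ...]:
    scorer = _Scorer(dict(sequences), scheme, config.word_size)
    families: list[HomologyFamily] = []
    claimed: set[str] = set()
    member_sets: set[frozenset[str]] = set()
    for i, seed in enumerate(sorted(set(seeds))):
        if seed in claimed:
            continue
        fam = find_homologues(
            f"F{len(families) + 1:02d}",
            [seed],
            dict(sequences),
            scheme,
            threshold=config.sim_score_threshold,
            max_iters=config.max_iters,
            word_size=config.word_size,
            scorer=scorer,
        )
        if len(fam.members) < 2:
            log.info("seed %s found no homologues; dropped", seed)
            continue
        if fam.members in member_sets:
            continue
        member_sets.add(fam.members)
        families.append(fam)
        claimed |= fam.members
    return tuple(families)


def _family_alignment(fam: HomologyFamily, sequences: Mapping[str, str]) -> AlignmentBlock:
    """Member alignment (members share a length by construction; stray
    contaminants of deviant length are dropped with a log note)."""
    lengths: dict[int, int] = {}
    for m in fam.members:
        L = len(sequences[m])
        lengths[L] = lengths.get(L, 0) + 1
    modal = max(sorted(lengths), key=lambda L: lengths[L])
    keep = sorted(m for m in fam.members if len(sequences[m]) == modal)
    if len(keep) < len(fam.members):
        log.info(
            "family %s: dropped %d member(s) of deviant length",
            fam.family_id,
            len(fam.members) - len(keep),
        )
    return AlignmentBlock(tuple(keep), tuple(sequences[m] for m in keep))


def run_pipeline(
    config: PipelineConfig = PipelineConfig(),
    mode: str = "synthetic",
    sim_config: Optional[SimulationConfig] = None,
    genomes: Optional[Sequence[GenomeRecord]] = None,
    sequences: Optional[Mapping[str, str]] = None,
    features: Optional[FeatureTable] = None,
    species_tree: Optional[dendropy.Tree] = None,
    outdir: Optional[str | Path] = None,
) -> PipelineResult:
    """Execute the full pipeline and return all stage artifacts.

    In synthetic mode the simulator provides every input plus ground truth
    (recovery metrics are computed); in real mode the caller supplies
    genomes, a sequence map (locus tag -> protein sequence), a feature
    table and a rooted species tree.
    """
    dataset = None
    if mode == "synthetic":
        sim_config = sim_config or SimulationConfig(seed=config.random_seed)
        dataset = simulate_dataset(sim_config)
        genomes = dataset.genomes
        sequences = dict(dataset.sequences)
        features = dataset.feature_table
        species_tree = dataset.species_tree
        if not config.focal_clades:
            config = config.with_(focal_clades=frozenset({dataset.focal_clade}))
    elif mode == "real":
        missing = [
            n
            for n, v in [
                ("genomes", genomes),
                ("sequences", sequences),
                ("features", features),
                ("species_tree", species_tree),
            ]
            if v is None
        ]
        if missing:
            raise ValueError(f"real mode requires inputs: {missing}")
    else:
        raise ValueError(f"unknown mode {mode!r}")
    if not config.focal_clades:
        raise ValueError("config.focal_clades must be set (or synthetic mode used)")
    genomes = tuple(genomes)
    label_internal_nodes(species_tree)

    # --- stage: screen
    universe = {(g.genome_id, l.locus_tag) for g in genomes for l in g.loci}
    screen = screen_candidates(features, universe)
    cand_by_genome: dict[str, set[str]] = {}
    for gid, tag in screen.candidates:
        cand_by_genome.setdefault(gid, set()).add(tag)

    # --- stage: candidate clustering
    candidate_clusters = {
        g.genome_id: clusters_for_genome(
            g, cand_by_genome.get(g.genome_id, ()), config.max_gap
        )
        for g in genomes
    }

    # --- stage: homologue families, seeded from a focal genome's clustered hits
    focal_genomes = sorted(
        g.genome_id for g in genomes if config.focal_clades & set(g.clade_path)
    )
    if not focal_genomes:
        raise ValueError("no genome lies inside the focal clades")
    by_id = {g.genome_id: g for g in genomes}
    # extend each multi-hit cluster to the full contiguous gene run: cluster
    # genes the feature screen missed still become family seeds; pooling
    # over the focal genomes keeps families whose cluster happens to be
    # scattered in any one genome
    seeds: list[str] = []
    seed_genome = focal_genomes[0]
    for gid in focal_genomes:
        multi = [c for c in candidate_clusters[gid] if c.n_hits >= 2]
        if multi and not seeds:
            seed_genome = gid
        seeds.extend(
            t
            for c in multi
            for t in extend_cluster(
                c, by_id[gid], config.merge_rules, config.discard
            ).member_tags()
        )
    if not seeds:
        seeds = sorted(cand_by_genome.get(seed_genome, ()))
    if not seeds:
        raise ValueError("no candidate seeds found in the focal clade")
    scheme = ScoringScheme()
    families = _infer_families(seeds, sequences, config, scheme)

    member_genome = {
        l.locus_tag: g.genome_id for g in genomes for l in g.loci
    }
    profile = build_profile(families, genomes, member_genome)
    clade_paths = {g.genome_id: g.clade_path for g in genomes}
    group_labels = {
        f.family_id: classify_distribution(
            profile.loc[f.family_id].to_dict(), clade_paths, config.focal_clades
        )
        for f in families
    }

    # --- stage: per-family trees + displacement
    family_alignments: dict[str, AlignmentBlock] = {}
    family_trees: dict[str, SupportedTree] = {}
    rooted_trees: dict[str, dendropy.Tree] = {}
    displacement: dict[str, tuple] = {}
    clade_map = clade_partition(species_tree, max_size=3)
    for i, fam in enumerate(families):
        aln = mask_columns(
            _family_alignment(fam, sequences), config.mask_max_missing
        )
        family_alignments[fam.family_id] = aln
        if aln.n_rows < 3:
            continue
        st = bootstrap_support(
            aln,
            model=config.distance_model,
            n_reps=config.n_bootstrap,
            seed=_seed_for(config.random_seed, 1, i),
            alpha=config.gamma_alpha,
            cap=config.distance_cap,
        )
        family_trees[fam.family_id] = st
        rooted = st.tree.clone(depth=1)
        try:
            rooted.reroot_at_midpoint(update_bipartitions=False)
        except Exception:  # pragma: no cover - degenerate trees
            pass
        rooted.is_rooted = True
        rooted_trees[fam.family_id] = rooted
        displacement[fam.family_id] = displacement_test(
            SupportedTree(rooted, st.support),
            clade_map,
            config.support_min,
            leaf_to_taxon=lambda l: member_genome[l],
            species_tree=species_tree,
        )

    # --- stage: linkage clusters over inferred family members
    fam_of_member = {
        m: f.family_id for f in families for m in f.members
    }
    linkage_clusters: dict[str, tuple[GenomicCluster, ...]] = {}
    colocated: set[frozenset[str]] = set()
    shadow: dict[str, GenomeRecord] = {}
    for g in genomes:
        loci = tuple(
            dataclasses.replace(l, family_id=fam_of_member.get(l.locus_tag))
            for l in g.loci
        )
        sg = dataclasses.replace(g, loci=loci)
        shadow[g.genome_id] = sg
        fam_loci = [l for l in sg.loci if l.family_id is not None]
        cl = detect_clusters(fam_loci, config.max_gap) if fam_loci else ()
        linkage_clusters[g.genome_id] = cl
        for c in cl:
            fams_here = frozenset(
                l.family_id for l in c.members if l.family_id is not None
            )
            if len(fams_here) >= 2:
                colocated.add(fams_here)

    # --- stage: congruence groups + supermatrices
    trees_for_grouping = {
        f: family_trees[f] for f in family_trees
    }
    leaf_to_taxon = {
        f: {m: member_genome[m] for m in fam.members}
        for f, fam in ((fam.family_id, fam) for fam in families)
        if f in trees_for_grouping
    }
    groups = congruence_groups(
        trees_for_grouping,
        leaf_to_taxon,
        sorted(colocated, key=sorted),
        rf_max=config.rf_congruence_max,
        min_shared_taxa=config.min_shared_taxa,
    )
    supermatrices: dict[str, Supermatrix] = {}
    supermatrix_trees: dict[str, SupportedTree] = {}
    for gi, group in enumerate(groups):
        if len(group) < 2:
            continue
        fams = sorted(group)
        tuples = []
        for gid in sorted(shadow):
            tpls, unassigned = link_paralogues(
                shadow[gid], fams, linkage_clusters[gid]
            )
            tuples.extend(tpls)
            if unassigned:
                log.info("genome %s: %d unassigned cop(ies)", gid, len(unassigned))
        if len(tuples) < 3:
            continue
        sm = concatenate(tuples, fams, family_alignments)
        name = "+".join(fams)
        supermatrices[name] = sm
        supermatrix_trees[name] = bootstrap_support(
            sm.alignment,
            model=config.distance_model,
            n_reps=config.n_bootstrap,
            seed=_seed_for(config.random_seed, 2, gi),
            alpha=config.gamma_alpha,
            cap=config.distance_cap,
        )

    # --- stage: scenario
    presence_rows = {
        f.family_id: profile.loc[f.family_id].to_dict() for f in families
    }
    l2t_all = {
        f.family_id: {m: member_genome[m] for m in f.members} for f in families
    }
    scenarios, _ = assemble_scenario(
        presence_rows,
        species_tree,
        rooted_trees,
        l2t_all,
        displacement,
        group_labels,
        truth=None,
    )

    metrics = None
    family_membership = None
    if dataset is not None:
        metrics, family_membership = evaluate_recovery(
            scenarios, families, dataset
        )

    result = PipelineResult(
        config=config,
        genomes=genomes,
        candidates=screen.candidates,
        candidate_clusters=candidate_clusters,
        families=families,
        profile=profile,
        group_labels=group_labels,
        family_trees=family_trees,
        displacement=displacement,
        groups=groups,
        supermatrices=supermatrices,
        supermatrix_trees=supermatrix_trees,
        scenarios=scenarios,
        metrics=metrics,
        family_membership=family_membership,
        dataset=dataset,
    )
    result.report = build_report(result, seed_genome)
    if outdir is not None:
        write_artifacts(result, outdir)
    return result


def _truth_label(fam: HomologyFamily) -> Optional[str]:
    votes: dict[str, int] = {}
    for m in fam.members:
        if FAMILY_SEP in m:
            t = copy_family(m)
            votes[t] = votes.get(t, 0) + 1
    if not votes:
        return None
    return max(sorted(votes), key=lambda t: votes[t])


def evaluate_recovery(
    scenarios: Sequence[FamilyScenario],
    families: Sequence[HomologyFamily],
    dataset: SimulatedDataset,
) -> tuple[RecoveryMetrics, dict]:
    """Score inferred families and events against the simulator truth log.

    Inferred families are matched to true families by majority vote over
    their members' true family identities; event metrics then compare
    (type, family, branch) tuples against the observable true events.
    """
    mapping = {f.family_id: _truth_label(f) for f in families}
    truth_members: dict[str, set[str]] = {}
    for cp in dataset.truth.tip_copies:
        truth_members.setdefault(copy_family(cp), set()).add(cp)

    n_assigned = 0
    matched: set[str] = set()
    for f in families:
        t = mapping[f.family_id]
        n_assigned += len(f.members)
        if t is None:
            continue
        matched |= f.members & truth_members.get(t, set())
    total_truth = sum(len(v) for v in truth_members.values())
    membership = {
        "precision": len(matched) / n_assigned if n_assigned else 1.0,
        "recall": len(matched) / total_truth if total_truth else 1.0,
        "n_inferred_members": n_assigned,
        "n_true_members": total_truth,
    }

    renamed = [
        dataclasses.replace(s, family_id=mapping.get(s.family_id) or s.family_id)
        for s in scenarios
    ]
    metrics = score_events(renamed, dataset.truth, dataset.species_tree)
    return metrics, membership


def build_report(result: PipelineResult, seed_genome: str) -> dict:
    """Machine-readable run report; every count is derived from artifacts."""
    multi = {
        gid: [c for c in cl if c.n_hits >= 2]
        for gid, cl in result.candidate_clusters.items()
    }
    report = {
        "seed": result.config.random_seed,
        "config": {
            k: sorted(v) if isinstance(v, frozenset) else v
            for k, v in vars(result.config).items()
        },
        "seed_genome": seed_genome,
        "counts": {
            "n_screen_input": sum(len(g.loci) for g in result.genomes),
            "n_candidates": len(result.candidates),
            "n_clusters_multi": sum(len(v) for v in multi.values()),
            "n_clustered_candidates": sum(
                c.n_hits for v in multi.values() for c in v
            ),
            "per_cluster_gene_counts": {
                gid: [c.n_members for c in v] for gid, v in sorted(multi.items()) if v
            },
            "n_families": len(result.families),
            "n_group_a": sum(
                1 for v in result.group_labels.values() if v == GROUP_A
            ),
            "n_group_b": sum(
                1 for v in result.group_labels.values() if v == GROUP_B
            ),
        },
        "supermatrix_shapes": {
            name: [sm.n_sequences, sm.n_positions]
            for name, sm in sorted(result.supermatrices.items())
        },
        "scenario": {
            s.family_id: {
                "origin": s.origin_branch,
                "n_losses": len(s.loss_branches),
                "n_duplications": len(s.duplications),
                "n_transfers": len(s.transfers),
                "group": s.group_label,
            }
            for s in result.scenarios
        },
    }
    if result.metrics is not None:
        report["recovery"] = {
            etype: {
                "precision": round(v[0], 6),
                "recall": round(v[1], 6),
                "f1": round(v[2], 6),
                "n_true": v[3],
                "n_inferred": v[4],
            }
            for etype, v in sorted(result.metrics.per_type.items())
        }
        report["family_membership"] = {
            k: round(v, 6) if isinstance(v, float) else v
            for k, v in result.family_membership.items()
        }
    return report


def report_json(result: PipelineResult) -> str:
    return json.dumps(result.report, sort_keys=True, indent=2)


def write_artifacts(result: PipelineResult, outdir: str | Path) -> None:
    from .io import write_feature_table, write_gene_table
    from .supermatrix import write_phylip

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "report.json").write_text(report_json(result) + "\n")
    write_gene_table(result.genomes, outdir / "gene_table.tsv")
    result.profile.to_csv(outdir / "profile.tsv", sep="\t")
    for fid, st in sorted(result.family_trees.items()):
        st.annotate_labels()
        write_newick(st.tree, outdir / f"tree_{fid}.nwk")
    for name, sm in sorted(result.supermatrices.items()):
        write_phylip(sm, outdir / f"supermatrix_{name}.phy")
    lines = ["family\tevent\tbranch\tdetail"]
    for s in result.scenarios:
        if s.origin_branch:
            lines.append(f"{s.family_id}\tgain\t{s.origin_branch}\t")
        for b in sorted(s.loss_branches):
            lines.append(f"{s.family_id}\tloss\t{b}\t")
        for node, b in s.duplications:
            lines.append(f"{s.family_id}\tduplication\t{b}\tnode={node}")
        for t in s.transfers:
            lines.append(
                f"{s.family_id}\ttransfer\t{t.recipient_branch}\t"
                f"source={t.source_clade};support={t.support:.0f}"
            )
    (outdir / "scenario.tsv").write_text("\n".join(lines) + "\n")
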