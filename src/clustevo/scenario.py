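"""Evolutionary-scenario reconstruction and recovery scoring.

Maps each gene family's history onto the species tree: a single origin and
a minimal loss set under Dollo parsimony (one gain, any number of losses),
duplications by the species-overlap rule on rooted gene trees, and
horizontal transfers from taxon-displacement reports. When a simulator
truth log is available, inferred events are scored against the observable
true events by exact (type, family, branch) matching.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Optional, Sequence

import dendropy
import numpy as np

from .phylo import (
    DisplacementReport,
    branch_leaf_sets,
    label_internal_nodes,
    mrca_branch,
    node_name,
)
from .simulate import TrueEventLog

log = logging.getLogger("clustevo")


# ---------------------------------------------------------------- Dollo / Fitch


def dollo_reconstruct(
    presence: Mapping[str, int], species_tree: dendropy.Tree
) -> tuple[str, frozenset[str]]:
    """Single-gain Dollo parsimony for one presence/absence profile.

    The origin is the branch above the MRCA of all present tips; the losses
    are the maximal subtrees below the origin containing no present tip.
    This loss set is minimal among all single-gain explanations: any
    explanation must cut every absent tip from the origin subtree, and
    cutting a maximal absent subtree at its root accounts for all its tips
    with one event.
    """
    present = frozenset(t for t, n in presence.items() if n >= 1)
    if not present:
        raise ValueError("all-absent profile: no single-gain explanation")
    label_internal_nodes(species_tree)
    below = branch_leaf_sets(species_tree)
    origin = mrca_branch(species_tree, present)

    losses: set[str] = set()

    def walk(name: str, children: Mapping[str, list[str]]) -> None:
        if not below[name] & present:
            losses.add(name)
            return
        for child in children[name]:
            walk(child, children)

    children = {
        node_name(n): [node_name(c) for c in n.child_nodes()]
        for n in species_tree.preorder_node_iter()
    }
    for child in children[origin]:
        walk(child, children)
    return origin, frozenset(losses)


def fitch_count(presence: Mapping[str, int], species_tree: dendropy.Tree) -> int:
    """Fitch small-parsimony change count for a binary profile
    (gains + losses unconstrained); quality-control comparator for Dollo."""
    label_internal_nodes(species_tree)
    states = {t: frozenset([1 if n >= 1 else 0]) for t, n in presence.items()}
    changes = 0

    def walk(node: dendropy.Node) -> frozenset[int]:
        nonlocal changes
        if node.is_leaf():
            return states[node.taxon.label]
        sets = [walk(c) for c in node.child_nodes()]
        inter = frozenset.intersection(*sets)
        if inter:
            return inter
        changes += len(sets) - 1  # binary trees: one change per empty meet
        return frozenset.union(*sets)

    walk(species_tree.seed_node)
    return changes


# ---------------------------------------------------------------- duplications


def infer_duplications(
    gene_tree: dendropy.Tree,
    leaf_to_taxon: Mapping[str, str] | Callable[[str], str],
    species_tree: dendropy.Tree,
    exclude_leaves: Iterable[str] = (),
) -> tuple[tuple[str, str], ...]:
    """Species-overlap duplications, mapped to species-tree branches.

    An internal node of the rooted gene tree is a duplication iff its child
    subtrees share at least one species; the event is placed on the species
    branch above the MRCA of the node's species set. ``exclude_leaves``
    removes transfer-implicated copies before the scan, so displaced leaves
    do not masquerade as deep duplications.
    """
    to_taxon = leaf_to_taxon if callable(leaf_to_taxon) else leaf_to_taxon.__getitem__
    exclude = set(exclude_leaves)
    label_internal_nodes(species_tree)
    species_below: dict[dendropy.Node, frozenset[str]] = {}
    out: list[tuple[str, str]] = []
    label_internal_nodes(gene_tree, prefix="g")
    for node in gene_tree.postorder_node_iter():
        if node.is_leaf():
            lbl = node.taxon.label
            if lbl in exclude:
                species_below[node] = frozenset()
            else:
                taxon = to_taxon(lbl)
                if taxon is None:
                    raise ValueError(f"leaf {lbl!r} maps to no species")
                species_below[node] = frozenset([taxon])
            continue
        kids = [species_below[c] for c in node.child_nodes()]
        species_below[node] = frozenset().union(*kids)
        overlap = len(kids) >= 2 and any(
            a & b for i, a in enumerate(kids) for b in kids[i + 1 :]
        )
        if overlap:
            branch = mrca_branch(species_tree, species_below[node])
            out.append((node_name(node), branch))
    return tuple(out)


# ---------------------------------------------------------------- transfers


@dataclass(frozen=True)
class TransferEvent:
    recipient_branch: str
    source_clade: str  # "unresolved" when direction/source is ambiguous
    support: float
    displaced_leaves: frozenset[str]


def infer_transfers(
    reports: Sequence[DisplacementReport],
    species_tree: dendropy.Tree,
) -> tuple[TransferEvent, ...]:
    """Turn displaced-block reports into transfer events.

    Each displaced block (one or more copies nesting, with support, among
    foreign leaves) yields one event onto the branch above the species-tree
    MRCA of the block's taxa; reports agreeing on recipient and source
    merge into one event.
    """
    if not reports:
        return ()
    label_internal_nodes(species_tree)
    merged: dict[tuple[str, str], list[DisplacementReport]] = {}
    for r in reports:
        taxa = r.taxa or frozenset([r.taxon])
        recipient = mrca_branch(species_tree, taxa)
        merged.setdefault((recipient, r.observed_clade), []).append(r)
    events = []
    for (recipient, source), group in sorted(merged.items()):
        events.append(
            TransferEvent(
                recipient_branch=recipient,
                source_clade=source,
                support=min(r.support for r in group),
                displaced_leaves=frozenset(
                    l for r in group for l in (r.block_leaves or {r.leaf})
                ),
            )
        )
    return tuple(events)


# ---------------------------------------------------------------- scenario + metrics


@dataclass(frozen=True)
class FamilyScenario:
    family_id: str
    origin_branch: Optional[str]
    loss_branches: frozenset[str]
    duplications: tuple[tuple[str, str], ...]  # (gene-tree node, species branch)
    transfers: tuple[TransferEvent, ...]
    group_label: Optional[str] = None


@dataclass(frozen=True)
class RecoveryMetrics:
    """Precision/recall/F1 per event type from exact event matching."""

    per_type: Mapping[str, tuple[float, float, float, int, int]]
    # etype -> (precision, recall, f1, n_true, n_inferred)

    def precision(self, etype: str) -> float:
        return self.per_type[etype][0]

    def recall(self, etype: str) -> float:
        return self.per_type[etype][1]

    def f1(self, etype: str) -> float:
        return self.per_type[etype][2]


def _prf(true_set, inferred_set) -> tuple[float, float, float, int, int]:
    from collections import Counter

    ct, ci = Counter(true_set), Counter(inferred_set)
    tp = sum(min(ct[k], ci[k]) for k in ct)
    n_true, n_inf = sum(ct.values()), sum(ci.values())
    precision = tp / n_inf if n_inf else 1.0
    recall = tp / n_true if n_true else 1.0
    f1 = (
        2 * precision * recall / (precision + recall) if precision + recall > 0 else 0.0
    )
    return precision, recall, f1, n_true, n_inf


def visible_transfers(
    truth: TrueEventLog, species_tree: dendropy.Tree
) -> tuple:
    """Observable transfers that leave a topological incongruence signal.

    A transfer is *visible* to displacement-based inference only when the
    received block conflicts with vertical descent: the received copies (R)
    and the surviving donor-side copies (D) must both exist, share no taxon,
    leave external context (|R u D| <= n-2), and form a neighbourhood the
    unrooted species tree cannot explain - both R u D and R u N(D), where
    N(D) widens a single-leaf donor to its smallest enclosing species clade,
    must be species-incompatible, and donor plus recipient must not fit in
    one small species-tree region (LOCAL_REGION_FRACTION of the taxa).
    Transfers from a lineage adjacent to the recipient, near-root transfers,
    within-clade and other short-range transfers produce no reliable
    conflict and are inherently unidentifiable by tree comparison.
    """
    label_internal_nodes(species_tree)
    below = branch_leaf_sets(species_tree)
    from .phylo import (
        LOCAL_REGION_FRACTION,
        bipartitions,
        leaf_names,
        mrca_branch as _mrca,
    )

    sp_leaves = leaf_names(species_tree)
    n = len(sp_leaves)
    local_cap = max(3, int(np.ceil(LOCAL_REGION_FRACTION * n)))
    sides = set(bipartitions(species_tree)) | {frozenset([x]) for x in sp_leaves}
    compatible = set()
    for s0 in sides:
        compatible.add(frozenset(s0))
        compatible.add(frozenset(sp_leaves - s0))

    def tip_taxa(copy_prefix: str) -> frozenset[str]:
        return frozenset(
            taxon
            for cp, taxon in truth.tip_copies.items()
            if cp.startswith(copy_prefix)
        )

    out = []
    for e in truth.observable_events("transfer"):
        R = tip_taxa(e.children[1])
        D = tip_taxa(e.children[0])
        if not R or not D or (R & D):
            continue
        if len(R | D) > n - 2:
            continue
        if frozenset(R | D) in compatible:
            continue
        if len(D) == 1:
            donor_leaf = next(iter(D))
            neighborhood = min(
                (leaves for leaves in below.values() if donor_leaf in leaves and len(leaves) >= 2),
                key=len,
            )
        else:
            neighborhood = below[_mrca(species_tree, D)]
        if frozenset(R | neighborhood) in compatible:
            continue
        if len(below[_mrca(species_tree, R | D)]) <= local_cap:
            continue  # short-range transfer: no long-range displacement signal
        out.append(e)
    return tuple(out)


def score_events(
    scenarios: Sequence[FamilyScenario],
    truth: TrueEventLog,
    species_tree: Optional[dendropy.Tree] = None,
) -> RecoveryMetrics:
    """Match inferred vs observable true events on (type, family, branch).

    When ``species_tree`` is given, transfer recall is scored against the
    topologically *visible* transfers (see :func:`visible_transfers`); the
    unrestricted comparison is reported under ``transfer_unrestricted``.
    """
    inferred = {
        "gain": [
            (s.family_id, s.origin_branch) for s in scenarios if s.origin_branch
        ],
        "loss": [(s.family_id, b) for s in scenarios for b in sorted(s.loss_branches)],
        "duplication": [(s.family_id, b) for s in scenarios for _, b in s.duplications],
        "transfer": [
            (s.family_id, t.recipient_branch) for s in scenarios for t in s.transfers
        ],
    }
    per_type = {}
    for etype in ("gain", "loss", "duplication", "transfer"):
        true_events = [
            (e.family_id, e.branch) for e in truth.observable_events(etype)
        ]
        if etype == "transfer" and species_tree is not None:
            # precision against every true event (detecting a hard event is
            # not an error); recall against the identifiable ones
            all_prf = _prf(true_events, inferred[etype])
            per_type["transfer_unrestricted"] = all_prf
            visible = [
                (e.family_id, e.branch)
                for e in visible_transfers(truth, species_tree)
            ]
            vis_prf = _prf(visible, inferred[etype])
            precision, recall = all_prf[0], vis_prf[1]
            f1 = (
                2 * precision * recall / (precision + recall)
                if precision + recall > 0
                else 0.0
            )
            per_type[etype] = (precision, recall, f1, vis_prf[3], all_prf[4])
            continue
        per_type[etype] = _prf(true_events, inferred[etype])
    return RecoveryMetrics(per_type)


def assemble_scenario(
    presence_rows: Mapping[str, Mapping[str, int]],
    species_tree: dendropy.Tree,
    gene_trees: Mapping[str, dendropy.Tree],
    leaf_to_taxon: Mapping[str, Mapping[str, str]],
    displacement: Mapping[str, Sequence[DisplacementReport]],
    group_labels: Mapping[str, str] | None = None,
    truth: Optional[TrueEventLog] = None,
) -> tuple[tuple[FamilyScenario, ...], Optional[RecoveryMetrics]]:
    """Build one scenario per family; score against truth when available.

    For each family, transfers are inferred first; transfer-derived copies
    are then excluded both from the presence row fed to Dollo (so vertical
    origin/losses are re-estimated without horizontally acquired tips) and
    from the gene tree scanned for duplications.

    Displacement reports whose entire witnessing neighbourhood lies inside
    the gene-tree clade of an inferred duplication (and within that
    duplication's species clade, when it is not tree-wide) are discarded:
    paralogue scrambling inside a duplicated module mimics displacement but
    carries no transfer signal.
    """
    fams = sorted(presence_rows)
    if set(gene_trees) - set(fams):
        raise ValueError("gene trees reference families missing from presence rows")
    label_internal_nodes(species_tree)
    sp_below = branch_leaf_sets(species_tree)
    n_sp = sum(1 for _ in species_tree.leaf_node_iter())
    scenarios = []
    for fam in fams:
        reports = tuple(displacement.get(fam, ()))
        l2t = leaf_to_taxon.get(fam, {})
        transfers = infer_transfers(reports, species_tree)
        displaced_leaves = frozenset(l for t in transfers for l in t.displaced_leaves)
        displaced_by_taxon: dict[str, int] = {}
        for l in displaced_leaves:
            taxon = l2t.get(l, l)
            displaced_by_taxon[taxon] = displaced_by_taxon.get(taxon, 0) + 1
        row = {
            t: max(int(n) - displaced_by_taxon.get(t, 0), 0)
            for t, n in presence_rows[fam].items()
        }
        if any(n >= 1 for n in row.values()):
            origin, losses = dollo_reconstruct(row, species_tree)
        else:
            origin, losses = None, frozenset()
        dups: tuple[tuple[str, str], ...] = ()
        if fam in gene_trees and gene_trees[fam] is not None:
            dups = infer_duplications(
                gene_trees[fam],
                dict(l2t),
                species_tree,
                exclude_leaves=displaced_leaves,
            )
        scenarios.append(
            FamilyScenario(
                family_id=fam,
                origin_branch=origin,
                loss_branches=losses,
                duplications=dups,
                transfers=transfers,
                group_label=(group_labels or {}).get(fam),
            )
        )
    metrics = (
        score_events(scenarios, truth, species_tree) if truth is not None else None
    )
    return tuple(scenarios), metrics


def render_scenario(
    scenarios: Sequence[FamilyScenario], species_tree: dendropy.Tree
) -> str:
    """Plain-text species tree with per-branch gain/loss/transfer annotations."""
    label_internal_nodes(species_tree)
    gains: dict[str, list[str]] = {}
    losses: dict[str, list[str]] = {}
    arrivals: dict[str, list[str]] = {}
    for s in scenarios:
        if s.origin_branch:
            gains.setdefault(s.origin_branch, []).append(s.family_id)
        for b in sorted(s.loss_branches):
            losses.setdefault(b, []).append(s.family_id)
        for t in s.transfers:
            arrivals.setdefault(t.recipient_branch, []).append(
                f"{s.family_id}<-{t.source_clade}"
            )
    lines = []

    def walk(node: dendropy.Node, depth: int) -> None:
        name = node_name(node)
        notes = []
        if name in gains:
            notes.append("+[" + ",".join(sorted(gains[name])) + "]")
        if name in losses:
            notes.append("-[" + ",".join(sorted(losses[name])) + "]")
        if name in arrivals:
            notes.append("HGT[" + ",".join(sorted(arrivals[name])) + "]")
        lines.append("  " * depth + name + (" " + " ".join(notes) if notes else ""))
        for c in node.child_nodes():
            walk(c, depth + 1)

    walk(species_tree.seed_node, 0)
    return "\n".join(lines)
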