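"""Desk-scale distance phylogenetics and tree comparison.

Column masking, multiple-hit-corrected distances under a uniform 20-state
substitution model, classical neighbor-joining (Saitou-Nei criterion with
Studier-Keppler updates and deterministic lexicographic tie-breaking),
nonparametric bootstrap support, Robinson-Foulds bipartition distance, and a
taxon-displacement test that flags horizontal-transfer signal: a sequence
nesting, with support, inside a clade of leaves from a foreign part of the
species tree.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Optional, Sequence

import dendropy
import numpy as np

from .core import AlignmentBlock, MISSING_CODE

log = logging.getLogger("clustevo")


# ---------------------------------------------------------------- tree utilities


def label_internal_nodes(tree: dendropy.Tree, prefix: str = "N") -> dendropy.Tree:
    """Assign stable preorder labels to unlabeled internal nodes (in place)."""
    i = 0
    for node in tree.preorder_node_iter():
        if node.is_leaf():
            continue
        if not node.label:
            node.label = f"{prefix}{i}"
        i += 1
    return tree


def leaf_names(tree: dendropy.Tree) -> frozenset[str]:
    return frozenset(lf.taxon.label for lf in tree.leaf_node_iter())


def node_name(node: dendropy.Node) -> str:
    return node.taxon.label if node.is_leaf() else node.label


def branch_leaf_sets(tree: dendropy.Tree) -> dict[str, frozenset[str]]:
    """Map each branch (named by its child node) to the leaf set below it."""
    out: dict[str, frozenset[str]] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            out[node_name(node)] = frozenset([node.taxon.label])
        else:
            out[node_name(node)] = frozenset().union(
                *(out[node_name(c)] for c in node.child_nodes())
            )
    return out


def mrca_branch(tree: dendropy.Tree, taxa: Iterable[str]) -> str:
    """Name of the branch above the most recent common ancestor of ``taxa``."""
    taxa = frozenset(taxa)
    if not taxa:
        raise ValueError("empty taxon set")
    below = branch_leaf_sets(tree)
    best: Optional[tuple[int, str]] = None
    for name, leaves in below.items():
        if taxa <= leaves and (best is None or len(leaves) < best[0]):
            best = (len(leaves), name)
    assert best is not None
    return best[1]


def bipartitions(tree: dendropy.Tree) -> dict[frozenset[str], dendropy.Edge]:
    """Non-trivial unrooted bipartitions, canonicalized to the side *not*
    containing the lexicographically smallest leaf."""
    leaves = leaf_names(tree)
    ref = min(leaves)
    out: dict[frozenset[str], dendropy.Edge] = {}
    below = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            below[node] = frozenset([node.taxon.label])
        else:
            below[node] = frozenset().union(*(below[c] for c in node.child_nodes()))
        side = below[node]
        if ref in side:
            side = leaves - side
        if 2 <= len(side) <= len(leaves) - 2:
            out[side] = node.edge
    return out


def robinson_foulds(t1: dendropy.Tree, t2: dendropy.Tree) -> int:
    """Count of non-trivial bipartitions present in exactly one tree."""
    l1, l2 = leaf_names(t1), leaf_names(t2)
    if l1 != l2:
        raise ValueError(
            f"leaf sets differ: only in first {sorted(l1 - l2)}, "
            f"only in second {sorted(l2 - l1)}"
        )
    b1, b2 = set(bipartitions(t1)), set(bipartitions(t2))
    return len(b1 ^ b2)


# ---------------------------------------------------------------- masking


def mask_columns(alignment: AlignmentBlock, max_missing: float) -> AlignmentBlock:
    """Drop columns whose gap/unknown fraction exceeds ``max_missing``."""
    if alignment.n_rows == 0 or alignment.n_positions == 0:
        raise ValueError("empty alignment")
    if not (0.0 <= max_missing <= 1.0):
        raise ValueError("max_missing must be in [0, 1]")
    codes = alignment.to_codes()
    missing_frac = (codes == MISSING_CODE).mean(axis=0)
    keep = np.flatnonzero(missing_frac <= max_missing)
    return alignment.select_columns(keep.tolist())


# ---------------------------------------------------------------- distances


@dataclass(frozen=True)
class DistanceMatrix:
    labels: tuple[str, ...]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = self.matrix
        if m.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape must match labels")
        if not np.allclose(m, m.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(m) != 0):
            raise ValueError("diagonal must be zero")
        if np.any(m < 0):
            raise ValueError("distances must be non-negative")

    def get(self, a: str, b: str) -> float:
        return float(self.matrix[self.labels.index(a), self.labels.index(b)])


def correct_distance(p: float, model: str, alpha: float = 1.0, cap: float = 10.0) -> float:
    """Multiple-hit correction of a mismatch fraction under the uniform
    20-state model; saturated pairs are capped."""
    if model == "p":
        return p
    arg = 1.0 - (20.0 / 19.0) * p
    if arg <= 0.0:
        log.warning("saturated pair (p=%.4f): distance capped at %.2f", p, cap)
        return cap
    if model == "poisson":
        return min(-(19.0 / 20.0) * math.log(arg), cap)
    if model == "gamma":
        return min((19.0 / 20.0) * alpha * (arg ** (-1.0 / alpha) - 1.0), cap)
    raise ValueError(f"unknown distance model {model!r}")


def _distances_from_codes(
    codes: np.ndarray,
    row_ids: Sequence[str],
    model: str,
    alpha: float,
    cap: float,
) -> DistanceMatrix:
    valid = codes != MISSING_CODE
    n = codes.shape[0]
    # pairwise-deletion mismatch fractions, fully vectorized
    both = valid[:, None, :] & valid[None, :, :]
    shared = both.sum(axis=2)
    off = ~np.eye(n, dtype=bool)
    if np.any(shared[off] == 0):
        i, j = np.argwhere((shared == 0) & off)[0]
        raise ValueError(
            f"rows {row_ids[i]!r} and {row_ids[j]!r} share no aligned columns"
        )
    diff = ((codes[:, None, :] != codes[None, :, :]) & both).sum(axis=2)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(shared > 0, diff / np.maximum(shared, 1), 0.0)
        if model == "p":
            d = p
        else:
            arg = 1.0 - (20.0 / 19.0) * p
            saturated = arg <= 0.0
            arg = np.where(saturated, 1.0, arg)
            if model == "poisson":
                d = -(19.0 / 20.0) * np.log(arg)
            elif model == "gamma":
                d = (19.0 / 20.0) * alpha * (arg ** (-1.0 / alpha) - 1.0)
            else:
                raise ValueError(f"unknown distance model {model!r}")
            if saturated.any():
                log.warning(
                    "%d saturated pair(s): distance capped at %.2f",
                    int(saturated[off].sum()) // 2,
                    cap,
                )
            d = np.where(saturated, cap, np.minimum(d, cap))
    np.fill_diagonal(d, 0.0)
    d = 0.5 * (d + d.T)  # exact symmetry against float noise
    return DistanceMatrix(tuple(row_ids), d)


def pairwise_distance(
    alignment: AlignmentBlock,
    model: str = "poisson",
    alpha: float = 1.0,
    cap: float = 10.0,
) -> DistanceMatrix:
    """Pairwise-deletion distances between alignment rows.

    Each pair is compared over the columns where both rows carry residues;
    a pair with zero shared columns is an error.
    """
    if alignment.n_rows < 2:
        raise ValueError("need at least 2 rows")
    return _distances_from_codes(
        alignment.to_codes(), alignment.row_ids, model, alpha, cap
    )


# ---------------------------------------------------------------- neighbor joining


@dataclass
class SupportedTree:
    """A tree plus per-internal-edge bootstrap support (percentages)."""

    tree: dendropy.Tree
    support: dict[frozenset[str], float] = field(default_factory=dict)

    def leaf_set(self) -> frozenset[str]:
        return leaf_names(self.tree)

    def annotate_labels(self) -> None:
        """Write supports onto internal node labels for newick export."""
        bps = bipartitions(self.tree)
        for side, edge in bps.items():
            if side in self.support and not edge.head_node.is_leaf():
                edge.head_node.label = f"{self.support[side]:.0f}"


def neighbor_joining(D: DistanceMatrix) -> dendropy.Tree:
    """Classical NJ; deterministic via lexicographic tie-breaking.

    Ties in the Saitou-Nei Q criterion are broken toward the pair whose
    (sorted) representative labels are lexicographically smallest, where a
    merged node is represented by the smallest leaf label beneath it.
    Negative branch lengths are clamped to zero and the deficit logged.
    """
    n = len(D.labels)
    if n < 3:
        raise ValueError("need at least 3 labels")
    taxa = dendropy.TaxonNamespace(list(D.labels))
    tree = dendropy.Tree(taxon_namespace=taxa)
    nodes: list[dendropy.Node] = []
    reps: list[str] = []
    for lbl in D.labels:
        node = dendropy.Node()
        node.taxon = taxa.get_taxon(lbl)
        nodes.append(node)
        reps.append(lbl)
    d = D.matrix.astype(float).copy()
    active = list(range(n))
    deficit = 0.0

    while len(active) > 2:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        qmin = q.min()
        ties = np.argwhere(np.isclose(q, qmin, rtol=0.0, atol=1e-10))
        best = min(
            (tuple(sorted((reps[active[i]], reps[active[j]]))), i, j)
            for i, j in ties
            if i < j
        )
        _, ai, aj = best
        i, j = active[ai], active[aj]
        dij = d[i, j]
        li = 0.5 * dij + (r[ai] - r[aj]) / (2.0 * (m - 2))
        lj = dij - li
        for length in (li, lj):
            if length < 0:
                deficit += -length
        li, lj = max(li, 0.0), max(lj, 0.0)
        parent = dendropy.Node()
        ni, nj = nodes[i], nodes[j]
        parent.add_child(ni)
        parent.add_child(nj)
        ni.edge.length = li
        nj.edge.length = lj
        # Studier-Keppler update
        new_row = 0.5 * (d[i, :] + d[j, :] - dij)
        d[i, :] = new_row
        d[:, i] = new_row
        d[i, i] = 0.0
        nodes[i] = parent
        reps[i] = min(reps[i], reps[j])
        active.remove(j)

    i, j = active
    # attach the last node below the other (the internal one if any), so the
    # unrooted tree carries the full terminal edge length
    if nodes[i].is_leaf() and not nodes[j].is_leaf():
        i, j = j, i
    root = nodes[i]
    root.add_child(nodes[j])
    nodes[j].edge.length = max(d[i, j], 0.0)
    if deficit > 0:
        log.info("NJ clamped negative branch lengths (total deficit %.4g)", deficit)
    tree.seed_node = root
    tree.is_rooted = False
    label_internal_nodes(tree)
    return tree


def bootstrap_support(
    alignment: AlignmentBlock,
    model: str = "poisson",
    n_reps: int = 100,
    seed: int = 0,
    alpha: float = 1.0,
    cap: float = 10.0,
) -> SupportedTree:
    """NJ tree from the full alignment plus column-resampling bootstrap.

    Support of an internal edge is the percentage of replicates whose NJ
    tree contains the same bipartition.
    """
    if alignment.n_positions < 1:
        raise ValueError("alignment has no columns")
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    codes = alignment.to_codes()
    ref = neighbor_joining(
        _distances_from_codes(codes, alignment.row_ids, model, alpha, cap)
    )
    ref_bps = set(bipartitions(ref))
    counts = {bp: 0 for bp in ref_bps}
    rng = np.random.default_rng(seed)
    ncol = alignment.n_positions
    for _ in range(n_reps):
        cols = rng.integers(0, ncol, size=ncol)
        try:
            rep_tree = neighbor_joining(
                _distances_from_codes(
                    codes[:, cols], alignment.row_ids, model, alpha, cap
                )
            )
        except ValueError:
            continue  # e.g. a resample with no shared columns for some pair
        for bp in bipartitions(rep_tree):
            if bp in counts:
                counts[bp] += 1
    support = {bp: 100.0 * c / n_reps for bp, c in counts.items()}
    return SupportedTree(ref, support)


# ---------------------------------------------------------------- displacement

#: transfers whose donor and recipient lie within a species-tree region of at
#: most this fraction of all taxa are treated as unidentifiable: short-range
#: displacement is indistinguishable from local incongruence noise/paralogy
LOCAL_REGION_FRACTION = 0.35



@dataclass(frozen=True)
class DisplacementReport:
    """A displaced copy block: gene-tree leaves nesting among foreign leaves.

    ``block_leaves`` are the horizontally acquired copies themselves (one
    leaf for the classic single-taxon case); ``clade_leaves`` is the
    enclosing neighbourhood that witnessed the displacement. ``taxon`` is
    the smallest taxon of the block (the displaced taxon in the classic
    case).
    """

    leaf: str
    taxon: str
    expected_clade: str
    observed_clade: str  # "unresolved" when the foreign neighbourhood is mixed
    support: float
    clade_leaves: frozenset[str]
    block_leaves: frozenset[str] = frozenset()
    taxa: frozenset[str] = frozenset()


def displacement_test(
    gene_tree: SupportedTree,
    clade_map: Mapping[str, str],
    support_min: float,
    leaf_to_taxon: Optional[Callable[[str], str]] = None,
    species_tree: Optional[dendropy.Tree] = None,
    max_rounds: int = 3,
) -> tuple[DisplacementReport, ...]:
    """Flag copy blocks nesting, with support, among foreign leaves.

    ``gene_tree.tree`` must be rooted (e.g. at its midpoint). A supported
    clade of copies is reported as a *displaced block* - a horizontally
    received unit - when its supported neighbourhood cannot be explained by
    the unrooted species tree, removing the block restores that
    consistency, and the block's taxa are copy-redundant (each carries
    another copy elsewhere in the tree) or the block is a classic
    foreign-nested single copy. When the two halves of an anomalous
    neighbourhood are both explicable, the wider context (the next
    supported enclosing clade) and copy redundancy decide which half is the
    received one. Detected blocks are peeled off and the scan repeats (up
    to ``max_rounds``), so several transfers stacked in one region unmask
    each other.

    ``clade_map`` maps taxa to reference clades and is used to name the
    expected/observed clades in reports; ``leaf_to_taxon`` converts
    gene-tree leaf names (sequence copies) to taxa and defaults to
    identity. Without ``species_tree`` only the classic single-copy rule
    (smallest supported enclosing clade of >= 3 leaves entirely from a
    foreign reference clade) is applied.
    """
    to_taxon = leaf_to_taxon or (lambda x: x)
    tree = gene_tree.tree
    all_leaves = gene_tree.leaf_set()
    ref = min(all_leaves)
    for lf in all_leaves:
        if to_taxon(lf) not in clade_map:
            raise ValueError(f"leaf {lf!r} maps to no clade")

    def edge_support(clade: frozenset[str]) -> float:
        if len(clade) <= 1 or len(clade) >= len(all_leaves) - 1:
            return 100.0  # trivial splits are certain
        side = clade if ref not in clade else all_leaves - clade
        return gene_tree.support.get(side, 0.0)

    orig_below: dict[dendropy.Node, frozenset[str]] = {}
    parent_of: dict[dendropy.Node, dendropy.Node] = {}
    postorder = list(tree.postorder_node_iter())
    for node in postorder:
        if node.is_leaf():
            orig_below[node] = frozenset([node.taxon.label])
        else:
            orig_below[node] = frozenset().union(
                *(orig_below[c] for c in node.child_nodes())
            )
        for c in node.child_nodes():
            parent_of[c] = node

    compatible_sides: Optional[set[frozenset[str]]] = None
    species_clades: set[frozenset[str]] = set()
    if species_tree is not None:
        gene_taxa = frozenset(to_taxon(l) for l in all_leaves)
        sp_leaves = leaf_names(species_tree)
        all_sides = set(bipartitions(species_tree)) | {
            frozenset([x]) for x in sp_leaves
        }
        compatible_sides = set()
        for side in all_sides:
            for s in (side, sp_leaves - side):
                compatible_sides.add(frozenset(s & gene_taxa))
        species_clades = set(branch_leaf_sets(species_tree).values())
        local_cap = max(3, int(np.ceil(LOCAL_REGION_FRACTION * len(sp_leaves))))

        def region_size(taxa: frozenset[str]) -> int:
            best = None
            for leaves in species_clades:
                if taxa <= leaves and (best is None or len(leaves) < best):
                    best = len(leaves)
            return best if best is not None else len(sp_leaves)

    def compatible(taxa: frozenset[str]) -> bool:
        if compatible_sides is None:
            return False
        return taxa in compatible_sides

    def clade_label(taxa_set) -> str:
        cl = {clade_map[t] for t in taxa_set}
        return cl.pop() if len(cl) == 1 else "unresolved"

    def scan(
        active: frozenset[str],
        strict: bool,
        prior: Sequence[DisplacementReport] = (),
    ) -> list[DisplacementReport]:
        below = {
            n: orig_below[n] & active for n in postorder
        }
        n_copies: dict[str, int] = {}
        for lf in active:
            t = to_taxon(lf)
            n_copies[t] = n_copies.get(t, 0) + 1
        seen_blocks: set[frozenset[str]] = set()
        raw: list[tuple] = []  # (clean, e1_ok, report, E0)
        for node in postorder:
            block = below[node]
            if not block or len(block) >= len(active) - 1:
                continue
            if block in seen_blocks:
                continue
            seen_blocks.add(block)
            if edge_support(orig_below[node]) < support_min:
                continue
            block_taxa = frozenset(to_taxon(l) for l in block)
            enclosings: list[frozenset[str]] = []
            anc = parent_of.get(node)
            while anc is not None and len(enclosings) < 2:
                clade = below[anc]
                if (
                    len(clade) >= len(block) + 2
                    and len(clade) < len(active)
                    and edge_support(orig_below[anc]) >= support_min
                ):
                    if not enclosings or clade != enclosings[-1]:
                        enclosings.append(clade)
                anc = parent_of.get(anc)
            if not enclosings:
                continue
            E0 = enclosings[0]
            others = E0 - block
            others_taxa = frozenset(to_taxon(l) for l in others)
            if block_taxa & others_taxa:
                continue  # own material adjacent: vertical descent or paralogy
            if compatible(frozenset(to_taxon(l) for l in E0)):
                continue  # the species tree explains this neighbourhood
            if species_tree is not None and not compatible(others_taxa):
                continue  # removing the block does not restore consistency
            if (
                species_tree is not None
                and region_size(block_taxa | others_taxa) <= local_cap
            ):
                continue  # short-range anomaly: no long-range transfer signal
            block_redundant = all(
                n_copies[t] > sum(1 for l in block if to_taxon(l) == t)
                for t in block_taxa
            )
            others_redundant = all(
                n_copies[t] > sum(1 for l in others if to_taxon(l) == t)
                for t in others_taxa
            )
            if len(block) == 1:
                if (
                    species_tree is not None
                    and not block_redundant
                    and others_redundant
                ):
                    continue  # the neighbours are the received block
                if clade_map[next(iter(block_taxa))] in {
                    clade_map[t] for t in others_taxa
                }:
                    continue  # classic rule: neighbours include the own clade
            elif species_tree is None or not block_redundant:
                continue  # multi-leaf blocks need the redundancy signal
            e1_ok = True
            if species_tree is not None and len(enclosings) > 1:
                e1_ok = compatible(
                    frozenset(to_taxon(l) for l in enclosings[1] - block)
                )
            clean = species_tree is None or block_taxa in species_clades
            raw.append(
                (
                    clean,
                    e1_ok,
                    DisplacementReport(
                        leaf=min(block),
                        taxon=min(block_taxa),
                        expected_clade=clade_label(block_taxa),
                        observed_clade=clade_label(others_taxa),
                        support=min(
                            edge_support(orig_below[node]), edge_support(E0)
                        ),
                        clade_leaves=frozenset(E0),
                        block_leaves=frozenset(block),
                        taxa=block_taxa,
                    ),
                    E0,
                )
            )
        # sibling disambiguation: when two candidates are the two halves of
        # one anomalous neighbourhood, only one of them is the received
        # block; the wider context (e1_ok) and redundancy decide
        drop: set[frozenset[str]] = set()
        for ca in raw:
            for cb in raw:
                ba, bb = ca[2].block_leaves, cb[2].block_leaves
                if ba == bb or (ba & bb):
                    continue
                if bb == ca[3] - ba:  # complements within ca's enclosing
                    if ca[1] and not cb[1]:
                        drop.add(bb)
                    elif cb[1] and not ca[1]:
                        drop.add(ba)
                    elif len(ba) == 1 and len(bb) > 1:
                        drop.add(ba)  # lone copy vs block: block received
                    elif len(bb) == 1 and len(ba) > 1:
                        drop.add(bb)
        raw = [c for c in raw if c[2].block_leaves not in drop]
        if strict:
            # on a peeled tree only the most confident blocks are trusted:
            # taxa must exactly fill a species clade and the wider context
            # must be explicable once the block is removed
            raw = [c for c in raw if c[0] and c[1]]
        # overlap resolution: clean (species-clade-exact) blocks first, then
        # wider-context-consistent, then larger
        raw.sort(
            key=lambda c: (not c[0], not c[1], -len(c[2].block_leaves), c[2].leaf)
        )
        kept: list[DisplacementReport] = []
        for _, _, r, _ in raw:
            if any(r.block_leaves & k.block_leaves for k in kept):
                continue
            if any(
                r.block_leaves <= k.clade_leaves for k in list(kept) + list(prior)
            ):
                continue  # this block is a kept block's donor-side context
            kept.append(r)
        return kept

    reports: list[DisplacementReport] = []
    active = frozenset(all_leaves)
    for round_no in range(max(1, max_rounds)):
        new = scan(active, strict=round_no > 0, prior=reports)
        if not new:
            break
        reports.extend(new)
        active = active - frozenset(l for r in new for l in r.block_leaves)
        if len(active) < 4 or species_tree is None:
            break
    return tuple(sorted(reports, key=lambda r: r.leaf))


def clade_partition(tree: dendropy.Tree, max_size: int = 3) -> dict[str, str]:
    """Partition species-tree leaves into small reference clades.

    Maximal subtrees with at most ``max_size`` leaves become the expected
    clades used by the displacement test; finer clades make within-clade
    transfers (which leave no displacement signal) rarer. A leaf that would
    end up alone in its clade (an isolated deep lineage) is merged into its
    sister clade, since a taxon with no own-clade companions would otherwise
    always look displaced.
    """
    label_internal_nodes(tree)
    assignment: dict[str, str] = {}
    below = branch_leaf_sets(tree)

    def walk(node: dendropy.Node) -> None:
        name = node_name(node)
        if len(below[name]) <= max_size and len(below[name]) >= 2:
            for lf in below[name]:
                assignment[lf] = name
            return
        if node.is_leaf():
            assignment[node.taxon.label] = name  # provisional singleton
            return
        for child in node.child_nodes():
            walk(child)

    walk(tree.seed_node)
    # merge singleton clades into the clade of the nearest sibling leaf
    clade_sizes: dict[str, int] = {}
    for c in assignment.values():
        clade_sizes[c] = clade_sizes.get(c, 0) + 1
    for leaf, clade in list(assignment.items()):
        if clade_sizes[clade] > 1:
            continue
        node = next(
            lf for lf in tree.leaf_node_iter() if lf.taxon.label == leaf
        )
        parent = node.parent_node
        while parent is not None:
            sibs = below[node_name(parent)] - {leaf}
            candidates = sorted(
                s for s in sibs if clade_sizes.get(assignment[s], 0) > 1
            )
            if candidates:
                assignment[leaf] = assignment[candidates[0]]
                break
            parent = parent.parent_node
    return assignment
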