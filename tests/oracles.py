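"""Independent brute-force oracles used by unit and acceptance tests.

These deliberately avoid the implementations they check: local alignment by
exhaustive path enumeration, Dollo by exhaustive ancestral-state
minimization, and tree comparison via dendropy.
"""

from __future__ import annotations

import itertools

from Bio.Align import substitution_matrices

_B62 = substitution_matrices.load("BLOSUM62")


def brute_force_local_score(
    a: str, b: str, gap_open: float = -11.0, gap_extend: float = -1.0
) -> float:
    """Best local alignment score by enumerating every alignment path.

    Starts at every (i, j) pair and extends by match, gap-in-a or gap-in-b
    moves, recording the running score at every prefix (a local alignment
    may end anywhere). Exponential: only for tiny sequences.
    """
    best = 0.0

    def extend(i: int, j: int, state: str, score: float) -> None:
        nonlocal best
        if score > best:
            best = score
        if i < len(a) and j < len(b):
            extend(i + 1, j + 1, "m", score + _B62[a[i], b[j]])
        if i < len(a):
            extend(i + 1, j, "ga", score + (gap_extend if state == "ga" else gap_open))
        if j < len(b):
            extend(i, j + 1, "gb", score + (gap_extend if state == "gb" else gap_open))

    for i in range(len(a)):
        for j in range(len(b)):
            extend(i, j, "start", 0.0)
    return best


def exhaustive_dollo_losses(presence: dict[str, int], tree) -> int:
    """Minimal loss count over all single-gain ancestral assignments.

    Enumerates every binary state assignment to the internal nodes (tips
    fixed by the profile); a root in state 1 counts as the single gain on
    the root branch. Returns the minimum number of 1->0 edges among
    assignments with exactly one gain.
    """
    nodes = list(tree.preorder_node_iter())
    internal = [n for n in nodes if not n.is_leaf()]
    best = None
    for states in itertools.product([0, 1], repeat=len(internal)):
        assign = dict(zip((id(n) for n in internal), states))
        for n in nodes:
            if n.is_leaf():
                assign[id(n)] = 1 if presence[n.taxon.label] >= 1 else 0
        gains = assign[id(tree.seed_node)]
        losses = 0
        ok = True
        for n in nodes:
            for c in n.child_nodes():
                s, t = assign[id(n)], assign[id(c)]
                if s == 0 and t == 1:
                    gains += 1
                elif s == 1 and t == 0:
                    losses += 1
        if gains == 1 and (best is None or losses < best):
            best = losses
    assert best is not None, "profile must have at least one present tip"
    return best


def exhaustive_fitch_changes(presence: dict[str, int], tree) -> int:
    """Minimal total change count over all ancestral assignments."""
    nodes = list(tree.preorder_node_iter())
    internal = [n for n in nodes if not n.is_leaf()]
    best = None
    for states in itertools.product([0, 1], repeat=len(internal)):
        assign = dict(zip((id(n) for n in internal), states))
        for n in nodes:
            if n.is_leaf():
                assign[id(n)] = 1 if presence[n.taxon.label] >= 1 else 0
        changes = sum(
            1
            for n in nodes
            for c in n.child_nodes()
            if assign[id(n)] != assign[id(c)]
        )
        if best is None or changes < best:
            best = changes
    return best
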