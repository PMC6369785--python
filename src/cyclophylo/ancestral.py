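"""Ancestral-state reconstruction on a rooted tree under parsimony.

For each character the module computes, per node, the MPR set (states the
node takes in at least one most-parsimonious reconstruction, via a unit-cost
Sankoff inside/outside pass), plus one accelerated (ACCTRAN) and one delayed
(DELTRAN) resolution of the ambiguity, and turns the resolved assignments
into per-branch change lists from which synapomorphies are read off.

ACCTRAN follows the classical downpass-set rule (keep the parent's state
whenever it is in the child's Fitch downpass set), which pushes changes
rootward, favouring early gain plus reversal.  DELTRAN walks the tree in
preorder keeping the parent's state whenever that is consistent with
minimality (checked against the Sankoff subtree costs), which defers
changes tipward, favouring parallel late gains.  Both realise the Fitch
length exactly.

Nodes are identified by the frozenset of their descendant leaf labels, so
reports are invariant to leaf-order permutation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable

from .matrix import CharacterMatrix
from .tree import Cladogram, Node, TreeError

__all__ = [
    "ReconstructionReport",
    "BranchChange",
    "mpr_sets",
    "acctran",
    "deltran",
    "reconstruct",
    "synapomorphies",
]

INF = math.inf


@dataclass(frozen=True)
class BranchChange:
    """One state change on the branch subtending `branch` (a leaf set)."""

    branch: frozenset[str]
    character: str
    from_state: str
    to_state: str
    flag: str  # unambiguous | acctran-only | deltran-only | ambiguous


@dataclass
class ReconstructionReport:
    tree: Cladogram
    matrix: CharacterMatrix
    mpr: dict[str, dict[frozenset[str], frozenset[str]]]
    acctran_states: dict[str, dict[frozenset[str], str]]
    deltran_states: dict[str, dict[frozenset[str], str]]
    changes: list[BranchChange] = field(default_factory=list)

    def changes_on(self, branch: frozenset[str]) -> list[BranchChange]:
        return [c for c in self.changes if c.branch == branch]


def _require_rooted_binary(tree: Cladogram) -> None:
    if not tree.rooted:
        raise TreeError("ancestral reconstruction requires a rooted tree")
    for n in tree.postorder():
        if not n.is_leaf and len(n.children) != 2:
            raise TreeError("ancestral reconstruction requires a binary tree")


def _leaf_state_sets(
    matrix: CharacterMatrix, char_id: str
) -> tuple[dict[str, frozenset[str]], list[str]]:
    space = sorted(matrix.state_space(char_id))
    j = matrix.char_index(char_id)
    full = frozenset(space)
    out = {}
    for taxon, row in zip(matrix.taxa, matrix.cells):
        cv = row[j]
        out[taxon] = frozenset(cv.states) if cv.is_states else full
    return out, space


def _node_keys(tree: Cladogram) -> dict[int, frozenset[str]]:
    keys: dict[int, frozenset[str]] = {}
    for node in tree.postorder():
        if node.is_leaf:
            keys[id(node)] = frozenset([node.label])
        else:
            keys[id(node)] = frozenset().union(*(keys[id(c)] for c in node.children))
    return keys


def _sankoff_tables(tree, leaf_sets, space):
    """Unit-cost inside (subtree) and outside (rest-of-tree) cost tables."""
    k = len(space)
    down: dict[int, list[float]] = {}
    for node in tree.postorder():
        if node.is_leaf:
            allowed = leaf_sets[node.label]
            down[id(node)] = [0.0 if s in allowed else INF for s in space]
        else:
            costs = []
            for si in range(k):
                total = 0.0
                for c in tree_children(node):
                    dc = down[id(c)]
                    total += min(
                        dc[ti] + (0 if ti == si else 1) for ti in range(k)
                    )
                costs.append(total)
            down[id(node)] = costs
    up: dict[int, list[float]] = {id(tree.root): [0.0] * k}
    for node in tree.preorder():
        if node.is_leaf:
            continue
        for child in tree_children(node):
            others = [c for c in tree_children(node) if c is not child]
            uc = []
            for si in range(k):
                best = INF
                for ti in range(k):
                    val = up[id(node)][ti] + (0 if ti == si else 1)
                    for o in others:
                        do = down[id(o)]
                        val += min(
                            do[oi] + (0 if oi == ti else 1) for oi in range(k)
                        )
                    best = min(best, val)
                uc.append(best)
            up[id(child)] = uc
    return down, up


def tree_children(node: Node) -> list[Node]:
    return node.children


def mpr_sets(
    tree: Cladogram, matrix: CharacterMatrix
) -> dict[str, dict[frozenset[str], frozenset[str]]]:
    """Per character and node, the states taken in >= 1 most-parsimonious
    reconstruction (leaves included; an unambiguous leaf is its own
    singleton)."""
    _require_rooted_binary(tree)
    _check_leaves(tree, matrix)
    keys = _node_keys(tree)
    result: dict[str, dict[frozenset[str], frozenset[str]]] = {}
    for ch in matrix.characters:
        leaf_sets, space = _leaf_state_sets(matrix, ch)
        if len(space) <= 1:
            sets = {
                keys[id(n)]: frozenset(space) for n in tree.postorder()
            }
            result[ch] = sets
            continue
        down, up = _sankoff_tables(tree, leaf_sets, space)
        best = min(down[id(tree.root)])
        sets = {}
        for node in tree.postorder():
            d, u = down[id(node)], up[id(node)]
            sets[keys[id(node)]] = frozenset(
                space[si] for si in range(len(space)) if d[si] + u[si] == best
            )
        result[ch] = sets
    return result


def _fitch_downpass_sets(tree, leaf_sets):
    sets: dict[int, frozenset[str]] = {}
    for node in tree.postorder():
        if node.is_leaf:
            sets[id(node)] = leaf_sets[node.label]
        else:
            a, b = (sets[id(c)] for c in node.children)
            inter = a & b
            sets[id(node)] = inter if inter else a | b
    return sets


def acctran(tree: Cladogram, matrix: CharacterMatrix) -> dict[str, dict[frozenset[str], str]]:
    """Accelerated-transformation resolution (changes as rootward as possible)."""
    _require_rooted_binary(tree)
    _check_leaves(tree, matrix)
    keys = _node_keys(tree)
    out: dict[str, dict[frozenset[str], str]] = {}
    for ch in matrix.characters:
        leaf_sets, space = _leaf_state_sets(matrix, ch)
        if not space:
            out[ch] = {}
            continue
        down = _fitch_downpass_sets(tree, leaf_sets)
        states: dict[int, str] = {}
        for node in tree.preorder():
            s = down[id(node)]
            if node.parent is None:
                states[id(node)] = min(s)
            else:
                p = states[id(node.parent)]
                states[id(node)] = p if p in s else min(s)
        out[ch] = {keys[i]: st for i, st in states.items()}
    return out


def deltran(tree: Cladogram, matrix: CharacterMatrix) -> dict[str, dict[frozenset[str], str]]:
    """Delayed-transformation resolution (changes as tipward as possible).

    Preorder traceback over the Sankoff subtree costs: the parent's state
    is kept whenever doing so is consistent with overall minimality.
    """
    _require_rooted_binary(tree)
    _check_leaves(tree, matrix)
    keys = _node_keys(tree)
    out: dict[str, dict[frozenset[str], str]] = {}
    for ch in matrix.characters:
        leaf_sets, space = _leaf_state_sets(matrix, ch)
        if not space:
            out[ch] = {}
            continue
        down, _ = _sankoff_tables(tree, leaf_sets, space)
        k = len(space)
        states: dict[int, str] = {}
        for node in tree.preorder():
            d = down[id(node)]
            if node.parent is None:
                best = min(d)
                cands = [si for si in range(k) if d[si] == best]
            else:
                pi = space.index(states[id(node.parent)])
                best = min(d[si] + (0 if si == pi else 1) for si in range(k))
                cands = [
                    si for si in range(k) if d[si] + (0 if si == pi else 1) == best
                ]
                if pi in cands:
                    cands = [pi]
            states[id(node)] = space[min(cands)]
        out[ch] = {keys[i]: st for i, st in states.items()}
    return out


def _check_leaves(tree: Cladogram, matrix: CharacterMatrix) -> None:
    missing = sorted(tree.leaf_labels() - set(matrix.taxa))
    if missing:
        raise TreeError(f"leaves without matrix rows: {missing}")


def reconstruct(tree: Cladogram, matrix: CharacterMatrix) -> ReconstructionReport:
    """Full report: MPR sets, both resolutions, and flagged branch changes.

    A change is flagged ``unambiguous`` when the MPR sets at both ends of
    the branch are singletons (so every most-parsimonious reconstruction
    contains the identical change).  Changes on terminal branches of taxa
    scored missing or inapplicable for that character are never reported.
    """
    mpr = mpr_sets(tree, matrix)
    acc = acctran(tree, matrix)
    dlt = deltran(tree, matrix)
    keys = _node_keys(tree)
    changes: list[BranchChange] = []
    missing_leaf: dict[str, set[str]] = {
        ch: set() for ch in matrix.characters
    }
    for taxon, row in zip(matrix.taxa, matrix.cells):
        for ch, cv in zip(matrix.characters, row):
            if not cv.is_states:
                missing_leaf[ch].add(taxon)
    for node in tree.postorder():
        if node.parent is None:
            continue
        bkey = keys[id(node)]
        pkey = keys[id(node.parent)]
        for ch in matrix.characters:
            if node.is_leaf and node.label in missing_leaf[ch]:
                continue
            a_change = None
            if ch in acc and bkey in acc[ch] and acc[ch][pkey] != acc[ch][bkey]:
                a_change = (acc[ch][pkey], acc[ch][bkey])
            d_change = None
            if ch in dlt and bkey in dlt[ch] and dlt[ch][pkey] != dlt[ch][bkey]:
                d_change = (dlt[ch][pkey], dlt[ch][bkey])
            if a_change is None and d_change is None:
                continue
            unamb = (
                len(mpr[ch][pkey]) == 1
                and len(mpr[ch][bkey]) == 1
                and mpr[ch][pkey] != mpr[ch][bkey]
            )
            if unamb:
                flag = "unambiguous"
                frm, to = a_change
            elif a_change and d_change:
                flag = "ambiguous"
                frm, to = a_change
            elif a_change:
                flag = "acctran-only"
                frm, to = a_change
            else:
                flag = "deltran-only"
                frm, to = d_change
            changes.append(BranchChange(bkey, ch, frm, to, flag))
    return ReconstructionReport(
        tree=tree, matrix=matrix, mpr=mpr,
        acctran_states=acc, deltran_states=dlt, changes=changes,
    )


def synapomorphies(
    report: ReconstructionReport, clade: Iterable[str]
) -> list[BranchChange]:
    """Changes on the branch subtending the clade with the given leaf set."""
    key = frozenset(clade)
    node_keys = set(_node_keys(report.tree).values())
    if key not in node_keys:
        raise TreeError(f"no node subtends exactly {sorted(key)}")
    return report.changes_on(key)


def assignment_steps(
    tree: Cladogram, states: dict[frozenset[str], str]
) -> int:
    """Number of changes implied by one resolved assignment (oracle hook)."""
    keys = _node_keys(tree)
    steps = 0
    for node in tree.postorder():
        if node.parent is None:
            continue
        a = states.get(keys[id(node)])
        b = states.get(keys[id(node.parent)])
        if a is not None and b is not None and a != b:
            steps += 1
    return steps
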