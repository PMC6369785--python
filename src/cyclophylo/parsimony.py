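"""Fitch parsimony scoring, heuristic tree search, and consensus trees.

Characters are unordered and equally weighted.  Missing (``?``) and
inapplicable (``-``) cells enter tree scoring as full ambiguity over the
character's observed state set -- the classical treatment; the coding layer
(:mod:`cyclophylo.contingency`) is where the inapplicable distinction does
its work.  State sets are packed into integer bitmasks so that per-character
Fitch passes vectorise across the whole matrix.
"""

from __future__ import annotations

import itertools
import random
from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .matrix import CharacterMatrix
from .tree import Cladogram, Node, TreeError, tree_from_splits

__all__ = [
    "SearchSettings",
    "TreeScore",
    "fitch_length",
    "heuristic_search",
    "strict_consensus",
    "majority_consensus",
    "enumerate_unrooted_topologies",
    "exhaustive_search",
]


@dataclass
class SearchSettings:
    """Heuristic-search controls (random addition + branch swapping)."""

    n_replicates: int = 100
    swap: str = "TBR"  # one of NNI, SPR, TBR
    max_trees: int = 1000
    seed: int = 0
    constraint: None = None  # no topological constraint, as in the study

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.swap not in ("NNI", "SPR", "TBR"):
            raise ValueError(f"unknown swap algorithm {self.swap!r}")
        if self.constraint is not None:
            raise ValueError("topological constraints are not supported")


@dataclass
class TreeScore:
    total: int
    per_character: np.ndarray

    def __post_init__(self) -> None:
        assert self.total == int(self.per_character.sum())


# ---------------------------------------------------------------------------
# bitmask encoding
# ---------------------------------------------------------------------------

def character_masks(matrix: CharacterMatrix) -> np.ndarray:
    """(n_taxa, n_characters) uint32 bitmask encoding of the matrix.

    Bit b of column j is state ``sorted(state_space(j))[b]``.  Missing,
    inapplicable, and fully ambiguous cells carry the full observed mask.
    """
    n, m = matrix.n_taxa, matrix.n_characters
    masks = np.zeros((n, m), dtype=np.uint32)
    for j, ch in enumerate(matrix.characters):
        space = sorted(matrix.state_space(ch))
        bit = {s: 1 << i for i, s in enumerate(space)}
        full = (1 << len(space)) - 1 if space else 1
        for i in range(n):
            cv = matrix.cells[i][j]
            if cv.is_states:
                masks[i, j] = sum(bit[s] for s in cv.states)
            else:
                masks[i, j] = full
    return masks


class _FitchScorer:
    """Caches the matrix encoding for repeated scoring during search."""

    def __init__(self, matrix: CharacterMatrix):
        self.matrix = matrix
        self.masks = character_masks(matrix)
        self.row = {t: i for i, t in enumerate(matrix.taxa)}

    def per_character_steps(self, tree: Cladogram) -> np.ndarray:
        steps = np.zeros(self.matrix.n_characters, dtype=np.int64)
        cache: dict[int, np.ndarray] = {}
        root = tree.root
        for node in root.postorder():
            if node.is_leaf:
                if node.label not in self.row:
                    raise TreeError(f"leaf {node.label!r} has no matrix row")
                cache[id(node)] = self.masks[self.row[node.label]]
                continue
            kids = node.children
            if node is root and len(kids) == 3:
                # trifurcating root of an unrooted tree: fold as ((b,c),a),
                # a valid binary rooting of the same unrooted tree
                a, b, c = (cache[id(k)] for k in kids)
                inter = b & c
                empty = inter == 0
                steps += empty
                state = np.where(empty, b | c, inter)
                inter = state & a
                empty = inter == 0
                steps += empty
                cache[id(node)] = np.where(empty, state | a, inter)
                continue
            if len(kids) != 2:
                raise TreeError(
                    "Fitch scoring requires a binary tree "
                    f"(node with {len(kids)} children)"
                )
            a, b = cache[id(kids[0])], cache[id(kids[1])]
            inter = a & b
            empty = inter == 0
            steps += empty
            cache[id(node)] = np.where(empty, a | b, inter)
        return steps

    def score(self, tree: Cladogram) -> int:
        return int(self.per_character_steps(tree).sum())


def fitch_length(tree: Cladogram, matrix: CharacterMatrix) -> TreeScore:
    """Fitch parsimony length of `tree` under `matrix`.

    Invariant to rooting; polymorphic cells enter as their state set.
    """
    per_char = _FitchScorer(matrix).per_character_steps(tree)
    return TreeScore(total=int(per_char.sum()), per_character=per_char)


# ---------------------------------------------------------------------------
# tree rearrangements (on leaf-rooted binary representations)
# ---------------------------------------------------------------------------

def _postorder_index(tree: Cladogram) -> list[Node]:
    return list(tree.root.postorder())


def _copy_with_target(tree: Cladogram, target: Node) -> tuple[Cladogram, Node]:
    nodes = _postorder_index(tree)
    idx = next(i for i, n in enumerate(nodes) if n is target)
    clone = tree.copy()
    return clone, _postorder_index(clone)[idx]


def _attach_positions(root: Node) -> list[Node]:
    """Nodes whose parent edge is a distinct edge of the unrooted tree."""
    out = []
    skip_first_root_child = len(root.children) == 2
    for node in root.preorder():
        if node is root:
            continue
        if skip_first_root_child and node is root.children[0]:
            continue  # same unrooted edge as its sibling
        out.append(node)
    return out


def _insert_subtree(at: Node, subtree: Node) -> Node:
    """Graft `subtree` onto the edge above `at`; returns the new junction."""
    parent = at.parent
    idx = parent.children.index(at)
    junction = Node()
    parent.children[idx] = junction
    junction.parent = parent
    junction.add_child(at)
    junction.add_child(subtree)
    return junction


def nni_neighbors(tree: Cladogram):
    """Yield all nearest-neighbor-interchange neighbors (unrooted).

    Internal edges are edges above an internal node whose parent is also
    internal and not the edge-point root; each yields its two interchanges.
    """
    nodes = _postorder_index(tree)
    for v in nodes:
        if v.is_leaf or v.parent is None or v.parent is tree.root:
            continue
        for child_slot in (0, 1):
            clone, v2 = _copy_with_target(tree, v)
            u = v2.parent
            s = next(c for c in u.children if c is not v2)
            a = v2.children[child_slot]
            ui, vi = u.children.index(s), v2.children.index(a)
            u.children[ui], v2.children[vi] = a, s
            a.parent, s.parent = u, v2
            yield clone


def spr_neighbors(tree: Cladogram, tbr: bool = False):
    """Yield subtree-prune-regraft (or TBR) neighbors of an unrooted tree."""
    nodes = _postorder_index(tree)
    for v in nodes:
        if v.parent is None:
            continue
        clone, v2 = _copy_with_target(tree, v)
        parent = v2.parent
        parent.remove_child(v2)
        remainder = Cladogram(clone.root, rooted=False)
        remainder.suppress_unifurcations()
        if remainder.root.is_leaf or (
            len(remainder.root.children) == 1 and remainder.root.children[0].is_leaf
        ):
            continue  # nothing left to attach into
        subtree_variants = [v2]
        if tbr and not v2.is_leaf:
            subtree_variants = _rerootings(v2)
        positions = _attach_positions(remainder.root)
        for pos_idx in range(len(positions)):
            for var_idx in range(len(subtree_variants)):
                rem2, pos2 = _copy_with_target(remainder, positions[pos_idx])
                sub2 = subtree_variants[var_idx].copy()
                sub2.parent = None
                _insert_subtree(pos2, sub2)
                yield Cladogram(rem2.root, rooted=False)


def _rerootings(subtree_root: Node) -> list[Node]:
    """All distinct rootings of a pruned subtree (for TBR reconnection)."""
    base = Cladogram(subtree_root.copy(), rooted=False)
    out = [subtree_root]
    seen = {Cladogram(subtree_root, rooted=True).clades()}
    nodes = _postorder_index(base)
    for i, n in enumerate(nodes):
        if n.parent is None:
            continue
        clone, target = _copy_with_target(base, n)
        clone.reroot_on_edge(target)
        key = Cladogram(clone.root, rooted=True).clades()
        if key not in seen:
            seen.add(key)
            out.append(clone.root)
    return out


def _neighbors(tree: Cladogram, swap: str):
    if swap == "NNI":
        return nni_neighbors(tree)
    return spr_neighbors(tree, tbr=(swap == "TBR"))


# ---------------------------------------------------------------------------
# heuristic search
# ---------------------------------------------------------------------------

def _random_addition_tree(
    taxa: list[str], scorer: _FitchScorer, rng: random.Random
) -> Cladogram:
    order = list(taxa)
    rng.shuffle(order)
    root = Node(children=[Node(order[0]), Node(children=[Node(order[1]), Node(order[2])])])
    tree = Cladogram(root, rooted=False)
    for label in order[3:]:
        best = None
        best_score = None
        for pos in _attach_positions(tree.root):
            clone, pos2 = _copy_with_target(tree, pos)
            _insert_subtree(pos2, Node(label))
            cand = Cladogram(clone.root, rooted=False)
            sc = scorer.score(cand)
            if best_score is None or sc < best_score:
                best, best_score = cand, sc
        tree = best
    return tree


def heuristic_search(
    matrix: CharacterMatrix, settings: SearchSettings | None = None
) -> tuple[list[Cladogram], TreeScore]:
    """Random-addition + branch-swapping search for minimum-length trees.

    Each replicate hill-climbs until no neighbor improves, then the
    equal-length plateau around each optimum is explored breadth-first so
    that distinct co-optimal trees (up to ``max_trees``) are collected.
    Fully deterministic given ``settings.seed``.
    """
    settings = settings or SearchSettings()
    if matrix.n_taxa < 4:
        raise ValueError("heuristic search requires at least 4 taxa")
    scorer = _FitchScorer(matrix)
    best_score: int | None = None
    best_trees: dict = {}
    for rep in range(settings.n_replicates):
        rng = random.Random(settings.seed * 100003 + rep)
        tree = _random_addition_tree(matrix.taxa, scorer, rng)
        score = scorer.score(tree)
        improved = True
        while improved:
            improved = False
            for cand in _neighbors(tree, settings.swap):
                sc = scorer.score(cand)
                if sc < score:
                    tree, score = cand, sc
                    improved = True
                    break
        if best_score is not None and score > best_score:
            continue
        if best_score is None or score < best_score:
            best_score = score
            best_trees = {}
        # explore the equal-length plateau around this optimum
        frontier = [tree]
        best_trees.setdefault(tree.topology_key(), tree)
        while frontier and len(best_trees) < settings.max_trees:
            current = frontier.pop(0)
            for cand in _neighbors(current, settings.swap):
                if scorer.score(cand) != best_score:
                    continue
                key = cand.topology_key()
                if key not in best_trees:
                    best_trees[key] = cand
                    frontier.append(cand)
                    if len(best_trees) >= settings.max_trees:
                        break
    trees = list(best_trees.values())
    per_char = scorer.per_character_steps(trees[0])
    return trees, TreeScore(total=best_score, per_character=per_char)


# ---------------------------------------------------------------------------
# exhaustive enumeration (oracle-grade, small taxon counts)
# ---------------------------------------------------------------------------

def enumerate_unrooted_topologies(taxa: list[str]):
    """Yield every unrooted binary topology over `taxa` ((2n-5)!! trees)."""
    if len(taxa) < 3:
        raise ValueError("need at least 3 taxa")

    def grow(tree: Cladogram, remaining: list[str]):
        if not remaining:
            yield tree
            return
        label = remaining[0]
        for pos in _attach_positions(tree.root):
            clone, pos2 = _copy_with_target(tree, pos)
            _insert_subtree(pos2, Node(label))
            yield from grow(Cladogram(clone.root, rooted=False), remaining[1:])

    root = Node(
        children=[Node(taxa[0]), Node(children=[Node(taxa[1]), Node(taxa[2])])]
    )
    yield from grow(Cladogram(root, rooted=False), list(taxa[3:]))


def exhaustive_search(matrix: CharacterMatrix) -> tuple[list[Cladogram], int]:
    """Minimum-length trees by complete enumeration (oracle for tests)."""
    scorer = _FitchScorer(matrix)
    best: list[Cladogram] = []
    best_score: int | None = None
    for tree in enumerate_unrooted_topologies(matrix.taxa):
        sc = scorer.score(tree)
        if best_score is None or sc < best_score:
            best, best_score = [tree], sc
        elif sc == best_score:
            best.append(tree)
    return best, best_score


# ---------------------------------------------------------------------------
# consensus trees
# ---------------------------------------------------------------------------

def _split_counts(trees: list[Cladogram]) -> tuple[Counter, frozenset[str]]:
    if not trees:
        raise ValueError("no trees given")
    leaves = trees[0].leaf_labels()
    for t in trees[1:]:
        if t.leaf_labels() != leaves:
            raise TreeError("consensus requires a shared leaf set")
    counts: Counter = Counter()
    for t in trees:
        counts.update(t.bipartitions())
    return counts, leaves


def strict_consensus(trees: list[Cladogram]) -> Cladogram:
    """Tree displaying exactly the splits present in every input tree."""
    counts, leaves = _split_counts(trees)
    splits = [s for s, c in counts.items() if c == len(trees)]
    return tree_from_splits(splits, leaves)


def majority_consensus(
    trees: list[Cladogram], threshold: float = 0.5
) -> tuple[Cladogram, dict[frozenset[str], float]]:
    """Majority-rule consensus: splits with frequency strictly > threshold.

    Returns the tree and the frequency of each retained split.
    """
    if not 0.5 <= threshold < 1.0:
        raise ValueError("threshold must be in [0.5, 1)")
    counts, leaves = _split_counts(trees)
    n = len(trees)
    kept = {s: c / n for s, c in counts.items() if c / n > threshold}
    return tree_from_splits(list(kept), leaves), kept
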