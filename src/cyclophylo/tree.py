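"""Lightweight phylogenetic trees.

The package keeps its own mutable node/tree structure because the hot loops
(Fitch scoring inside heuristic search, MCMC topology moves) need cheap
in-place rearrangement and index-based access; conversion to and from
Newick goes through dendropy so the on-disk format handling is standard.

Conventions
-----------
* A tree is always stored with a root node.  ``rooted=True`` means the root
  is meaningful (outgroup-rooted, or a time tree); ``rooted=False`` means
  the structure is an arbitrary rooting of an unrooted tree and only its
  bipartitions matter.
* Leaves carry a ``label``; internal nodes have ``label=None``.
* ``length`` is the length of the edge above a node (``None`` if absent).
* ``age`` (node age, units of time before present) and ``is_fossil`` are
  used by time trees only and default to ``None``/``False``.
"""

from __future__ import annotations

import itertools
from typing import Callable, Iterable, Iterator, Sequence

import dendropy

__all__ = ["Node", "Cladogram", "TreeError"]


class TreeError(ValueError):
    pass


class Node:
    __slots__ = ("children", "parent", "label", "length", "age", "is_fossil")

    def __init__(
        self,
        label: str | None = None,
        length: float | None = None,
        children: list["Node"] | None = None,
    ) -> None:
        self.label = label
        self.length = length
        self.children: list[Node] = []
        self.parent: Node | None = None
        self.age: float | None = None
        self.is_fossil: bool = False
        if children:
            for c in children:
                self.add_child(c)

    # -- structure -------------------------------------------------------
    def add_child(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    def remove_child(self, child: "Node") -> None:
        self.children.remove(child)
        child.parent = None

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def postorder(self) -> Iterator["Node"]:
        # iterative to cope with pectinate trees beyond recursion depth
        stack: list[tuple[Node, bool]] = [(self, False)]
        while stack:
            node, expanded = stack.pop()
            if expanded or node.is_leaf:
                yield node
            else:
                stack.append((node, True))
                for c in reversed(node.children):
                    stack.append((c, False))

    def preorder(self) -> Iterator["Node"]:
        stack = [self]
        while stack:
            node = stack.pop()
            yield node
            for c in reversed(node.children):
                stack.append(c)

    def leaves(self) -> list["Node"]:
        return [n for n in self.postorder() if n.is_leaf]

    def leaf_labels(self) -> frozenset[str]:
        return frozenset(n.label for n in self.leaves())

    def copy(self) -> "Node":
        mapping: dict[int, Node] = {}
        for node in self.postorder():
            clone = Node(node.label, node.length)
            clone.age = node.age
            clone.is_fossil = node.is_fossil
            for c in node.children:
                clone.add_child(mapping[id(c)])
            mapping[id(node)] = clone
        return mapping[id(self)]


class Cladogram:
    """A rooted or unrooted tree over labelled leaves."""

    def __init__(self, root: Node, rooted: bool = True) -> None:
        self.root = root
        self.rooted = rooted
        self._validate()

    def _validate(self) -> None:
        labels = [n.label for n in self.root.postorder() if n.is_leaf]
        if len(labels) != len(set(labels)):
            dupes = sorted({l for l in labels if labels.count(l) > 1})
            raise TreeError(f"duplicate leaf labels: {dupes}")
        if any(l is None for l in labels):
            raise TreeError("unlabelled leaf")

    # -- constructors ----------------------------------------------------
    @classmethod
    def from_newick(cls, newick: str, rooted: bool | None = None) -> "Cladogram":
        try:
            dtree = dendropy.Tree.get(
                data=newick,
                schema="newick",
                suppress_internal_node_taxa=True,
                preserve_underscores=True,
            )
        except Exception as exc:  # dendropy raises several parse error types
            raise TreeError(f"malformed Newick: {exc}") from exc
        root = _from_dendropy(dtree.seed_node)
        if rooted is None:
            rooted = bool(dtree.is_rooted)
        return cls(root, rooted=rooted)

    @classmethod
    def from_nested(cls, nested, rooted: bool = True) -> "Cladogram":
        """Build from nested tuples/lists of leaf labels, e.g. ((\"A\",\"B\"),\"C\")."""

        def build(obj) -> Node:
            if isinstance(obj, str):
                return Node(obj)
            node = Node()
            for sub in obj:
                node.add_child(build(sub))
            return node

        return cls(build(nested), rooted=rooted)

    # -- export ----------------------------------------------------------
    def to_newick(self, lengths: bool = True, comments: Callable | None = None) -> str:
        def fmt(node: Node) -> str:
            if node.is_leaf:
                s = _quote_label(node.label)
            else:
                s = "(" + ",".join(fmt(c) for c in node.children) + ")"
            if comments is not None:
                note = comments(node)
                if note:
                    s += f"[&{note}]"
            if lengths and node.length is not None:
                s += f":{node.length:.10g}"
            return s

        return fmt(self.root) + ";"

    def to_dendropy(self, taxon_namespace=None) -> dendropy.Tree:
        return dendropy.Tree.get(
            data=self.to_newick(),
            schema="newick",
            taxon_namespace=taxon_namespace,
            preserve_underscores=True,
            rooting="force-rooted" if self.rooted else "force-unrooted",
        )

    # -- basic queries ---------------------------------------------------
    def copy(self) -> "Cladogram":
        return Cladogram(self.root.copy(), rooted=self.rooted)

    def leaves(self) -> list[Node]:
        return self.root.leaves()

    def leaf_labels(self) -> frozenset[str]:
        return self.root.leaf_labels()

    @property
    def n_leaves(self) -> int:
        return len(self.leaves())

    def postorder(self) -> Iterator[Node]:
        return self.root.postorder()

    def preorder(self) -> Iterator[Node]:
        return self.root.preorder()

    def find_leaf(self, label: str) -> Node:
        for n in self.leaves():
            if n.label == label:
                return n
        raise KeyError(f"no leaf labelled {label!r}")

    def is_binary(self) -> bool:
        for n in self.postorder():
            if not n.is_leaf and len(n.children) != 2:
                return False
        return True

    # -- bipartitions ----------------------------------------------------
    def bipartitions(self) -> frozenset[frozenset[str]]:
        """Nontrivial splits of the unrooted shape of this tree.

        Each split is canonicalised as the side *not* containing the
        lexicographically smallest leaf label.
        """
        all_leaves = self.leaf_labels()
        ref = min(all_leaves)
        n = len(all_leaves)
        splits: set[frozenset[str]] = set()
        below: dict[int, frozenset[str]] = {}
        for node in self.root.postorder():
            if node.is_leaf:
                below[id(node)] = frozenset([node.label])
            else:
                below[id(node)] = frozenset().union(
                    *(below[id(c)] for c in node.children)
                )
            if node is self.root:
                continue
            side = below[id(node)]
            if ref in side:
                side = all_leaves - side
            if 2 <= len(side) <= n - 2:
                splits.add(side)
        return frozenset(splits)

    def clades(self) -> frozenset[frozenset[str]]:
        """Leaf sets of all internal nodes (rooted-tree clades)."""
        out: set[frozenset[str]] = set()
        below: dict[int, frozenset[str]] = {}
        for node in self.root.postorder():
            if node.is_leaf:
                below[id(node)] = frozenset([node.label])
            else:
                below[id(node)] = frozenset().union(
                    *(below[id(c)] for c in node.children)
                )
                out.add(below[id(node)])
        return frozenset(out)

    def topology_key(self):
        """Hashable identity: splits for unrooted trees, clades for rooted."""
        if self.rooted:
            return ("rooted", self.leaf_labels(), self.clades())
        return ("unrooted", self.leaf_labels(), self.bipartitions())

    def rf_distance(self, other: "Cladogram") -> int:
        """Robinson-Foulds distance (symmetric difference of splits)."""
        if self.leaf_labels() != other.leaf_labels():
            raise TreeError("trees have different leaf sets")
        return len(self.bipartitions() ^ other.bipartitions())

    def has_clade(self, labels: Iterable[str]) -> bool:
        """Monophyly test: is `labels` one side of some edge (unrooted) or
        a clade (rooted)?"""
        group = frozenset(labels)
        all_leaves = self.leaf_labels()
        if not group <= all_leaves:
            missing = sorted(group - all_leaves)
            raise TreeError(f"taxa not in tree: {missing}")
        if group == all_leaves or len(group) == 1:
            return True
        if self.rooted:
            return group in self.clades()
        ref = min(all_leaves)
        side = all_leaves - group if ref in group else group
        return len(side) in (1, len(all_leaves) - 1) or side in self.bipartitions()

    # -- manipulation ----------------------------------------------------
    def suppress_unifurcations(self) -> None:
        """Collapse degree-2 internal nodes, summing edge lengths."""
        changed = True
        while changed:
            changed = False
            for node in list(self.root.postorder()):
                if node.is_leaf or len(node.children) != 1:
                    continue
                child = node.children[0]
                if node.parent is None:
                    # root with single child: child becomes root
                    child.parent = None
                    child.length = None
                    self.root = child
                else:
                    parent = node.parent
                    idx = parent.children.index(node)
                    if node.length is not None and child.length is not None:
                        child.length = node.length + child.length
                    elif node.length is not None:
                        child.length = node.length
                    parent.children[idx] = child
                    child.parent = parent
                changed = True

    def reroot_on_edge(self, node: Node) -> None:
        """Re-root on the edge above `node`, making it a child of a new root."""
        if node.parent is None:
            return
        half = node.length / 2 if node.length is not None else None
        new_root = Node()
        # reverse parent pointers from node's parent up to old root
        path = []
        p = node.parent
        while p is not None:
            path.append(p)
            p = p.parent
        node.parent.remove_child(node)
        new_root.add_child(node)
        node.length = half
        prev = new_root
        prev_len = half
        for anc in path:
            parent = anc.parent
            if parent is not None:
                parent.remove_child(anc)
            anc_len = anc.length
            prev.add_child(anc)
            anc.length = prev_len
            prev_len = anc_len
            prev = anc
        self.root = new_root
        self.suppress_unifurcations()

    def root_on_outgroup(self, outgroup: Sequence[str]) -> "Cladogram":
        """Return a rooted copy with the outgroup on one side of the root.

        The outgroup must be monophyletic in the unrooted shape (or a single
        taxon).
        """
        group = frozenset(outgroup)
        tree = self.copy()
        all_leaves = tree.leaf_labels()
        if not group <= all_leaves:
            raise TreeError(f"outgroup taxa not in tree: {sorted(group - all_leaves)}")
        if not (len(group) == 1 or Cladogram(tree.root, rooted=False).has_clade(group)):
            raise TreeError("outgroup is not monophyletic on this tree")
        # find an edge whose below-set equals the group or its complement
        below: dict[int, frozenset[str]] = {}
        target = None
        for node in tree.root.postorder():
            if node.is_leaf:
                below[id(node)] = frozenset([node.label])
            else:
                below[id(node)] = frozenset().union(
                    *(below[id(c)] for c in node.children)
                )
            if node is not tree.root and below[id(node)] in (group, all_leaves - group):
                target = node
        if target is None:
            raise TreeError("could not locate outgroup edge")
        tree.reroot_on_edge(target)
        tree.rooted = True
        return tree


def _from_dendropy(dnode) -> Node:
    label = None
    if dnode.taxon is not None:
        label = dnode.taxon.label
    elif dnode.is_leaf():
        label = dnode.label
    node = Node(label=label, length=dnode.edge.length)
    for child in dnode.child_nodes():
        node.add_child(_from_dendropy(child))
    return node


def _quote_label(label: str) -> str:
    if any(ch in label for ch in " (),:;[]'"):
        return "'" + label.replace("'", "''") + "'"
    return label


def tree_from_splits(
    splits: Iterable[frozenset[str]], leaves: Iterable[str]
) -> Cladogram:
    """Build the (possibly polytomous) unrooted tree displaying the given
    pairwise-compatible splits.

    Splits must be canonicalised as sides not containing the reference
    (lexicographically smallest) leaf.
    """
    all_leaves = frozenset(leaves)
    ref = min(all_leaves)
    groups = sorted(set(splits), key=len)
    for a, b in itertools.combinations(groups, 2):
        if a & b and not (a <= b or b <= a):
            raise TreeError("splits are not pairwise compatible")
    # top-level components, keyed by their leaf sets; splits are processed
    # smallest-first so components inside a split are disjoint and complete
    placed: dict[frozenset[str], Node] = {
        frozenset([l]): Node(l) for l in all_leaves if l != ref
    }
    for g in groups:
        node = Node()
        for s in [s for s in placed if s <= g]:
            node.add_child(placed.pop(s))
        placed[g] = node
    root = Node()
    root.add_child(Node(ref))
    for node in placed.values():
        root.add_child(node)
    return Cladogram(root, rooted=False)
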