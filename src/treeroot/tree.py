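"""Weighted-tree representation, newick I/O, and rerooting at edge points.

The rooting algorithms in this package all operate on a minimal rooted-tree
structure: nodes with an ordered child list and a branch length to the
parent.  An unrooted tree is represented, as is conventional in newick
files, by a rooted tree whose base node has three (or more) children; all
algorithms treat the initial rooting as arbitrary.

Newick parsing is delegated to dendropy; writing is done here so that the
output precision and child order are fully under our control.
"""

from __future__ import annotations

import io
import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Iterator, TextIO

import dendropy

__all__ = [
    "Node",
    "WeightedTree",
    "RootPosition",
    "NewickParseError",
    "TreeStructureError",
    "parse_newick",
    "read_newick",
    "write_newick",
    "tree_to_newick",
    "reroot_at",
    "tip_distances",
    "tip_distance_stats",
    "var_at_position",
]


class NewickParseError(ValueError):
    """Malformed newick input, or branch lengths missing/invalid."""


class TreeStructureError(ValueError):
    """A tree violates the structural contract of an operation."""


class Node:
    """A node of a rooted weighted tree.

    ``edge_length`` is the length of the branch to the parent (``None`` for
    the root).  ``children`` is ordered and the order is preserved by
    newick round-trips.
    """

    __slots__ = ("label", "edge_length", "children", "parent")

    def __init__(self, label: str = "", edge_length: float | None = None):
        self.label = label
        self.edge_length = edge_length
        self.children: list[Node] = []
        self.parent: Node | None = None

    def add_child(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        kind = "leaf" if self.is_leaf else f"internal({len(self.children)})"
        return f"<Node {self.label or '?'} {kind} e={self.edge_length}>"


@dataclass(frozen=True)
class RootPosition:
    """A point on an edge: ``offset`` measured from the parent-side node.

    ``offset == 0`` denotes the parent node itself, ``offset == e`` the
    child node; rerooting at those offsets roots at the existing node
    rather than creating a degree-2 vertex.
    """

    parent: Node
    child: Node
    offset: float

    @property
    def edge(self) -> tuple[Node, Node]:
        return (self.parent, self.child)

    @property
    def edge_length(self) -> float:
        return float(self.child.edge_length)

    def validate(self) -> None:
        if self.child.parent is not self.parent:
            raise TreeStructureError("RootPosition edge endpoints are not parent/child")
        e = self.edge_length
        if not (-1e-12 <= self.offset <= e + 1e-12):
            raise ValueError(
                f"offset {self.offset} outside [0, {e}] on edge to "
                f"{self.child.label or '<internal>'}"
            )


class WeightedTree:
    """A rooted tree with non-negative branch lengths."""

    def __init__(self, root: Node):
        if root is None:
            raise TreeStructureError("tree has no root")
        self.root = root

    # -- traversal ---------------------------------------------------------
    def preorder(self) -> Iterator[Node]:
        stack = [self.root]
        while stack:
            u = stack.pop()
            yield u
            stack.extend(reversed(u.children))

    def postorder(self) -> Iterator[Node]:
        out: list[Node] = []
        stack = [self.root]
        while stack:
            u = stack.pop()
            out.append(u)
            stack.extend(u.children)
        return iter(reversed(out))

    def edges(self) -> Iterator[tuple[Node, Node]]:
        """(parent, child) pairs in preorder."""
        for u in self.preorder():
            if u.parent is not None:
                yield (u.parent, u)

    def leaves(self) -> list[Node]:
        return [u for u in self.preorder() if u.is_leaf]

    @property
    def n_leaves(self) -> int:
        return sum(1 for u in self.preorder() if u.is_leaf)

    @property
    def leaf_labels(self) -> list[str]:
        return [u.label for u in self.leaves()]

    def find_leaf(self, label: str) -> Node:
        for u in self.leaves():
            if u.label == label:
                return u
        raise KeyError(f"leaf {label!r} not found")

    def total_length(self) -> float:
        return sum(u.edge_length for u in self.preorder() if u.parent is not None)

    # -- copying -----------------------------------------------------------
    def copy(self) -> "WeightedTree":
        tree, _ = self.copy_with_map()
        return tree

    def copy_with_map(self) -> tuple["WeightedTree", dict[Node, Node]]:
        """Deep copy; the map sends original nodes to their copies."""
        mapping: dict[Node, Node] = {}
        new_root = Node(self.root.label, self.root.edge_length)
        mapping[self.root] = new_root
        stack = [self.root]
        while stack:
            u = stack.pop()
            cu = mapping[u]
            for v in u.children:
                cv = Node(v.label, v.edge_length)
                cu.add_child(cv)
                mapping[v] = cv
                stack.append(v)
        return WeightedTree(new_root), mapping

    # -- validation --------------------------------------------------------
    def validate(self) -> None:
        seen_labels: set[str] = set()
        for u in self.preorder():
            if u.parent is None:
                if u is not self.root:
                    raise TreeStructureError("non-root node without parent")
            else:
                e = u.edge_length
                if e is None or not math.isfinite(e):
                    raise TreeStructureError(
                        f"non-finite branch length on edge to {u.label or '<internal>'}"
                    )
                if e < 0:
                    raise TreeStructureError(
                        f"negative branch length {e} on edge to {u.label or '<internal>'}"
                    )
            if u.is_leaf:
                if not u.label:
                    raise TreeStructureError("leaf without a label")
                if u.label in seen_labels:
                    raise TreeStructureError(f"duplicate leaf label {u.label!r}")
                seen_labels.add(u.label)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"<WeightedTree n={self.n_leaves}>"


# ---------------------------------------------------------------------------
# newick I/O
# ---------------------------------------------------------------------------

def _convert_dendropy(dtree: dendropy.Tree, clamp_negative: bool) -> WeightedTree:
    droot = dtree.seed_node

    def node_name(dnode) -> str:
        if dnode.taxon is not None:
            return dnode.taxon.label or ""
        return dnode.label or ""

    root = Node(node_name(droot))
    stack = [(droot, root)]
    while stack:
        dnode, node = stack.pop()
        for dchild in dnode.child_nodes():
            length = dchild.edge.length
            if length is None:
                raise NewickParseError(
                    "missing branch length on edge to "
                    f"{node_name(dchild) or '<internal node>'}"
                )
            length = float(length)
            if length < 0:
                if clamp_negative:
                    warnings.warn(
                        f"negative branch length {length} on edge to "
                        f"{node_name(dchild) or '<internal node>'} clamped to 0",
                        stacklevel=3,
                    )
                    length = 0.0
                else:
                    raise NewickParseError(
                        f"negative branch length {length} on edge to "
                        f"{node_name(dchild) or '<internal node>'}"
                    )
            child = node.add_child(Node(node_name(dchild), length))
            stack.append((dchild, child))
    tree = WeightedTree(root)
    tree.validate()
    return tree


def parse_newick(text: str, clamp_negative: bool = False) -> WeightedTree:
    """Parse a single newick string into a :class:`WeightedTree`.

    All branch lengths must be present (the rooting algorithms are
    meaningless without them).  Negative lengths are rejected unless
    ``clamp_negative`` replaces them with 0 (with a warning).
    """
    text = text.strip()
    if not text:
        raise NewickParseError("empty newick string")
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several error types
        raise NewickParseError(f"malformed newick: {exc}") from exc
    return _convert_dendropy(dtree, clamp_negative)


def read_newick(source: TextIO | str, clamp_negative: bool = False) -> list[WeightedTree]:
    """Read one tree per non-blank line from a text stream or string."""
    if isinstance(source, str):
        source = io.StringIO(source)
    trees: list[WeightedTree] = []
    for lineno, line in enumerate(source, start=1):
        line = line.strip()
        if not line:
            continue
        try:
            trees.append(parse_newick(line, clamp_negative=clamp_negative))
        except NewickParseError as exc:
            raise NewickParseError(f"line {lineno}: {exc}") from exc
    return trees


def _fmt(x: float) -> str:
    return format(float(x), ".12g")


def tree_to_newick(tree: WeightedTree) -> str:
    """Serialize to a single ';'-terminated newick line (12 sig. digits)."""
    if tree.root is None or (tree.root.is_leaf and not tree.root.label):
        raise TreeStructureError("cannot serialize an empty tree")
    parts: list[str] = []
    # iterative traversal: (node, child_index)
    stack: list[tuple[Node, int]] = [(tree.root, 0)]
    while stack:
        node, idx = stack.pop()
        if node.is_leaf:
            parts.append(node.label)
            if node.edge_length is not None:
                parts.append(f":{_fmt(node.edge_length)}")
            continue
        if idx == 0:
            parts.append("(")
            stack.append((node, 1))
            stack.append((node.children[0], 0))
        elif idx <= len(node.children) - 1:
            parts.append(",")
            stack.append((node, idx + 1))
            stack.append((node.children[idx], 0))
        else:
            parts.append(")")
            parts.append(node.label)
            if node.parent is not None and node.edge_length is not None:
                parts.append(f":{_fmt(node.edge_length)}")
    return "".join(parts) + ";"


def write_newick(trees: WeightedTree | Iterable[WeightedTree], sink: TextIO) -> None:
    """Write one newick line per tree."""
    if isinstance(trees, WeightedTree):
        trees = [trees]
    for tree in trees:
        sink.write(tree_to_newick(tree))
        sink.write("\n")


# ---------------------------------------------------------------------------
# rerooting
# ---------------------------------------------------------------------------

def _reroot_at_node(tree: WeightedTree, new_root: Node) -> WeightedTree:
    """Re-orient ``tree`` in place so that ``new_root`` is the root.

    If the former root is left with a single child (it was a bifurcating
    base), it is spliced out and the two incident branch lengths merged.
    """
    chain: list[Node] = []
    node: Node | None = new_root
    while node is not None:
        chain.append(node)
        node = node.parent
    old_root = chain[-1]
    if new_root is old_root:
        return tree
    lengths = [chain[i].edge_length for i in range(len(chain) - 1)]
    for i in range(len(chain) - 1):
        child, par = chain[i], chain[i + 1]
        par.children.remove(child)
        child.children.append(par)
        par.parent = child
        par.edge_length = lengths[i]
    new_root.parent = None
    new_root.edge_length = None
    # splice out an old bifurcating base that became a degree-2 pass-through
    if len(old_root.children) == 1:
        only = old_root.children[0]
        grand = old_root.parent
        only.edge_length = only.edge_length + old_root.edge_length
        only.parent = grand
        grand.children[grand.children.index(old_root)] = only
        old_root.children = []
        old_root.parent = None
    return WeightedTree(new_root)


def reroot_at(tree: WeightedTree, pos: RootPosition) -> WeightedTree:
    """Return a new tree rooted at ``pos``; the input tree is left intact.

    Splits the edge ``(u, v)`` at distance ``offset`` from ``u`` by a new
    root vertex with branch lengths ``offset`` and ``e - offset`` on its
    two sides, then directs all edges away from it.  An offset of exactly
    0 (or the full edge length, for an internal child) roots at the
    existing node instead of creating a degree-2 vertex.
    """
    pos.validate()
    copy, mapping = tree.copy_with_map()
    u = mapping[pos.parent]
    v = mapping[pos.child]
    e = float(v.edge_length)
    x = float(pos.offset)
    tol = 1e-12 * max(1.0, e)
    if x <= tol:
        return _reroot_at_node(copy, u)
    if x >= e - tol and not v.is_leaf:
        return _reroot_at_node(copy, v)
    # interior point (or the tip end of a pendant edge, where collapsing
    # onto the leaf would destroy it as a leaf): insert a new vertex
    p = Node("")
    u.children[u.children.index(v)] = p
    p.parent = u
    p.edge_length = x
    v.parent = p
    v.edge_length = e - x
    p.children.append(v)
    return _reroot_at_node(copy, p)


# ---------------------------------------------------------------------------
# distances from an arbitrary point
# ---------------------------------------------------------------------------

def tip_distances(tree: WeightedTree, pos: RootPosition) -> dict[str, float]:
    """Path lengths from ``pos`` to every leaf, keyed by leaf label."""
    pos.validate()
    u, v, x = pos.parent, pos.child, float(pos.offset)
    e = float(pos.child.edge_length)
    dist: dict[str, float] = {}
    # walk outward from the two endpoints of the split edge
    stack: list[tuple[Node, float, Node | None]] = [(u, x, v), (v, e - x, u)]
    while stack:
        node, d, block = stack.pop()
        if node.is_leaf:
            dist[node.label] = d
        for nb in node.children:
            if nb is not block:
                stack.append((nb, d + nb.edge_length, node))
        par = node.parent
        if par is not None and par is not block:
            stack.append((par, d + node.edge_length, node))
    return dist


def tip_distance_stats(tree: WeightedTree, pos: RootPosition) -> tuple[float, float]:
    """Mean and population variance of root-to-tip distances from ``pos``."""
    d = list(tip_distances(tree, pos).values())
    n = len(d)
    mean = sum(d) / n
    var = sum((x - mean) ** 2 for x in d) / n
    return mean, var


def var_at_position(tree: WeightedTree, pos: RootPosition) -> float:
    return tip_distance_stats(tree, pos)[1]
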