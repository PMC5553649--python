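"""Rooting-accuracy metrics.

Triplet distance: the fraction of leaf triples on which the rooted
topology induced by the estimated tree differs from the reference.  For
each unordered triple {a, b, c} a rooted binary tree resolves exactly one
"cherry" pair (the pair with the deepest last common ancestor); a
multifurcation may leave the triple unresolved.  A triple unresolved in
the *reference* is excluded from the denominator; one resolved in the
reference but unresolved in the estimate counts as a mismatch.

Ideal rooting: the root placement of an (unrooted) estimate that
minimizes the triplet distance to the reference; it is zero exactly when
the unrooted estimate topology is correct.  "Delta triplet" is a
rooting's triplet distance minus this floor, isolating rooting error from
topological error.

Branch distance: for an estimated root placed on the *true* topology, the
number of edges between the estimated and the true root position,
normalized by the maximum number of edges from the root to any leaf.

Enumeration is O(n^3) with O(1) per triple after a pairwise-LCA-depth
table; this is deliberate — at evaluation scale (tens of leaves) it is
fast and easy to verify against independent oracles.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

from .tree import Node, RootPosition, WeightedTree, reroot_at

__all__ = [
    "RootingReport",
    "LabelMismatchError",
    "triplet_distance",
    "ideal_rooting",
    "branch_distance",
    "rf_distance",
]


class LabelMismatchError(ValueError):
    """The two trees do not share an identical leaf label set."""


@dataclass
class RootingReport:
    """Per-tree evaluation record for one rooting method."""

    method: str
    triplet_distance: float
    delta_triplet: float | None = None
    branch_distance: float | None = None
    root_variance: float | None = None


# ---------------------------------------------------------------------------
# triplet machinery
# ---------------------------------------------------------------------------

def _lca_depth_table(tree: WeightedTree, labels: list[str]) -> dict[tuple[str, str], int]:
    """Depth (edge count from the root) of the LCA of every leaf pair."""
    depth: dict[Node, int] = {tree.root: 0}
    for u, v in tree.edges():
        depth[v] = depth[u] + 1
    leaf_by_label = {u.label: u for u in tree.leaves()}
    missing = set(labels) - set(leaf_by_label)
    if missing:
        raise LabelMismatchError(f"labels missing from tree: {sorted(missing)}")
    # ancestor chains per leaf, root-first
    chains: dict[str, list[Node]] = {}
    for lab in labels:
        chain = []
        node: Node | None = leaf_by_label[lab]
        while node is not None:
            chain.append(node)
            node = node.parent
        chains[lab] = chain[::-1]
    table: dict[tuple[str, str], int] = {}
    for la, lb in combinations(labels, 2):
        ca, cb = chains[la], chains[lb]
        k = 0
        m = min(len(ca), len(cb))
        while k < m and ca[k] is cb[k]:
            k += 1
        key = (la, lb) if la < lb else (lb, la)
        table[key] = depth[ca[k - 1]]
    return table


def _cherry(table, a: str, b: str, c: str) -> int:
    """Which pair is the cherry of triple (a,b,c): 0=ab, 1=ac, 2=bc, -1=unresolved."""
    dab = table[(a, b) if a < b else (b, a)]
    dac = table[(a, c) if a < c else (c, a)]
    dbc = table[(b, c) if b < c else (c, b)]
    if dab > dac and dab > dbc:
        return 0
    if dac > dab and dac > dbc:
        return 1
    if dbc > dab and dbc > dac:
        return 2
    return -1


def triplet_distance(reference: WeightedTree, estimate: WeightedTree) -> float:
    """Fraction of reference-resolved leaf triples whose rooted topology
    differs in the estimate (0 = identical rooted topologies)."""
    labels = sorted(reference.leaf_labels)
    if sorted(estimate.leaf_labels) != labels:
        raise LabelMismatchError("reference and estimate leaf sets differ")
    if len(labels) < 3:
        raise LabelMismatchError("triplet distance needs at least 3 leaves")
    ref_t = _lca_depth_table(reference, labels)
    est_t = _lca_depth_table(estimate, labels)
    resolved = 0
    matches = 0
    for a, b, c in combinations(labels, 3):
        r = _cherry(ref_t, a, b, c)
        if r < 0:
            continue  # unresolved in the reference: excluded
        resolved += 1
        if _cherry(est_t, a, b, c) == r:
            matches += 1
    if resolved == 0:
        return 0.0
    return 1.0 - matches / resolved


def ideal_rooting(
    true_tree: WeightedTree, estimate: WeightedTree
) -> tuple[RootPosition, float]:
    """Best achievable triplet distance over all rootings of ``estimate``.

    Tries rooting the estimate at the midpoint of every edge (the offset
    along an edge never changes the rooted topology) as well as keeping
    the estimate's own base.  Returns the winning position and distance;
    zero iff the unrooted estimate topology matches the reference.
    """
    best_pos = RootPosition(estimate.root, estimate.root.children[0], 0.0)
    best = triplet_distance(true_tree, estimate)
    for u, v in estimate.edges():
        pos = RootPosition(u, v, float(v.edge_length) / 2.0)
        d = triplet_distance(true_tree, reroot_at(estimate, pos))
        if d < best - 1e-15:
            best, best_pos = d, pos
            if best == 0.0:
                break
    return best_pos, best


# ---------------------------------------------------------------------------
# branch distance
# ---------------------------------------------------------------------------

def _canonical_bipartitions(tree: WeightedTree, ref_label: str):
    """Map canonical child-side leafset -> (parent, child) for every edge.

    Canonical form: the side of the split that excludes ``ref_label``, so
    that the two rooted half-edges at a bifurcating base collapse onto the
    same unrooted edge key.
    """
    sets: dict[Node, frozenset[str]] = {}
    all_labels = frozenset(tree.leaf_labels)
    for u in tree.postorder():
        sets[u] = (
            frozenset((u.label,))
            if u.is_leaf
            else frozenset().union(*(sets[v] for v in u.children))
        )
    out: dict[frozenset[str], tuple[Node, Node]] = {}
    for u, v in tree.edges():
        side = sets[v]
        key = side if ref_label not in side else all_labels - side
        out.setdefault(key, (u, v))
    return out


def _unrooted_edge_key(tree: WeightedTree, u: Node, v: Node) -> Node:
    """Identify the unrooted edge carrying rooted edge (u, v) by a node.

    Each unrooted edge is keyed by its child node in the rooted tree,
    except that the two half-edges at a bifurcating base merge into one
    unrooted edge keyed by the base's first child.
    """
    if len(tree.root.children) == 2 and u is tree.root:
        return tree.root.children[0]
    return v


def _unrooted_node_dist(tree: WeightedTree, a: Node, b: Node) -> int:
    """Edge count between two nodes on the unrooted topology (a degree-2
    bifurcating base is suppressed, so its two half-edges count as one)."""
    suppress = tree.root if len(tree.root.children) == 2 else None

    def chain(x: Node) -> list[Node]:
        out = []
        node: Node | None = x
        while node is not None:
            out.append(node)
            node = node.parent
        return out[::-1]

    ca, cb = chain(a), chain(b)
    k = 0
    m = min(len(ca), len(cb))
    while k < m and ca[k] is cb[k]:
        k += 1
    d = (len(ca) - k) + (len(cb) - k)
    # the path passes *through* the suppressed base iff the base is the
    # meeting node and neither endpoint is the base itself
    if suppress is not None and ca[k - 1] is suppress and a is not suppress and b is not suppress:
        d -= 1
    return d


def _edge_endpoints(tree: WeightedTree, key: Node) -> tuple[Node, Node]:
    if len(tree.root.children) == 2 and key is tree.root.children[0]:
        a, b = tree.root.children
        return a, b
    return key.parent, key


def branch_distance(
    true_tree: WeightedTree,
    estimated_root: RootPosition,
    estimate_tree: WeightedTree | None = None,
) -> float:
    """Normalized topological distance between estimated and true root.

    ``estimated_root`` may live on ``true_tree`` itself or on
    ``estimate_tree``, a differently-rooted tree with the *same* unrooted
    topology (the usual case: a rooting method was run on the unrooted
    version of the true tree).  The number of branches separating the two
    root positions (0 when both sit on the same unrooted edge, 1 for
    adjacent edges, ...) is divided by the maximum number of edges from
    the true root to any leaf.
    """
    ref_label = min(true_tree.leaf_labels)
    if estimate_tree is None or estimate_tree is true_tree:
        est_u, est_v = estimated_root.edge
    else:
        if sorted(estimate_tree.leaf_labels) != sorted(true_tree.leaf_labels):
            raise LabelMismatchError("leaf sets differ")
        true_bip = _canonical_bipartitions(true_tree, ref_label)
        est_bip = _canonical_bipartitions(estimate_tree, ref_label)
        if set(est_bip) != set(true_bip):
            raise LabelMismatchError(
                "estimate topology differs from the true tree; branch "
                "distance is undefined"
            )
        all_labels = frozenset(estimate_tree.leaf_labels)
        side: set[str] = set()
        stack = [estimated_root.child]
        while stack:
            node = stack.pop()
            if node.is_leaf:
                side.add(node.label)
            stack.extend(node.children)
        key = frozenset(side)
        if ref_label in key:
            key = all_labels - key
        est_u, est_v = true_bip[key]
    est_key = _unrooted_edge_key(true_tree, est_u, est_v)

    if len(true_tree.root.children) == 2:
        # true root is a point on the unrooted edge between its children
        root_key = true_tree.root.children[0]
        if est_key is root_key:
            count = 0
        else:
            count = 1 + min(
                _unrooted_node_dist(true_tree, a, b)
                for a in _edge_endpoints(true_tree, est_key)
                for b in _edge_endpoints(true_tree, root_key)
            )
    else:
        # multifurcating base: the true root is the base node itself
        count = min(
            _unrooted_node_dist(true_tree, a, true_tree.root)
            for a in _edge_endpoints(true_tree, est_key)
        )
    depth = 0
    depths: dict[Node, int] = {true_tree.root: 0}
    for u, v in true_tree.edges():
        depths[v] = depths[u] + 1
        if v.is_leaf:
            depth = max(depth, depths[v])
    return count / depth


# ---------------------------------------------------------------------------
# unrooted Robinson-Foulds (reporting utility)
# ---------------------------------------------------------------------------

def rf_distance(t1: WeightedTree, t2: WeightedTree) -> float:
    """Normalized unrooted Robinson-Foulds distance (bipartition symmetric
    difference over 2n - 6)."""
    labels = sorted(t1.leaf_labels)
    if sorted(t2.leaf_labels) != labels:
        raise LabelMismatchError("leaf sets differ")
    n = len(labels)
    if n < 4:
        return 0.0
    ref = labels[0]

    def nontrivial(tree: WeightedTree) -> set[frozenset[str]]:
        out = set()
        for key, (u, v) in _canonical_bipartitions(tree, ref).items():
            if 2 <= len(key) <= n - 2:
                out.add(key)
        return out

    b1, b2 = nontrivial(t1), nontrivial(t2)
    return len(b1 ^ b2) / (2 * n - 6)
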