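"""Linear-time midpoint (MP) rooting.

Midpoint rooting places the root halfway along the longest leaf-to-leaf
path (the diameter), which minimizes the maximum root-to-tip distance.
Two traversals suffice: a post-order pass computing, per node u,

    MI(u) = max over children v of MI(v) + e_v

(the deepest leaf inside u's clade) and a pre-order pass propagating
MO(u), the farthest leaf reachable through u's parent.  On the edge
(p(v), v) the point equidistant from the deepest leaves on either side
lies at

    x* = (MI(v) - MO + e_v) / 2

from the parent; when x* falls inside [0, e_v] that point is the unique
center of the tree and the search stops.  The maximum tip distance from
it is (MI(v) + MO + e_v)/2 = diameter/2.
"""

from __future__ import annotations

from .tree import (
    Node,
    RootPosition,
    TreeStructureError,
    WeightedTree,
    tip_distances,
)

__all__ = ["midpoint_root", "tree_diameter"]


def midpoint_root(tree: WeightedTree) -> tuple[RootPosition, float]:
    """Midpoint root of ``tree`` (viewed as unrooted) and the maximum
    root-to-tip distance from it (= half the tree diameter)."""
    if tree.n_leaves < 2:
        raise TreeStructureError("midpoint rooting needs at least 2 leaves")
    MI: dict[Node, float] = {}
    for u in tree.postorder():
        if u.is_leaf:
            MI[u] = 0.0
        else:
            MI[u] = max(MI[v] + v.edge_length for v in u.children)
    # top-two "down" values per node, to get each child's best sibling in O(1)
    top2: dict[Node, tuple[float, float, Node | None]] = {}
    for u in tree.preorder():
        best, second, argbest = float("-inf"), float("-inf"), None
        for v in u.children:
            val = MI[v] + v.edge_length
            if val > best:
                best, second, argbest = val, best, v
            elif val > second:
                second = val
        top2[u] = (best, second, argbest)
    MO: dict[Node, float] = {tree.root: 0.0}
    for u, v in tree.edges():  # pre-order
        best, second, argbest = top2[u]
        sib = second if argbest is v else best
        mo = MO[u]
        if sib > float("-inf"):
            mo = max(mo, sib)
        x_star = (MI[v] - mo + v.edge_length) / 2.0
        if 0.0 <= x_star <= v.edge_length:
            return RootPosition(u, v, x_star), (MI[v] + mo + v.edge_length) / 2.0
        MO[v] = mo + v.edge_length
    raise AssertionError("no midpoint found; tree structure is inconsistent")


def tree_diameter(tree: WeightedTree) -> tuple[float, tuple[str, str]]:
    """Length of the longest leaf-to-leaf path and the leaf pair realizing it.

    Uses the classic two-sweep: the farthest leaf from an arbitrary leaf
    is one diameter endpoint, and the farthest leaf from *that* one is the
    other.  Exact on trees with non-negative edge lengths; ties resolved
    to the first leaf in traversal order.
    """
    leaves = tree.leaves()
    if len(leaves) < 2:
        raise TreeStructureError("diameter needs at least 2 leaves")

    def _position_at_leaf(leaf: Node) -> RootPosition:
        return RootPosition(leaf.parent, leaf, float(leaf.edge_length))

    def _farthest(leaf: Node) -> tuple[str, float]:
        d = tip_distances(tree, _position_at_leaf(leaf))
        best_label, best = leaf.label, float("-inf")
        for other in leaves:
            if other is leaf:
                continue
            if d[other.label] > best:
                best = d[other.label]
                best_label = other.label
        return best_label, best

    a_label, _ = _farthest(leaves[0])
    a = tree.find_leaf(a_label)
    b_label, diam = _farthest(a)
    return diam, (a_label, b_label)
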