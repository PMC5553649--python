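"""Shared helpers: random weighted trees with exponential branch lengths."""

from __future__ import annotations

import numpy as np

from treeroot.tree import Node, RootPosition, WeightedTree


def random_bltree(n: int, seed: int, mean_length: float = 1.0) -> WeightedTree:
    """Random rooted binary tree topology with i.i.d. Exp(mean) branch
    lengths (not ultrametric)."""
    rng = np.random.default_rng(seed)
    nodes: list[Node] = [Node(f"L{i + 1}") for i in range(n)]
    while len(nodes) > 1:
        k = len(nodes)
        i = int(rng.integers(k))
        j = int(rng.integers(k - 1))
        if j >= i:
            j += 1
        a, b = nodes[i], nodes[j]
        parent = Node("")
        a.edge_length = float(rng.exponential(mean_length))
        b.edge_length = float(rng.exponential(mean_length))
        parent.add_child(a)
        parent.add_child(b)
        hi, lo = max(i, j), min(i, j)
        nodes[lo] = parent
        nodes[hi] = nodes[-1]
        nodes.pop()
    tree = WeightedTree(nodes[0])
    tree.validate()
    return tree


def random_position(tree: WeightedTree, rng: np.random.Generator) -> RootPosition:
    """Uniformly random edge, uniform offset strictly inside it."""
    edges = list(tree.edges())
    u, v = edges[int(rng.integers(len(edges)))]
    e = float(v.edge_length)
    x = float(rng.uniform(0.0, e)) if e > 0 else 0.0
    return RootPosition(u, v, x)


def rooted_equal(t1: WeightedTree, t2: WeightedTree, tol: float = 1e-9) -> bool:
    """Rooted-topology + branch-length equality, insensitive to child order.

    Compares the map {clade leafset -> branch length above it} of the two
    trees; equal maps mean equal rooted weighted trees.
    """

    def clade_map(tree: WeightedTree) -> dict[frozenset[str], float]:
        sets: dict[Node, frozenset[str]] = {}
        out: dict[frozenset[str], float] = {}
        for u in tree.postorder():
            sets[u] = (
                frozenset((u.label,))
                if u.is_leaf
                else frozenset().union(*(sets[v] for v in u.children))
            )
            if u.parent is not None:
                out[sets[u]] = float(u.edge_length)
        return out

    m1, m2 = clade_map(t1), clade_map(t2)
    if set(m1) != set(m2):
        return False
    return all(abs(m1[k] - m2[k]) <= tol for k in m1)
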