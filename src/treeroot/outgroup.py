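"""Outgroup (OG) rooting: root on the edge separating a designated
outgroup taxon set from the ingroup.

The outgroup must be *bipartition-compatible*: some edge of the unrooted
tree must split the leaves exactly into outgroup vs. ingroup.  A
single-taxon outgroup always qualifies (its pendant edge separates it).
The rooting position along the separating edge is topologically
irrelevant for triplet-style metrics; the midpoint is used by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .tree import Node, RootPosition, WeightedTree

__all__ = ["OutgroupSpec", "OutgroupError", "outgroup_root", "is_gene_tree_outgroup"]


class OutgroupError(ValueError):
    """Outgroup labels missing or not separable by any edge."""


@dataclass(frozen=True)
class OutgroupSpec:
    labels: frozenset[str] = field(default_factory=frozenset)

    def __init__(self, labels):
        object.__setattr__(self, "labels", frozenset(labels))
        if not self.labels:
            raise OutgroupError("outgroup label set is empty")


def _clade_leafsets(tree: WeightedTree) -> dict[Node, frozenset[str]]:
    sets: dict[Node, frozenset[str]] = {}
    for u in tree.postorder():
        if u.is_leaf:
            sets[u] = frozenset((u.label,))
        else:
            acc: set[str] = set()
            for v in u.children:
                acc |= sets[v]
            sets[u] = frozenset(acc)
    return sets


def _check_labels(tree: WeightedTree, og: OutgroupSpec) -> frozenset[str]:
    all_labels = frozenset(tree.leaf_labels)
    missing = og.labels - all_labels
    if missing:
        raise OutgroupError(f"outgroup labels not in tree: {sorted(missing)}")
    if og.labels == all_labels:
        raise OutgroupError("outgroup cannot contain every leaf")
    return all_labels


def _separating_edge(tree: WeightedTree, og: OutgroupSpec):
    """The edge (parent, child, outgroup_on_child_side) splitting og from
    the ingroup, or None."""
    all_labels = _check_labels(tree, og)
    complement = all_labels - og.labels
    sets = _clade_leafsets(tree)
    for u, v in tree.edges():
        if sets[v] == og.labels:
            return u, v, True
        if sets[v] == complement:
            return u, v, False
    return None


def is_gene_tree_outgroup(tree: WeightedTree, og: OutgroupSpec | set[str]) -> bool:
    """True iff some rooting of ``tree`` makes ``og`` the outgroup clade,
    i.e. an edge separates exactly those labels from the rest."""
    if not isinstance(og, OutgroupSpec):
        og = OutgroupSpec(og)
    return _separating_edge(tree, og) is not None


def outgroup_root(
    tree: WeightedTree,
    og: OutgroupSpec | set[str],
    offset_policy: str = "midpoint",
) -> RootPosition:
    """Position of the root on the edge separating ``og`` from the ingroup.

    ``offset_policy`` places the root at the ``midpoint`` of the
    separating edge (default), or at its ``ingroup-end`` / ``outgroup-end``
    node (note those collapse onto an existing vertex, so the og/ingroup
    bipartition is then not displayed as the two root clades).
    """
    if not isinstance(og, OutgroupSpec):
        og = OutgroupSpec(og)
    found = _separating_edge(tree, og)
    if found is None:
        # report which non-outgroup leaves intrude into the smallest clade
        # spanning the outgroup (in the current rooting)
        sets = _clade_leafsets(tree)
        spanning = min(
            (u for u in tree.preorder() if og.labels <= sets[u]),
            key=lambda u: len(sets[u]),
            default=tree.root,
        )
        conflict = sorted(sets[spanning] - og.labels)
        raise OutgroupError(
            f"outgroup {sorted(og.labels)} is not separable by any edge; "
            f"conflicting leaves: {conflict}"
        )
    u, v, og_below = found
    e = float(v.edge_length)
    if offset_policy == "midpoint":
        x = e / 2.0
    elif offset_policy == "ingroup-end":
        x = 0.0 if og_below else e
    elif offset_policy == "outgroup-end":
        x = e if og_below else 0.0
    else:
        raise ValueError(f"unknown offset policy {offset_policy!r}")
    return RootPosition(u, v, x)
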