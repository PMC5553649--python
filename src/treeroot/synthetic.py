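"""Synthetic trees with controlled deviations from a strict molecular clock.

This module is the test bed for the rooting algorithms.  It generates
ultrametric trees (where rooting is unambiguous), perturbs them with two
clock-deviation mechanisms, and provides the small pieces of coalescent
arithmetic used to reason about outgroup reliability.

Random-deviations model: starting from an ultrametric tree, every branch
length is multiplied by an independent draw from a distribution with
support [1 - eps, 1 + eps] and mean 1 (uniform by default).  Under this
model the minimum-variance root stays, for small enough eps, on a branch
adjacent to the true root, and its signed displacement from the true
root has expectation zero.

Gamma rate-multiplier model: per replicate, a gamma shape k is drawn as
exp(Normal(location, sigma)); branch multipliers are then
Gamma(shape=k, scale=1/k), which has mean exactly 1 for any k.  Larger
``location`` concentrates the multipliers around 1 (weak deviation);
smaller values produce heavy rate heterogeneity.  Multipliers can be
drawn per branch per tree ("gene by lineage") and/or once per species and
applied to that species' pendant branch in every tree.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .tree import Node, RootPosition, TreeStructureError, WeightedTree

__all__ = [
    "RandomDeviationsConfig",
    "ClockDeviationConfig",
    "OutgroupPlacementConfig",
    "generate_ultrametric",
    "apply_random_deviations",
    "apply_gamma_rate_heterogeneity",
    "attach_outgroup",
    "outgroup_discordance_probability",
    "coalescent_units_to_years",
]


@dataclass(frozen=True)
class RandomDeviationsConfig:
    epsilon: float = 0.05
    n_leaves: int = 16
    height: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if not (0.0 <= self.epsilon < 1.0):
            raise ValueError("epsilon must lie in [0, 1)")


@dataclass(frozen=True)
class ClockDeviationConfig:
    """Gamma-multiplier clock deviation ("clock deviation parameter" =
    the log-normal location of the gamma shape; sigma its scale)."""

    location: float = 1.5
    sigma: float = 1.0
    per_species_rates: bool = True
    per_gene_lineage_rates: bool = True
    seed: int = 0


@dataclass(frozen=True)
class OutgroupPlacementConfig:
    """Stem above the ingroup crown = rc_ratio x ingroup height (the
    root-to-crown, R/C, ratio)."""

    rc_ratio: float = 1.0
    outgroup_label: str = "OUT"

    def __post_init__(self):
        if self.rc_ratio < 0:
            raise ValueError("rc_ratio must be >= 0")


# ---------------------------------------------------------------------------
# ultrametric substrates
# ---------------------------------------------------------------------------

def generate_ultrametric(
    n_leaves: int,
    height: float = 1.0,
    model: str = "yule",
    seed: int = 0,
) -> WeightedTree:
    """Random rooted binary ultrametric tree with all leaves at ``height``.

    ``model="yule"`` (default): pure-birth branching at rate 1, node
    times rescaled so the root sits at ``height`` — the shape of a
    speciation process, and the substrate used throughout the package's
    simulation studies.
    ``model="coalescent"``: Kingman coalescent node times (pairs merge at
    rate C(k,2)), likewise rescaled; yields cherry-heavy shapes with many
    short recent branches.
    Deterministic for a given seed.
    """
    if n_leaves < 2:
        raise ValueError("need at least 2 leaves")
    if height <= 0:
        raise ValueError("height must be positive")
    rng = np.random.default_rng(seed)
    if model == "coalescent":
        # active nodes at time 0 = leaves; merge until one remains
        active: list[tuple[Node, float]] = [
            (Node(f"L{i + 1}"), 0.0) for i in range(n_leaves)
        ]
        t = 0.0
        while len(active) > 1:
            k = len(active)
            t += rng.exponential(1.0 / (k * (k - 1) / 2.0))
            i = int(rng.integers(k))
            j = int(rng.integers(k - 1))
            if j >= i:
                j += 1
            if i > j:
                i, j = j, i
            (a, ta), (b, tb) = active[i], active[j]
            parent = Node("")
            a.edge_length = t - ta
            b.edge_length = t - tb
            parent.add_child(a)
            parent.add_child(b)
            active[i] = (parent, t)
            active[j] = active[-1]
            active.pop()
        root, total = active[0]
    elif model == "yule":
        # forward in time: lineages carry their birth times
        root = Node("")
        lineages: list[tuple[Node, float]] = []
        t = 0.0
        for _ in range(2):
            lineages.append((root.add_child(Node("")), t))
        while len(lineages) < n_leaves:
            k = len(lineages)
            t += rng.exponential(1.0 / k)
            i = int(rng.integers(k))
            node, tb = lineages[i]
            node.edge_length = t - tb
            lineages[i] = (node.add_child(Node("")), t)
            lineages.append((node.add_child(Node("")), t))
        total = t + rng.exponential(1.0 / n_leaves)
        for idx, (node, tb) in enumerate(lineages):
            node.label = f"L{idx + 1}"
            node.edge_length = total - tb
    else:
        raise ValueError(f"unknown model {model!r}")
    scale = height / total
    tree = WeightedTree(root)
    for u in tree.preorder():
        if u.parent is not None:
            u.edge_length *= scale
    tree.validate()
    return tree


def _check_ultrametric(tree: WeightedTree, tol: float = 1e-6) -> float:
    depths = {tree.root: 0.0}
    leaf_depths = []
    for u, v in tree.edges():
        depths[v] = depths[u] + v.edge_length
        if v.is_leaf:
            leaf_depths.append(depths[v])
    h = max(leaf_depths)
    if h - min(leaf_depths) > tol * max(1.0, h):
        raise TreeStructureError("tree is not ultrametric")
    return h


# ---------------------------------------------------------------------------
# clock deviations
# ---------------------------------------------------------------------------

def apply_random_deviations(
    tree: WeightedTree, cfg: RandomDeviationsConfig
) -> WeightedTree:
    """Multiply every branch of an ultrametric tree by an independent
    uniform draw on [1 - eps, 1 + eps] (mean 1).  The returned copy keeps
    the true root as its root."""
    _check_ultrametric(tree)
    rng = np.random.default_rng(cfg.seed)
    out = tree.copy()
    for u, v in out.edges():
        v.edge_length = v.edge_length * rng.uniform(1.0 - cfg.epsilon, 1.0 + cfg.epsilon)
    return out


def _mean_one_gamma(rng: np.random.Generator, shape: float, size: int) -> np.ndarray:
    return rng.gamma(shape, 1.0 / shape, size=size)


def apply_gamma_rate_heterogeneity(
    trees: list[WeightedTree], cfg: ClockDeviationConfig
) -> list[WeightedTree]:
    """Mean-preserving gamma rate multipliers on copies of ``trees``.

    Per tree, a fresh shape k = exp(Normal(location, sigma)) governs the
    per-branch ("gene by lineage") multipliers; a second shape, shared by
    all trees, governs the per-species multipliers applied to each
    species' pendant branch in every tree.
    """
    rng = np.random.default_rng(cfg.seed)
    species_mult: dict[str, float] = {}
    if cfg.per_species_rates:
        labels = sorted(trees[0].leaf_labels) if trees else []
        shape_sp = math.exp(rng.normal(cfg.location, cfg.sigma))
        mults = _mean_one_gamma(rng, shape_sp, len(labels))
        species_mult = dict(zip(labels, mults))
    out: list[WeightedTree] = []
    for tree in trees:
        copy = tree.copy()
        if cfg.per_gene_lineage_rates:
            shape_g = math.exp(rng.normal(cfg.location, cfg.sigma))
            edges = list(copy.edges())
            mults = _mean_one_gamma(rng, shape_g, len(edges))
            for (u, v), m in zip(edges, mults):
                v.edge_length = v.edge_length * float(m)
        if cfg.per_species_rates:
            for leaf in copy.leaves():
                leaf.edge_length = leaf.edge_length * species_mult[leaf.label]
        out.append(copy)
    return out


def attach_outgroup(
    ingroup_tree: WeightedTree, cfg: OutgroupPlacementConfig
) -> WeightedTree:
    """Add an outgroup as sister to an ultrametric ingroup tree.

    The stem above the ingroup crown has length rc_ratio x height; the
    outgroup pendant branch has length (1 + rc_ratio) x height, so the
    result is ultrametric with height (1 + rc_ratio) x height.
    """
    if cfg.outgroup_label in ingroup_tree.leaf_labels:
        raise ValueError(f"label collision: {cfg.outgroup_label!r} already a leaf")
    h = _check_ultrametric(ingroup_tree)
    copy = ingroup_tree.copy()
    new_root = Node("")
    crown = copy.root
    crown.edge_length = cfg.rc_ratio * h
    new_root.add_child(crown)
    new_root.add_child(Node(cfg.outgroup_label, (1.0 + cfg.rc_ratio) * h))
    return WeightedTree(new_root)


# ---------------------------------------------------------------------------
# coalescent arithmetic
# ---------------------------------------------------------------------------

def outgroup_discordance_probability(branch_cu: float) -> float:
    """Probability, under the multispecies coalescent, that a rooted
    triple is discordant across an internal branch of ``branch_cu``
    coalescent units: (2/3) exp(-t).

    Applied to an outgroup separated from the ingroups by that branch (in
    the idealization where only two lineages must coalesce below the
    root), this is the fraction of gene trees in which the outgroup mixes
    with the ingroups purely through incomplete lineage sorting.
    """
    if branch_cu < 0:
        raise ValueError("branch length in coalescent units must be >= 0")
    return (2.0 / 3.0) * math.exp(-branch_cu)


def coalescent_units_to_years(
    cu: float, diploid_Ne: float, generation_time_years: float
) -> float:
    """Convert coalescent units to years: one unit = 2 Ne generations for
    a diploid population."""
    if cu < 0:
        raise ValueError("coalescent units must be >= 0")
    if diploid_Ne <= 0 or generation_time_years <= 0:
        raise ValueError("Ne and generation time must be positive")
    return cu * 2.0 * diploid_Ne * generation_time_years


# ---------------------------------------------------------------------------
# study helper: signed MV displacement under random deviations
# ---------------------------------------------------------------------------

def signed_mv_offset(tree: WeightedTree) -> float | None:
    """Signed distance of the global MV root from the (current) root.

    Positive when the MV point falls on the edge to the root's first
    child, negative on the edge to any other child; ``None`` when the MV
    point is not adjacent to the root (then a sign is not defined).
    The root node itself scores 0.
    """
    from .minvar import minvar_root

    pos, _ = minvar_root(tree)
    u, v = pos.edge
    if u is tree.root:
        if pos.offset == 0.0:
            return 0.0
        return pos.offset if v is tree.root.children[0] else -pos.offset
    return None
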