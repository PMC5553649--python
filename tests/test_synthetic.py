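"""Generators: ultrametricity, seed determinism, mean-preserving
multipliers, outgroup construction, coalescent arithmetic."""

import math

import numpy as np
import pytest

from treeroot.midpoint import midpoint_root
from treeroot.minvar import minvar_root
from treeroot.outgroup import is_gene_tree_outgroup
from treeroot.synthetic import (
    ClockDeviationConfig,
    OutgroupPlacementConfig,
    RandomDeviationsConfig,
    apply_gamma_rate_heterogeneity,
    apply_random_deviations,
    attach_outgroup,
    coalescent_units_to_years,
    generate_ultrametric,
    outgroup_discordance_probability,
    signed_mv_offset,
)
from treeroot.tree import RootPosition, tip_distance_stats, tip_distances, tree_to_newick


def _root_pos(tree):
    return RootPosition(tree.root, tree.root.children[0], 0.0)


class TestUltrametricGenerator:
    @pytest.mark.parametrize("model", ["yule", "coalescent"])
    @pytest.mark.parametrize("n", [2, 5, 40])
    def test_zero_root_to_tip_variance(self, model, n):
        t = generate_ultrametric(n, height=2.5, model=model, seed=1)
        assert t.n_leaves == n
        mean, var = tip_distance_stats(t, _root_pos(t))
        assert mean == pytest.approx(2.5, abs=1e-9)
        assert var == pytest.approx(0.0, abs=1e-15)

    def test_two_leaves_is_a_cherry_at_height(self):
        t = generate_ultrametric(2, height=1.0, seed=0)
        assert all(c.is_leaf and c.edge_length == pytest.approx(1.0)
                   for c in t.root.children)

    def test_seed_determinism(self):
        a = tree_to_newick(generate_ultrametric(20, seed=42))
        b = tree_to_newick(generate_ultrametric(20, seed=42))
        c = tree_to_newick(generate_ultrametric(20, seed=43))
        assert a == b
        assert a != c

    def test_too_few_leaves_rejected(self):
        with pytest.raises(ValueError):
            generate_ultrametric(1)


class TestRandomDeviations:
    def test_epsilon_zero_is_identity(self):
        t = generate_ultrametric(10, seed=3)
        d = apply_random_deviations(t, RandomDeviationsConfig(epsilon=0.0, seed=5))
        assert tree_to_newick(d) == tree_to_newick(t)

    def test_epsilon_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            RandomDeviationsConfig(epsilon=1.0)

    def test_multipliers_are_mean_one(self):
        t = generate_ultrametric(6, seed=8)
        orig = {id(v): v.edge_length for _, v in t.edges()}
        reps = 2000
        sums = {id(v): 0.0 for _, v in t.edges()}
        for r in range(reps):
            d = apply_random_deviations(t, RandomDeviationsConfig(epsilon=0.5, seed=r))
            for (ou, ov), (du, dv) in zip(t.edges(), d.edges()):
                sums[id(ov)] += dv.edge_length
        # uniform on [1-eps,1+eps]: SE of the mean = eps/sqrt(3 reps)
        se = 0.5 / math.sqrt(3 * reps)
        for _, v in t.edges():
            mean_ratio = sums[id(v)] / reps / v.edge_length
            assert abs(mean_ratio - 1.0) < 3 * se

    def test_small_epsilon_keeps_mv_near_root(self):
        """With weak deviations the global MV stays on a root-adjacent
        edge in essentially all replicates."""
        hits = total = 0
        for rep in range(200):
            base = generate_ultrametric(16, seed=rep)
            dev = apply_random_deviations(
                base, RandomDeviationsConfig(epsilon=0.01, seed=10_000 + rep)
            )
            total += 1
            if signed_mv_offset(dev) is not None:
                hits += 1
        assert hits / total >= 0.99


class TestGammaRateHeterogeneity:
    def test_large_location_approaches_strict_clock(self):
        bases = [generate_ultrametric(12, seed=s) for s in range(5)]
        devs = apply_gamma_rate_heterogeneity(
            bases, ClockDeviationConfig(location=12.0, sigma=0.0, seed=1)
        )
        for base, dev in zip(bases, devs):
            _, var = tip_distance_stats(dev, _root_pos(dev))
            assert var < 1e-3  # shape e^12: multipliers within ~0.3% of 1

    def test_mean_multiplier_is_one(self):
        base = generate_ultrametric(4, seed=2)
        reps = 3000
        ratios = []
        for r in range(reps):
            dev = apply_gamma_rate_heterogeneity(
                [base],
                ClockDeviationConfig(location=1.0, sigma=0.0,
                                     per_species_rates=False, seed=r),
            )[0]
            for (bu, bv), (du, dv) in zip(base.edges(), dev.edges()):
                ratios.append(dv.edge_length / bv.edge_length)
        ratios = np.asarray(ratios)
        se = ratios.std(ddof=1) / math.sqrt(len(ratios))
        assert abs(ratios.mean() - 1.0) < 3 * se

    def test_divergence_ordering_follows_location(self):
        """Lower clock-deviation location = heavier rate heterogeneity =
        larger coefficient of variation of root-to-tip distances."""
        med = {}
        for loc in (0.15, 1.5, 5.0):
            bases = [generate_ultrametric(30, seed=100 + s) for s in range(40)]
            devs = apply_gamma_rate_heterogeneity(
                bases, ClockDeviationConfig(location=loc, seed=9)
            )
            covs = []
            for d in devs:
                dist = np.array(list(tip_distances(d, _root_pos(d)).values()))
                covs.append(dist.std() / dist.mean())
            med[loc] = float(np.median(covs))
        assert med[0.15] > med[1.5] > med[5.0]

    def test_per_species_rates_shared_across_trees(self):
        bases = [generate_ultrametric(8, seed=s) for s in range(3)]
        devs = apply_gamma_rate_heterogeneity(
            bases,
            ClockDeviationConfig(location=0.5, per_species_rates=True,
                                 per_gene_lineage_rates=False, seed=4),
        )
        # each species' pendant multiplier is identical in every tree
        for lab in bases[0].leaf_labels:
            ratios = [
                d.find_leaf(lab).edge_length / b.find_leaf(lab).edge_length
                for b, d in zip(bases, devs)
            ]
            assert max(ratios) - min(ratios) < 1e-12


class TestAttachOutgroup:
    def test_construction_arithmetic(self):
        ing = generate_ultrametric(6, height=1.0, seed=5)
        t = attach_outgroup(ing, OutgroupPlacementConfig(rc_ratio=1.0))
        out_leaf = t.find_leaf("OUT")
        assert out_leaf.edge_length == pytest.approx(2.0)
        stem = [c for c in t.root.children if not c.is_leaf][0]
        assert stem.edge_length == pytest.approx(1.0)
        mean, var = tip_distance_stats(t, _root_pos(t))
        assert mean == pytest.approx(2.0) and var == pytest.approx(0.0, abs=1e-15)
        assert is_gene_tree_outgroup(t, {"OUT"})

    def test_zero_rc_ratio(self):
        ing = generate_ultrametric(5, height=1.0, seed=6)
        t = attach_outgroup(ing, OutgroupPlacementConfig(rc_ratio=0.0))
        stem = [c for c in t.root.children if not c.is_leaf][0]
        assert stem.edge_length == 0.0

    def test_label_collision_rejected(self):
        ing = generate_ultrametric(5, height=1.0, seed=6)
        with pytest.raises(ValueError):
            attach_outgroup(ing, OutgroupPlacementConfig(outgroup_label="L1"))


class TestCoalescentArithmetic:
    def test_discordance_probability_values(self):
        assert outgroup_discordance_probability(0.0) == pytest.approx(2 / 3)
        assert outgroup_discordance_probability(2.0) == pytest.approx(
            (2 / 3) * math.exp(-2.0)
        )
        assert outgroup_discordance_probability(50.0) < 1e-20
        with pytest.raises(ValueError):
            outgroup_discordance_probability(-0.1)

    def test_unit_conversion(self):
        assert coalescent_units_to_years(2.0, 200_000, 10.0) == 8_000_000
        assert coalescent_units_to_years(0.0, 200_000, 10.0) == 0.0
        # homogeneity in each argument
        assert coalescent_units_to_years(4.0, 200_000, 10.0) == pytest.approx(
            2 * coalescent_units_to_years(2.0, 200_000, 10.0)
        )
        with pytest.raises(ValueError):
            coalescent_units_to_years(1.0, -5.0, 10.0)


def test_ultrametric_recovery_by_both_rooting_methods():
    """On a strict-clock tree MV and MP both return the true root."""
    for seed in range(3):
        t = generate_ultrametric(25, height=1.0, seed=seed)
        mv_pos, var = minvar_root(t)
        mp_pos, max_tip = midpoint_root(t)
        assert var == pytest.approx(0.0, abs=1e-15)
        assert max_tip == pytest.approx(1.0, abs=1e-9)
        for d in (tip_distances(t, mv_pos), tip_distances(t, mp_pos)):
            assert all(x == pytest.approx(1.0, abs=1e-9) for x in d.values())
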