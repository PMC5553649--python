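# treeroot

Rooting phylogenetic trees by **minimum variance of root-to-tip
distances** (MV), by **midpoint** (MP), or by a designated **outgroup**
(OG) — with the accuracy metrics and clock-deviation simulators needed to
study when each method works.

Trees inferred under time-reversible substitution models are unrooted,
yet the root matters for interpretation and for downstream analyses
(ancestral states, dating, species-tree methods that consume rooted gene
trees). When branch lengths follow a strict molecular clock the rooted
tree is ultrametric and the root is the one point equidistant from all
leaves. Real trees deviate from the clock; `treeroot` is for people —
phylogeneticists and phylogenomics pipeline builders — who need a fast,
deterministic, outgroup-free way to root large trees, and a way to
quantify how well any rooting did.

## The methods

For a point *p* on a tree with leaves 1..*n* and path distances
*d<sub>i</sub>(p)*, let

- mean(p) = (1/n) Σ d<sub>i</sub>(p)
- var(p) = (1/n) Σ (d<sub>i</sub>(p) − mean(p))²

**MV rooting** finds the point minimizing var(p) over every position on
every edge. Restricted to one edge (u, v) with length e<sub>v</sub>, the
variance is an exact quadratic in the offset *x* from *u*:

    var(x; u, v) = (1 − β²) x² + (α − 2 ST(u) β / n) x + var(u)
    α = (2 ST(u) − 4 (SI(v) + |v| e_v)) / n,   β = 1 − 2 |v| / n

where |v| is the leaf count below *v*, SI(v) the sum of distances from
*v* to its clade's leaves, and ST(u) the sum of distances from *u* to all
leaves, propagated by ST(v) = ST(p(v)) + (n − 2|v|) e<sub>v</sub>. Since
|β| < 1 the quadratic is strictly convex, so each edge has one
constrained minimizer; three linear-time traversals score them all and
the global minimum is exact, in O(n) total. Interior minimizers are
*balance points* — mean tip distance is equal on their two sides — and on
an ultrametric tree the only balance point is the true root. Under
random, bounded, mean-1 multiplicative deviations from the clock, the
expected displacement of the MV root from the true root is zero.

**MP rooting** minimizes the *maximum* root-to-tip distance, i.e. roots
halfway along the longest leaf-to-leaf path, also in two linear-time
traversals. **OG rooting** roots on the edge separating an a-priori
outgroup from the ingroup — reliable for species trees, but an outgroup
separated by *t* coalescent units mixes with the ingroups in
(2/3)e<sup>−t</sup> of gene trees through incomplete lineage sorting
alone (≈ 9% at t = 2).

Accuracy metrics: **triplet distance** (share of 3-leaf rooted subtrees
that disagree), **delta triplet** (excess over the best rooting of the
same unrooted tree), and **normalized branch distance** from the true
root; plus an unrooted Robinson-Foulds utility.

## Worked example

```python
>>> import treeroot as tr
>>> t = tr.parse_newick("(A:1,B:3,C:4);")     # unrooted 3-leaf star
>>> pos, var = tr.minvar_root(t)
>>> pos.child.label, round(pos.offset, 6), round(var, 6)
('C', 1.0, 0.666667)
>>> tr.tree_to_newick(tr.reroot_at(t, pos))
'(C:3,(A:1,B:3):1);'
>>> tr.midpoint_root(t)[1]                    # max tip distance
3.5
>>> tr.tree_diameter(t)
(7.0, ('C', 'B'))
```

The MV root sits on the edge to C, one unit from the hub: tip distances
become {A: 2, B: 4, C: 3} with variance 2/3 — the balance point where C's
distance (3) equals the average of A's and B's. The midpoint root is half
a unit further toward C, halving the B–C diameter of 7.

From the shell:

```bash
treeroot simulate --model gamma-clock --n 30 --reps 100 --seed 1 -o trees.nwk
treeroot reroot -m MV -i trees.nwk -o rooted.nwk
treeroot evaluate --ref trees.nwk --est trees.nwk --true-root -o report.tsv
```

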