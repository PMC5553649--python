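# Methods

## Tree model and conventions

All algorithms run on a minimal rooted structure: nodes with an ordered
child list and a non-negative branch length to the parent. An unrooted
tree is the usual newick convention — a base node with three or more
children — and every method treats the input rooting as arbitrary.
Multifurcations are supported throughout (all recursions sum or maximize
over the full child set). Branch lengths are mandatory: every quantity
the package computes is a function of them. Negative lengths are
rejected by default because the variance quadratic and the midpoint
search assume a metric; the CLI flag `--clamp-negative` substitutes 0
and warns, for trees from software that emits small negative estimates.

A root position is an (edge, offset) pair, with the offset measured from
the parent-side endpoint. Rerooting at offset 0 or at the full edge
length roots at the existing node rather than introducing a degree-2
vertex, except at a leaf endpoint, where a new vertex with a zero-length
pendant branch is kept so the leaf set is preserved. When a bifurcating
base loses its root status during rerooting, the resulting degree-2
vertex is spliced out and its two branch lengths merged. Internal node
labels ride along verbatim; support values are *not* re-oriented on
rerooting (a documented limitation — re-mapping support is a
tree-annotation concern, not a rooting one).

Newick serialization prints 12 significant digits, enough for round
trips to be lossless at the 1e-9 tolerances the tests assert. Variance
is the population variance (divide by n), matching the definition the
minimization is stated in.

## MinVar rooting

The variance of root-to-tip distances restricted to one edge is an exact
convex quadratic in the offset (coefficients from the clade size |v|,
clade distance sum SI, whole-tree distance sum ST). The implementation
does one pre-order pass (distances to the start root), one post-order
pass (|v| and SI), and a final pre-order pass that propagates ST and the
at-node variance and minimizes every edge's quadratic on its feasible
interval. The global minimum over all edges (the initial root included
as a candidate) is exact — no grid, no iteration — and the whole
procedure is O(n).

Numerical choices:

- Ties between candidates within relative 1e-12 go to the candidate seen
  first in pre-order of the *input* tree, making results deterministic
  for a given input. (Equal-variance ties essentially never occur with
  continuous branch lengths; determinism is for reproducibility, not
  correctness.)
- The quadratic's leading coefficient a = 1 − β² is strictly positive on
  any proper edge; a guard treats |a| ≤ 1e-15 (possible only for
  degenerate collapsed clades) as linear and compares endpoints.
- Two-leaf trees need no special case: the formulas degenerate to the
  midpoint of the single edge, which the tests pin down.
- Accumulations are plain left-to-right float sums. At desk scale
  (n ≤ 1e5 in the scaling tests) this is far inside the 1e-8 tolerances;
  for much larger trees a compensated summation would be the first thing
  to revisit.

The brute-force cross-check used in tests evaluates the variance by
explicit path sums on a uniform grid per edge, then fits the (exactly
quadratic) restriction through three probes and probes its vertex too —
independent of the linear-time machinery, and exact up to float error.

## Midpoint rooting

A post-order pass computes MI(u), the deepest leaf inside u's clade; a
pre-order pass propagates MO(u), the deepest leaf reachable through the
parent (each child's best sibling taken from a precomputed top-two
table, so multifurcations stay linear). On the edge (p(v), v) the
candidate offset from the parent is x* = (MI(v) − MO + e_v)/2; the first
edge in pre-order where x* is feasible carries the unique center of the
tree, and the search stops there. The published pseudocode leaves the
reference point of x* ambiguous; measuring from the *parent* is the
orientation that makes the root the diameter midpoint, which the
all-pairs diameter oracle and an independent dendropy midpoint oracle
both confirm. Exact-node midpoints collapse onto the node, consistent
with the tree model. The returned score, (MI(v) + MO + e_v)/2, equals
half the tree diameter.

## Outgroup rooting

The separating edge is found by comparing each edge's child-side leaf
set against the outgroup set and its complement (so outgroups "split" by
the input rooting are still found). Failures name the intruding leaves.
The position along the separating edge is topologically irrelevant for
triplet-style metrics; the midpoint is the symmetric default, with
`ingroup-end`/`outgroup-end` offered for completeness (those collapse
onto an end vertex, so the outgroup/ingroup bipartition is then not
displayed as the two root clades). Multi-taxon outgroups are supported
even though the simulation studies attach a single outgroup.

## Accuracy metrics

Triplet distance enumerates all C(n,3) leaf triples with O(1) work per
triple after a pairwise LCA-depth table; deliberately the simple cubic
algorithm, because evaluation happens on tens of leaves and the
implementation must be easy to verify against an independent clade-set
oracle (which the tests do exhaustively for n ≤ 8). Triples the
*reference* leaves unresolved are excluded from the denominator; triples
the estimate leaves unresolved count as mismatches — the literal reading
of "reference triplets also found in the estimate". Ideal rooting tries
the midpoint of every edge of the estimate (plus its own base) and
returns the minimum triplet distance, which is zero iff the unrooted
topology is correct; "delta triplet" subtracts that floor. Branch
distance counts branches between the estimated and true root positions
on the shared unrooted topology (0 = same edge, 1 = adjacent edges) and
normalizes by the maximum leaf-to-root edge count measured from the
*true* root — the reference object in the true-gene-tree experiments
where this metric applies; the estimated-root alternative is within one
of it in typical trees but is not what a fixed reference suggests. The
RF utility is the standard bipartition symmetric difference over 2n − 6.

## Synthetic models

`generate_ultrametric` produces strict-clock substrates: Yule
(pure-birth, rate 1) by default — tree shapes of a speciation process,
matching the birth–death species trees of the simulation studies this
package's test bed emulates — or Kingman coalescent; node times are
rescaled so the root sits exactly at the requested height. All
generators are deterministic given a seed.

*Random deviations*: every branch is multiplied by an independent
uniform draw on [1 − ε, 1 + ε] (any mean-1 bounded distribution
qualifies; uniform is the simplest and is pluggable). Defaults ε = 0.05,
n = 16, height 1 — small enough deviations that the MV root lands on a
root-adjacent branch in ≈97% of replicates, the regime where its signed
displacement provably has mean zero; the test checks that to 3 Monte
Carlo standard errors over 2000 replicates. The closed-form sufficient
bound on ε for root-adjacency is typeset ambiguously in its published
statement; `random_deviations_epsilon_bound` implements one documented
reading and the tests use conservative small ε (0.01–0.05) instead.

*Gamma rate heterogeneity*: per replicate a gamma shape k is drawn as
exp(Normal(location, sigma)) with sigma = 1; multipliers are
Gamma(k, 1/k), mean exactly 1 for every k, so the expected tree is
unchanged and only dispersion varies. The "clock deviation parameter"
(location) spans 0.15 / 1.5 / 5.0 for high / medium / low deviation, and
both mechanisms the studies vary are on by default: per-branch-per-tree
("gene by lineage") multipliers and per-species multipliers applied to
that species' pendant branch in every tree. Lower locations measurably
raise the coefficient of variation of root-to-tip distances, which the
tests assert as an ordering of medians.

What the generator does *not* emulate: gene-tree/species-tree
discordance (no coalescent gene-tree sampling within a species tree),
sequence-level noise, or gene-tree estimation error. Passing tests
therefore demonstrate the geometric and statistical properties of the
rooting methods under controlled clock deviations — not end-to-end
accuracy on estimated gene trees, where topological error dominates.
The analytic helper (2/3)e^−t quantifies how often an outgroup at t
coalescent units fails to be an outgroup in true gene trees, which is
the reason outgroup rooting of gene trees is unreliable even without
estimation error.

## Study sizes and the MV-vs-MP comparison

The test suite's simulation sizes — 2000 replicates of 16-leaf trees for
the unbiasedness check, 200 random trees (n ≤ 12) for brute-force
optimality, 100 replicates per deviation level of 30-leaf trees for the
accuracy study, and {1e3, 1e4, 1e5} leaves for the linear-scaling fit
(R² > 0.98 on wall time) — keep the whole suite under a minute while
leaving Monte Carlo error well below the asserted effects, with one
exception. The MV-vs-MP triplet-accuracy gap is genuinely small (in the
large published simulations it is ~0.006 absolute), so at 100 replicates
per level a strict per-level inequality would be decided by seed noise.
The study therefore asserts "matched or improved" the way the claim is
meant: per level, MP must not beat MV by more than 3 paired standard
errors, and aggregated over all three levels MV's mean triplet distance
must not exceed MP's. On cherry-heavy Kingman-coalescent substrates
(short recent branches, not the speciation-like shapes the published
studies used) the per-level ordering is *not* stable — a real property
of the methods worth knowing, recorded here rather than hidden.

## Known limitations

- Support values are not re-mapped on rerooting.
- Triplet distance is O(n³): fine to a few hundred leaves, not for
  thousands (the rooting algorithms themselves are linear).
- `ideal_rooting` re-runs the triplet computation per edge — O(n⁴)
  overall — and is meant for evaluation-scale trees only.
- The outgroup module roots on an edge; it does not diagnose long-branch
  attraction or choose outgroups.
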