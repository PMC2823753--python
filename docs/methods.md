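# Methods

## The network evolution model

A regulatory network is a directed graph over genes, held as a square
adjacency matrix with rows as regulators and columns as targets (the
orientation is a convention; it is fixed here and used consistently by the
simulators and the learners). The simulator evolves a *weighted* matrix so
that expression data can later be generated from the leaves; ancestral
reconstruction and refinement operate on the binarized {0, 1} pattern,
extended with the character `x` for genes absent from an organism.

On each branch, gene content evolves first, connections second:

1. every gene present at the branch start duplicates independently with
   probability `p_d`; the new copy's row/column is initialized by the
   chosen rule (below) and the copy receives a globally fresh id
   `family.k`, so orthology in the union gene space is exact by
   construction;
2. every branch-start gene is lost independently with probability `p_l`,
   removing its row and column (a copy created in step 1 cannot be lost on
   the same branch — the two content steps act on the branch-start gene
   list);
3. every remaining entry mutates, 0 → 1 with probability `p_01` (drawing a
   fresh signed weight) and 1 → 0 with probability `p_10`.

Duplicate initialization rules:

* **neutral** — each connection of the copy is an edge with the background
  probability `pi1`, independent of the source;
* **inheritance** — the copy inherits the source's row and column, then
  drops each inherited edge with rate `r_lose` and gains each absent one
  with `r_gain` (defaults 0.1: duplicated copies correlate with, but are
  not identical to, their source);
* **preferential** — the copy attaches to ~Binomial(n, pi1) partners drawn
  without replacement with probability proportional to total (in + out)
  degree. In-, out- or total degree are equally defensible; total degree
  is used because regulatory "hubness" shows up on both sides (regulators
  with many targets, targets with many regulators).

Self-edges (autoregulation) are permitted and treated like any other
entry. If a loss draw would empty a network the draw is repeated (and
counts as a fresh draw); this slightly biases extreme-`p_l` regimes and is
preferred over conditioning the model because it keeps per-branch
independence.

### Parameter defaults

| parameter | default | meaning / rationale |
|---|---|---|
| `p_d`, `p_l` | 0.04 | per-gene per-branch duplication/loss; calibrated with the analytic event-count recursion (`expected_event_counts`) so the standard 35-node/15-gene instance realizes ≈ 20 duplications and ≈ 20 losses along the tree |
| `pi1` | 0.15 | background edge density; mean in-degree ≈ 2.3 at 15 genes, in the sparse range typical of curated regulatory subnetworks |
| `p_01` | 0.009 | per-entry edge gain; chosen with `p_10` so the edge dynamics are stationary near `pi1` (p_01/(p_01+p_10) ≈ 0.15) and densities do not drift down the tree |
| `p_10` | 0.05 | per-entry edge loss (≈ 5% of present edges turn over per branch) |
| weights | \|w\| ~ U[0.25, 1], random sign | weight magnitude floor keeps every true edge detectable in principle |
| branch lengths | events are per-branch | the model defines single per-branch probabilities, not rates × time; an optional mode scales the four probabilities by branch length (off by default) |

All probabilities are exposed on `EvoParams` and none is derived from data.

## Expression simulators

**DBNSim (binary).** A first-order dynamic Bayesian network: gene *i* is on
at time *t* with probability `sigmoid(beta * sum_j w_ji (2 x_j(t-1) - 1) +
bias)` over its regulators *j*. The logistic link is a modeling choice (the
conditional only has to respect weight sign and magnitude); `beta = 3`,
`bias = 0` by default, which keeps a single ±0.25-weight parent detectable
but not deterministic. Genes without regulators are redrawn from
Bernoulli(q0 = 0.5) at every step — matching the explicit treatment of
parentless genes in the continuous simulator, where the same ambiguity is
resolved the same way. Series length defaults to 13·n for an n-gene
network, the sample-size rule used throughout the benchmark.

**GeneSim (continuous).** Row-vector linear dynamics
`x(t+1) = x(t) + k_e (x(t) - z) C + eps`, with `k_e = 7`, constitutive
level `z = 50`, Gaussian noise (σ = 10 on the 0–100 scale), and parentless
genes (and all genes at t = 0) uniform on [0, 100]. Because regulators act
through columns of C under the row-vector convention, a single edge a→b of
weight w gives exactly `x_b(t+1) - x_b(t) = k_e (x_a(t) - 50) w` — the
two-gene worked case asserted in the tests. The linear map can be unstable
for large `k_e`·|w|; the simulator raises on overflow rather than
returning saturated values. Discretization for the binary learner is a
per-gene median split (robust to scale and offset; a fixed-threshold mode
exists); constant genes discretize to all-0 with a warning.

## Base inference (DBI)

Structure learning maximizes the decomposable penalized likelihood
`log Pr(D | G, θ̂) − k_p · #G · log N` with `#G = Σ_i 2^{|Pa_i|}` free CPT
parameters and `N = T − 1` observed transitions (the effective sample size
of the likelihood). CPTs are empirical conditional frequencies with
Laplace smoothing α = 1 (α avoids log 0; α = 0 reproduces the unsmoothed
ML fit where defined). Because the score decomposes over genes, each
gene's parent set (parents act at t − 1, at most `max_parents = 3`,
self-parents allowed) is found by exhaustive enumeration — exact and
cheap at benchmark sizes; a greedy forward-selection mode covers larger
problems. Ties break toward smaller parent sets, then lexicographically.
The 11-point sweep shares the per-parent-set log-likelihoods across grid
points, which is exactly equivalent to independent runs since only the
penalty term involves `k_p`.

The learned weight of edge j→i is the signed CPT effect of j on i — the
mean over the other parents' configurations of P(on | j = 1, rest) −
P(on | j = 0, rest).

## Ancestral gene contents

Three models reconstruct internal-node gene sets from the leaf presence
matrix: duplication-only (each node is the intersection of its subtree's
leaf gene sets; provably the minimum number of duplications among
loss-free histories), loss-only (unions; minimum losses among gain-free
histories), and per-gene joint ML on the 2-state presence character with
gain `g01 = p_d` and loss `g10 = p_l` — presence appears through
duplication and disappears through loss, so no new parameters are
introduced. The per-column root prior defaults to the column's leaf
presence frequency (clipped away from 0/1). Histories derived from
contents place each event on the branch where the content changes, which
these models make unambiguous. Multi-copy families violate the 1-1
orthology simplification of the presence encoding; each ortholog column is
modeled independently, and `randomize_orthology` scrambles copy↔column
assignments to study the cost of wrong orthology.

## Ancestral networks: joint ML over {0, 1, x}

All leaf networks are embedded into the union gene space; entries of
absent genes are `x`. Given gene contents at every node, entries whose row
or column gene is absent are fixed to `x` before the recursion, and the
remaining entries are reconstructed independently (sitewise) by
max-product dynamic programming: for each node *i* and parent character
*a*, `L_i(a)` is the best subtree likelihood given the parent is *a* and
`C_i(a)` the optimal character; the root takes
`argmax_{a∈{0,1}} π_a · L_j(a) · L_k(a)` and a top-down pass reads the
labels off `C`.

The ternary substitution matrix is derived from the model parameters:

```
P'[a][b] = (1 − p_l) · P[a][b]   a, b ∈ {0, 1}   (survive, then mutate)
P'[a][x] = p_l                                    (gene lost)
P'[x][b] = p_d · π_b                              (gene appears; edge by prior)
P'[x][x] = 1 − p_d
```

Rows sum to 1 exactly, and the {0, 1} block reduces to P when
`p_d = p_l = 0`, where the recursion coincides with standard 2-state joint
ML pruning (asserted against an independent implementation). At a
content-absent internal node the recursion multiplies `p'_ax · L_j(x) ·
L_k(x)`; `L` at character x is defined at every node by the same leaf rule
`L_i(a) = p'_{a,b}` and recursion, which extends the forced-x case
symmetrically to content-present children. Numerics: all bookkeeping in
log space (max-product is unaffected); argmax ties break toward 0,
biasing reconstruction to sparsity. The per-entry computation is
vectorized over all matrix entries at once; a scalar per-site path exists
and the two are asserted equal.

## Refinement

Both refiners compare each leaf entry with the corresponding entry of the
leaf's reconstructed parent; only entries that are not `x` in **both**
matrices are touched, so gene contents are never edited.

* **RefineFast** draws the refined entry from the parent's evolutionary
  distribution: 1 with probability `p_a1` where *a* is the parent value.
  From the second round on, the samples replace the leaves entirely.
* **RefineML** is deterministic: with parent value *a*, leaf value *b* and
  belief coefficient `k_b`, it assigns `argmax_{c∈{0,1}} p_ac · Q(c)`,
  `Q(c) = k_b` if `c = b` else `1 − k_b`.

The belief coefficient mixes two terms, `k_b = β·term1 + (1−β)·term2`
(β = 0.5): *term1* is the base learner's confidence in the entry — for a
fitted edge the absolute CPT effect; for an absent entry, 1 minus the
absolute empirical single-parent effect of the candidate regulator, so
confidently-absent entries score near 1 and suspiciously-absent ones near
0; for networks from non-DBN tools a normalized |weight| rank substitutes.
*term2* is the inverse-distance-weighted fraction of the other leaves
possessing both endpoint genes, `Σ_{i≠k}(1−h_i)/d_ik ÷ Σ_{i≠k} 1/d_ik`
with `h_i = 0` iff leaf *i* has both genes: corroboration by close
relatives counts more, and it degenerates to 1 (all leaves have the genes)
or 0 (none do).

The iterative driver alternates reconstruction and refinement for up to 3
rounds (stopping early at a fixed point). Beliefs are computed once from
the original base-learner models and frozen — the CPTs were fitted to the
original data, and recomputing them against refined networks would let the
refinement certify itself.

## Evaluation

Sensitivity TP/(TP+FN) and specificity TN/(TN+FP) are counted over
adjacency entries that are not `x` in both prediction and truth: scoring
absent-gene entries would mix content inference into edge inference, and
refinement never alters contents. Counts are pooled (micro-averaged) over
organisms per grid value — one curve per experiment — with a per-organism
macro mode available. Weighted networks from external tools are binarized
at 11 |weight| thresholds to trace the same trade-off. The edge-sharing
table classifies the union of edges by the number of networks containing
them, with a cumulative column.

## What the simulation does and does not emulate

The generator produces Erdős–Rényi root topologies with i.i.d. entries at
density `pi1`, inherited signed weights, and expression data drawn from
the same model family the learner fits. Real regulatory networks have
heavier-tailed degree distributions (TF hubs), module structure, and
expression dynamics that no DBN generated; passing benchmarks here shows
the machinery is correct and self-consistent, not that accuracy carries
over to biological data.

One consequence, visible in the acceptance summary, deserves a note. On
the standard instance (35-node tree, 15-gene root, ≈ 20 duplications and
losses, 13·n samples) the exact exhaustive learner is strong (mean
balanced accuracy ≈ 0.9), and much of its residual error is *shared*
across organisms: genes whose true in-degree exceeds `max_parents` lose
the same edges in every leaf, and the weakest-|w| edges are missed
everywhere. Shared errors survive ancestral averaging, so on this instance
RefineML sits at the base learner's level on the grid-mean (clearly above
it on the dense half of the penalty grid, below at the sparse end) while
dominating RefineFast throughout. Phylogenetic refinement nets a gain
precisely when independent, per-organism inference error dominates
between-organism evolutionary divergence — the regime of noisier base
learners or scarcer expression data than this benchmark's 13·n rule.

## Problem sizes

Unit and property tests run on 2–12-leaf trees and 3–15-gene networks;
exhaustive oracles (ancestral enumeration, whole-structure brute force,
history minimality) cover ≤ 6 leaves / ≤ 4 genes where enumeration is
exact. The end-to-end benchmark and the acceptance script use the
standard instance above with 10 replicates, a few minutes on one CPU.

## Known limitations

* No selection or fitness: all events are neutral and independent.
* Branch-length-independent event probabilities by default (the optional
  scaling mode is linear truncation, not a proper matrix exponential).
* The presence-string content model treats gene columns independently and
  assumes 1-1 orthology; families with copy number > 1 per organism are
  handled column-wise, which understates their uncertainty.
* Joint (max-product) reconstruction only; no per-node marginal
  posteriors.
* DEI-style differential-equation inference is not included; externally
  inferred weighted networks enter through `read_network` plus
  `threshold_sweep`.
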