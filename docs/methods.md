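# Methods

## Scope and conventions

`phylodepth` analyzes rooted tree *topologies*.  Branch lengths in
Newick input are parsed and discarded; every node is treated as a
diversification event.  Unary (single-child) internal nodes are collapsed
on ingest with a logged warning, because a node that did not split is not
a diversification event under this reading.  Trees are used exactly as
rooted in the input; no re-rooting is attempted.  Distance-based
reconstructions are naturally unrooted, and re-rooting changes every
depth statistic — users comparing depth curves across sources should be
sure the rootings are comparable.

**Depth convention.**  depth(root) = 0, depth(child) = depth(parent) + 1.
This choice is forced by the initial condition used throughout: a lone
root has cumulative branch size C = 1 and Sackin index S = 0, which makes
the identities below hold without offsets.

## Exact statistics

For a subtree with node set {j}, size A = |{j}| and depths d_j:

* mean depth d = (Σ d_j)/A over **all** nodes (not only leaves);
* cumulative branch size C = Σ_j A_j (A_j = size of the subtree rooted
  at j), equivalently C = Σ_j (1 + d_j) = A(1 + d), so **d = C/A − 1**;
* Sackin index S = Σ_leaves d_leaf; for strictly binary trees
  **C = 2S + 1**.

A, C, S are integers and the identities are exact; `mean_depth` returns a
`Fraction`.  The implementation computes C by accumulating subtree sizes
(post-order) and d by summing depths (level-order), so the d = C/A − 1
test in the suite genuinely cross-checks two independent code paths.
The growth view of the binary identity — each leaf bifurcation changes S
and C by amounts that keep C − 2S invariant — is asserted in the tests by
bifurcating random leaves one at a time and re-checking both identities
after every step, rather than by fixing particular increment formulas.

All statistics are defined for polytomic trees; the C = 2S + 1 check
applies only where the subtree is strictly binary (tracked per row in
`subtree_stats` as `is_binary_subtree`).

## Extreme topologies and closed forms

Derived under the depth convention above and validated in the test suite
against brute-force `mean_depth` of the generated trees at every
admissible size up to 10^4 (the generators, not the formulas, are ground
truth):

| shape | admissible A | d(A) | leading behavior |
| --- | --- | --- | --- |
| star | A ≥ 3 | (A − 1)/A | → 1 |
| caterpillar | odd A ≥ 3 | (A² − 1)/(4A) | ~ A/4 |
| balanced, k levels | A = 2^(k+1) − 1 | ((k − 1)·2^(k+1) + 2)/A | ~ ln A / ln 2 |

Derivations: a caterpillar with L leaves (A = 2L − 1) has internal nodes
at depths 0..L−2 and leaves at 1..L−2 plus two at L−1; the depth total is
L(L − 1).  For the balanced tree, Σ_{j≤k} j·2^j = (k − 1)·2^(k+1) + 2.
The star is taken as *the* fully polytomic minimizer of mean depth at
fixed A (it is the unique one).  A star needs A ≥ 3: a root with a single
child would be a unary chain.  The envelope ordering
d_star ≤ d_balanced ≤ d_caterpillar is asserted at all common sizes.

`make_max_balanced` builds maximally balanced trees for leaf counts that
are not powers of two (ceil/floor split at every node); the 15-tip
fixture uses it, since no complete binary tree has 15 leaves.

## Simulators

**ERM null.**  Start from one leaf; repeatedly bifurcate a uniformly
chosen leaf until L leaves (A = 2L − 1).  Mean depth grows ~ ln A; the
suite checks the growth ratio between L = 64 and 256 against the log
prediction rather than fitting an exponent, which would need much larger
trees.

**Evolvability model.**  Synchronous branching from a single capable
root.  Per branching event: with probability p both daughters capable;
otherwise exactly one, the side chosen uniformly (the side choice is not
observable in topology statistics, which are exchangeable under it).
Capable-lineage count never decreases, so trees never go extinct.  Two
stopping rules (exactly one active): a generation count, or a node cap
under which the final generation still completes in full — branching is
synchronous, so realized sizes may overshoot the cap and are recorded.

Because branching is synchronous, every node created at generation g has
depth g.  This yields the expectation recurrences (z = 1 + p):
capable count z^g, E[A_n] = 1 + 2 Σ_{g<n} z^g, and
E[C_n] = E[A_n] + Σ_g g·(2 z^{g−1}).  The recurrences are the contract;
the closed forms at p ∈ {0, 1} (caterpillar/balanced) and Monte-Carlo
agreement at intermediate p are test oracles.  At large n, A ~ z^n and
C ~ n·z^n give d ~ ln A / ln z: the non-logarithmic depth scaling at
moderate sizes is a transient, checked in `asymptotic_depth_check`.

Randomness: one `numpy` Generator per replicate, seeded from
`(seed, replicate_index)` — replicate sets are reproducible and
order-independent.  Internally a replicate is stored as per-generation
layers (parent indices + capability flags); the object-level trees and
the vectorized (A, d) subtree-point fast path are both derived from the
same layers, and the suite asserts they agree point for point.

## Binning and exponents

Subtree points are pooled over trees ("each subtree is one point");
points from nested subtrees are not independent, so the per-bin standard
error is a descriptive spread, not a confidence interval.  Bin k spans
[min_A·base^k, min_A·base^(k+1)); defaults base = 2 and min_A = 2
(leaf points d = 0 break log scales; excluding them is explicit, not
hidden).  The bin abscissa `A_center` is the geometric mean of the A
values inside the bin — the mass-weighted center, which makes a
single-size bin sit exactly at that size and in turn makes the local
exponents exact on exactly sampled curves.

Local exponents between consecutive bins i, i+1:
η_i = Δln d / Δln A (power-law probe) and β_i = Δln d / Δln ln A
(squared-log probe).  Bins with mean d ≤ 0 are skipped with a warning;
β is NaN when a bin center is ≤ e.  On exact d = A^0.5 and d = (ln A)²
curves the estimators recover 0.5 and 2 to machine precision.

## Size-distribution fit

Tip counts are fitted as a discrete power law P(T) ∝ T^−γ, T ≥ T_min = 2,
by maximum likelihood using the Hurwitz zeta normalization; the standard
error comes from the observed Fisher information (numerical second
derivative of ln ζ(γ, T_min)).  MLE was chosen over a straight-line fit
for statistical defensibility; a log-binned least-squares slope is
available via `method="ls"` for comparability.  Fits on fewer than 100
sizes, or on degenerate support, are refused rather than silently
returned.  The CCDF uses the strict convention F(T) = P(size > T),
reported at each observed size (so F at the smallest size is below 1;
the series is what a log-log survival plot needs).  Synthetic sizes are
drawn from `scipy.stats.zipf` with rejection below T_min — generation and
estimation deliberately use independent routes.

## Model fitting

`fit_p` rebuilds, for each grid p, the model's binned curve from all
subtrees of freshly simulated replicates, using the empirical curve's
binning, and scores the RMS difference of binned mean depths over
overlapping bins.  The RMS objective is fully specified and deterministic
given the curves; an inverse-variance-weighted variant (weights 1/se²,
pooled over both curves) is available but not the default, because
pooled-subtree standard errors are descriptive (above).  Ties break
toward the smaller p.  The default grid is 0.21–0.27 in steps of 0.01,
fully user-configurable.  The error's Monte-Carlo uncertainty is
estimated by splitting replicates into 5 batches.

Replicate budgets: the fitting loop's Monte-Carlo noise must be small
compared with the error separation between adjacent grid values (~0.03
in depth RMS at grid step 0.01 around p ≈ 0.24 with 14-generation
trees); 2,000 replicates per grid value achieves that and is what the
recovery tests use.  At that budget, recovery experiments at p_true =
0.24 land within one grid step of the truth in ≥ 90% of runs.

## Synthetic data: what it does and does not emulate

The fixture generators produce (i) the 15-tip worked-example topologies
(balanced / caterpillar / a fixed seeded ERM draw standing in for a real
15-tip phylogeny — labeled synthetic), (ii) seeded ERM tree sets, and
(iii) tree sets with power-law tip counts built by ERM growth.  These
reproduce the *structural* conditions the analyses need — binary
topologies, log-spread sizes, known generating parameters — but not
features of real phylogeny databases: reconstruction artifacts
(unresolved polytomies concentrated near the root, method-dependent
rootings), correlated families, or non-ERM balance in the individual
trees.  Passing tests therefore demonstrate that the estimators recover
known truth under the stated generative models, not that any particular
empirical database follows those models.

## Problem sizes used by the test suite

Chosen as the package's own verification budget: identity checks on
1,000 random binary trees up to 10^4 nodes; closed-form sweeps at every
admissible size ≤ 10^4; expectation recovery at n = 12 generations ×
5,000 replicates; p-recovery over 20 experiments (1,000 empirical +
7 × 2,000 fitting replicates each, 14 generations); γ-recovery over 50
catalogs of 7,738 sizes.  The whole suite runs in a couple of minutes on
one CPU.

## Known limitations

* Depth statistics depend on the rooting; nothing here infers roots.
* Binned-curve SEs understate uncertainty (nested-subtree correlation).
* The evolvability model has no extinction, no time-continuous rates and
  no trait structure beyond the capable/incapable flag; p is its only
  parameter, and the grid-search fit is not a likelihood.
* Local exponents are finite differences of binned curves: noisy in
  sparse bins and biased inside the finite-size cutoff of simulated
  trees (the last bins before the largest sizes).
* No formal model selection between d ~ A^η and d ~ (ln A)^β scaling is
  attempted; the package reports both local-exponent series and leaves
  the verdict to data with larger trees.
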