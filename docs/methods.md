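# Methods

## Model and procedure

`monoseq` screens a genes × samples expression matrix for genes whose mean
expression changes monotonically across ordered pathologic stages. The
screen has three steps, applied either to the raw values or to
network-weighted values.

### GeneRank weighting

For sample *i* with expression vector *e* over *p* genes, the weighted
vector *r* solves

    (I − d·W·D̃⁻¹) r = (1 − d) e

with *W* the symmetric 0/1 gene-interaction adjacency, *D̃* the diagonal
degree matrix, and damping *d* ∈ [0, 1). The transform blends each gene's
own expression with the (degree-normalised) scores of its interaction
partners: at *d* = 0 it is the identity, and as *d* grows the network
topology dominates. Well-connected genes with modest expression shifts are
boosted relative to isolated genes with equally modest shifts — the
mechanism by which the weighted screen can find progression genes that a
raw screen misses.

Numerical choices:

- **Zero-degree convention.** Isolated genes get a unit diagonal entry in
  *D̃*. Their *W* column is all-zero, so their solution is
  *r* = (1 − *d*)·*e* regardless; the convention only prevents a division
  by zero and matches the standard handling of dangling nodes in
  PageRank-family solvers.
- **Domain of d.** *d* = 1 makes the system singular (the matrix has a
  zero eigenvalue for each connected component), so the implementation
  requires *d* ∈ [0, 1); "purely network-driven" is a limit description,
  not a supported input. Default *d* = 0.5, an even balance.
- **Solver.** Dense LU below 500 genes, sparse LU above; both are direct,
  and a single iterative-refinement pass backs the residual contract
  ‖(I − dWD̃⁻¹)r − (1−d)e‖∞ ≤ tol·max(1, ‖(1−d)e‖∞), default tol 1e−8.
  One factorisation serves all samples of a matrix.
- **Output scale.** The solved vector *r* is used directly as the weighted
  expression value; no re-ranking or normalisation follows. The downstream
  Kruskal–Wallis test is rank-based, so any within-sample monotone
  rescaling would be immaterial anyway; an optional `rank_transform` flag
  exposes the literal within-sample ranking for users who want it, and a
  `shift_nonnegative` flag subtracts the per-sample minimum for inputs on
  scales that go negative. Both are off by default.

### Kruskal–Wallis screen and monotone classification

Per gene, the tie-corrected Kruskal–Wallis H across the stage groups is
referred to a χ²(K−1) null (`scipy.stats.kruskal`); constant genes are
assigned (H = 0, p = 1) rather than dropped, keeping the multiple-testing
denominator equal to the input gene count. P-values are adjusted across
genes by Benjamini–Hochberg step-up (`statsmodels`), with Bonferroni and
`none` as alternatives. Genes at or below the adjusted-p threshold α are
then classified from their stage-mean profile: **MI** when the means are
nondecreasing with at least one strict increase, **MD** for the mirror,
`none` otherwise. An all-equal profile satisfies both non-strict chains
but carries no trend, so it is classified `none` — it would not pass the
screen anyway. Thresholding precedes classification, so raising α can only
add MI/MD labels, never remove them; run summaries report the counts over
the grid α ∈ {0.05, 0.1, 0.15, 0.2}.

A stage coded 0 denotes a normal-control group. It always contributes the
first mean of the monotonicity chain; whether it also forms its own group
in the Kruskal–Wallis test is a flag (`include_control_in_test`, default
on). Sub-stage labels such as IA/IB/IIA/IIB are mapped to consecutive
integers in the stage file; the package never parses Roman numerals.

### MFSelector comparator

Per gene and each cumulative split *k* (stages ≤ k vs > k), a single
threshold ("discriminating line") is chosen to minimise the misclassified
count; DEtotal is the sum over the K−1 splits. Conventions, which the
score is only defined up to:

- Candidate thresholds are all observed values of the gene (a superset of
  any per-stage candidate set, so the minimum can only tie or improve).
- Under the increasing hypothesis a sample exactly on the line counts as
  below it; on tied counts the smallest threshold wins.
- The decreasing hypothesis is scored as the increasing score of the
  negated values, making the sign-flip duality
  `detotal(v, inc) = detotal(−v, dec)` an identity rather than an
  approximation.
- `perfect_monotone` requires DEtotal = 0 **and** strictly ordered lines
  across the K−1 splits.

Significance comes from permuting the stage labels: p = (1 + #{permuted
DEtotal ≤ observed}) / (B + 1) with B = 1000 by default (add-one estimator,
so p ≥ 1/(B+1) and never 0). By default each of the B shuffles is applied
to all genes at once, preserving between-gene correlation under the null;
a flag switches to independent per-gene streams. An `exhaustive` mode
enumerates all label arrangements (n ≤ 9) and returns the exact null
probability without the add-one correction. The permutation p-values are
BH-adjusted with the same routine as the Kruskal–Wallis screen rather than
by a separate q-value estimator — one fewer estimator, and directly
comparable across methods.

## Synthetic cohorts

The generator emulates staged bulk-expression cohorts on a log-like scale:
background genes are i.i.d. Normal(baseline = 8, σ²) across samples; a
planted MI gene at stage k has mean baseline + k·effect_step·σ (MD
mirrored); stages default to 4 groups of 15 samples, within the group-size
range of real staged cohorts (handfuls to a few dozen per stage). The
default study condition plants 50 MI + 50 MD genes among 1000 with
effect_step = 1.0 and σ = 1.0 — a one-standard-deviation mean step per
stage, a moderate effect for which the screen should be sensitive but not
trivially so. Networks come from either an Erdős–Rényi or a
Barabási–Albert (scale-free) generator via `networkx`; the scale-free
default matches the heavy-tailed degree distributions of curated
protein-interaction networks. An optional plateau effect shape (rise then
flat) exercises the non-strict chain's tie handling, and a hub-planted
mode places the signal on the highest-degree genes to exercise what the
weighting is meant to reward.

What the simulation does **not** model: probe-level microarray artifacts,
batch effects, RNA-seq count overdispersion, correlated co-expression
among background genes, and any dependence between a gene's expression and
its network degree (except in hub-planted mode). Passing recovery tests
therefore demonstrate correctness of the procedure under clean Gaussian
conditions, not performance claims on real cohorts.

## Problem sizes

The test suite and the acceptance script run the recovery study at 1000
genes × 60 samples (sensitivity and false-discovery proportion of the raw
and weighted screens, direction fidelity), oracle sweeps at n ≤ 30, and
the MFSelector permutation null at 200 genes × 200 permutations — sizes at
which every check completes in seconds while the planted/background
contrast is unambiguous.

## Known limitations

- Gene identifiers are matched as exact case-sensitive strings; no
  alias/symbol resolution is attempted. Expression genes absent from the
  network are kept as isolated nodes by default (`isolated_policy=keep`),
  receiving a purely expression-driven score; `drop` restricts to the
  intersection instead. Which is preferable depends on how complete the
  network's gene universe is relative to the platform.
- The monotone classification is a point decision on stage means; it
  carries no uncertainty of its own beyond the Kruskal–Wallis screen, so a
  gene squeaking past α with a noisy, barely-monotone profile is labelled
  as confidently as a textbook staircase.
- MFSelector's permutation null is exchangeable across stages; strong
  stage-size imbalance makes the DEtotal null distribution lumpy and the
  permutation p conservative at small B.
- The CLI's `weighted` method is deterministic; only simulation and
  permutation steps consume the seed.
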