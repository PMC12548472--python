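# Methods

## Overview

`phagepanel` implements a phenotype-to-receptor concordance analysis for
phage collections: spot-test titers become efficiency-of-plating (EoP)
records and receptor-requirement profiles; host-range matrices drive greedy
panel design; mixed phenotype tables are clustered; and competing
classification schemes are compared with the Adjusted Rand Index (ARI).
This note records the models, conventions and deliberate design choices.

## EoP and reduction calls

For phage *p* and strain *s*, EoP(p, s) = titer(p, s) / titer(p, reference).
The reference strain's titer must be finite and positive; an ND spot (no
plaques at any dilution) or a zero titer on the test strain means complete
loss of infectivity, encoded as EoP 0 with log₁₀ EoP = −∞.

*Replicate aggregation.* The summary log EoP of 3–7 biological replicates is
the arithmetic mean of the finite replicate values; ND replicates are
discarded and their count reported, and an all-ND set stays ND. This
generalizes the convention used when a minority of trials detect plaques
(e.g. averaging the three countable trials out of seven).

*Boundaries are strict.* A reduction in infection efficiency is
log₁₀ EoP < −1 ("more than 10-fold drop"): exactly −1 is *not* reduced.
Likewise, the adsorption assay rate 100 × (t₀ − t₁₀)/t₀ marks a
target-receptor mutant only when strictly below 20%. The rate is computed as
a single fraction so the 20% boundary is exact in floating point.

## Receptor-requirement profiles

Given a boolean phage × strain reduction table and a strain → mutated-genes
map, candidate receptor genes for phage *p* are the union of gene sets of
the strains that block *p*. Two refinements follow:

* **Subset exoneration.** Gene *g* is removed from the candidates when some
  strain that does *not* block *p* carries a gene set containing *g* that is
  a subset of a blocking strain's set. The canonical case is a single-gene
  mutant the phage still infects, which clears that gene from any
  co-mutated blocking strain. Exoneration requires an *observed*
  non-blocking strain — nothing is inferred from gene annotations.
* **Ambiguity flags.** A surviving requirement is unambiguous only if some
  blocking strain's surviving genes reduce to exactly that gene; otherwise
  (e.g. two double mutants sharing one gene, neither set nested in the
  other) all involved genes are kept at 1 and flagged ambiguous.

An override table ((phage, gene) → 0/1) is applied last and clears flags; it
is the designated channel for complementation or knockout-library evidence
that the reduction matrix alone cannot express. The bundled reference
dataset ships such an override table, and re-deriving its published
requirement matrix from the raw reduction calls plus overrides is part of
the test suite: the raw screen leaves the waaG requirement (shared by every
phage except T5, hence non-discriminative) and the wecA / manB-1 / ompA /
tolA attributions open, exactly as multi-gene knockouts force.

Receptor **types** are equivalence classes of identical profile rows
(ambiguity flags ignored), lettered a, b, c, … in order of first appearance
along the phage ordering — so the letters are reproducible functions of the
input row order.

## Greedy panel selection

The discriminatory power of a strain subset S is the number of distinct
phage row-vectors restricted to S (the empty panel scores 1). Strains are
added greedily by marginal gain; ties go to the earlier input column, and
selection stops at zero marginal gain — the saturation point where the panel
already realizes every distinct full row — or at an optional `max_strains`
cap for forcing a fixed panel size. Greedy set-cover-style selection is a
heuristic: it is exact for the first pick (tested against exhaustive search)
but not guaranteed optimal overall, which mirrors its intended screening use.

## Mixed-data clustering

*Gower distance.* d_ij = Σ_f w_f δ_f(i,j) / Σ_f w_f over the features
observed in both items (pairwise deletion with weight renormalization —
the standard Gower treatment of gaps). Binary features contribute a 0/1
mismatch; quantitative features contribute |x_i − x_j| / range_f with the
range over observed values. Zero-range features contribute δ = 0 but keep
their weight in the denominator. A pair sharing no observed feature is an
error, not a guess. Gower output is always in [0, 1].

*Complete linkage.* Naive O(n³) agglomeration minimizing the maximum
between-cluster member distance. Equal-height merge candidates are broken
by the lexicographically smallest cluster-index pair (creation order),
making dendrograms reproducible on tied data; on untied data the merge
heights and cut memberships match SciPy's implementation (a test, not an
implementation dependency — collection sizes here are tens of phages, so
the cubic loop is irrelevant to runtime).

*Cutting and silhouettes.* Cutting at k undoes the k−1 highest merges.
The silhouette of item *i* is (b_i − a_i)/max(a_i, b_i) with a_i the mean
within-cluster distance and b_i the smallest mean distance to another
cluster; singleton clusters score 0 (the standard convention), as does
max(a_i, b_i) = 0. `select_k` sweeps k over complete-linkage cuts and takes
the argmax of the average silhouette, resolving ties to the smallest k
(parsimony). The default sweep is 2..min(10, n−1): published descriptions
of this workflow vary between an upper bound of 9 and 10, so the wider
range is the default and both bounds are parameters.

*Trees.* Phylogeny-based classifications are consumed as Newick trees and
converted to patristic distance matrices (sum of branch lengths along the
leaf-to-leaf path). Which tree-derived distance originally fed such
analyses is generally not stated; patristic distance is this package's
documented choice. Every non-root edge must carry an explicit nonnegative
branch length — there is no silent default.

## Concordance

With contingency counts n_ij, a_i, b_j over n items:

ARI = (Σ_ij C(n_ij,2) − Σ_i C(a_i,2) Σ_j C(b_j,2)/C(n,2)) /
(½[Σ_i C(a_i,2) + Σ_j C(b_j,2)] − Σ_i C(a_i,2) Σ_j C(b_j,2)/C(n,2))

computed with exact integer combinatorics before one float division. When
both partitions are trivial (both all-singletons or both single-cluster)
the formula is 0/0; the package returns 1 for identical partitions and 0
otherwise, with a warning. Canonical first-appearance relabeling is applied
before comparison for readable output; it provably cannot change ARI and a
test asserts as much. Display values are rounded to 2 decimals; raw values
are always retained.

## Synthetic-data generator

`SyntheticConfig` / `simulate_dataset` produce a screen with planted ground
truth. Defaults mirror the reference study's shape: 13 phages, 6 receptor
types (round-robin assignment), reference titer 10⁷ PFU-equivalents, 3
spot-test replicates, p(ND | blocked) = 0.5, a 16-strain binary host-range
panel and 4 quantitative physiology features. Remaining noise defaults
(log-EoP sd 0.3, spurious-drop probability 0.02, host-range bit-flip rate
0.05, between-type separation Δ = 2 with within-type sd σ = 0.5) are chosen
as plausible assay-scale noise for test discrimination — the original
study's noise magnitudes are not published and these are not estimates of
them.

Construction details:

* Each type requires a distinct gene set: one unit gene per type, padded
  with private genes to `genes_per_type`; the second type's set is the
  first type's plus its own unit gene, planting the one-bit near-identical
  type pair that real requirement tables show. Knockout strains are one
  single mutant per gene (by default) plus seeded random double mutants.
* Blocked phage–strain pairs read ND with probability `p_nd_given_blocked`,
  else a finite titer with log EoP uniform in (−5, −2). Permissive pairs
  draw log EoP from a normal(0, noise_sd) truncated above −1, flipped to a
  spurious drop (uniform in (−4, −1.5)) with probability `p_spurious_drop`.
  The truncation makes "zero noise ⇒ exact recovery" literally true: with
  `p_spurious_drop = 0` no permissive pair can ever be called reduced, so
  all false reductions come from the explicit spurious mechanism, whose
  empirical rate the tests check against its nominal value.
* Quantitative features have per-type means Δ·N(0,1) and within-type sd σ;
  binary host-range bits are per-type patterns (redrawn until pairwise
  distinct) flipped at rate ε. The same bits form the infection matrix used
  for panel-selection tests.
* All randomness flows through one `numpy.random.default_rng(seed)` stream;
  identical configs give bit-identical bundles.

What the generator does *not* emulate: adsorption kinetics, sequence-level
structure, phylogenetic tree topologies (patristic tests use hand-written
Newick fixtures), correlated measurement error between replicates, and
plate-level batch effects. Passing the recovery suite therefore shows the
pipeline is correct under its own model assumptions, not that real screens
are this clean.

## Problem sizes and verification

Desk-scale computations (the bundled 13/16-phage dataset) run in well under
a second. Oracle tests compare against independent implementations —
per-pair Gower loops, brute-force linkage over cluster pairs, graph
shortest paths for patristic distances, scikit-learn for silhouette and
ARI — to 1e−12 on random instances up to n = 50. Parameter-recovery tests
use zero-noise bundles with k ∈ {2..6} planted groups and n = 3k phages;
the noise-response Monte Carlo uses 50 replicates per bit-flip rate at 12
phages, sizes at which the whole suite completes in a few seconds.

## Known limitations

* The exoneration rule assumes knocking out a required gene always blocks
  the phage; partial-redundancy biology (alternative receptors, genetically
  redundant gene pairs) must come in through overrides.
* Greedy panels are not globally optimal and strains are unweighted (no
  cost/availability terms).
* Only complete linkage is provided; the silhouette criterion inherits its
  known bias toward balanced, compact clusters.
* ARI between two schemes says nothing about which is right — the package
  deliberately treats receptor typing as the reference scheme only where
  the caller does.
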