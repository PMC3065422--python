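# Methods

## The statistic and the tests

The test treats each distance matrix as a judge ranking the same n =
m(m−1)/2 objects (the taxon pairs, ordered row-major over the upper triangle
in canonical sorted-label order). Kendall's W is the variance of the column
rank sums divided by its maximum attainable value, with the standard tie
correction: W = 12S / (p²(n³−n) − pT), S = Σⱼ(Rⱼ − R̄)², T = Σₖ(tₖ³ − tₖ)
summed over each row's tie groups. Because the statistic depends on the data
only through within-matrix ranks, it is invariant to any strictly monotone
transform of any matrix's distances — which is why the choice between p
distances and model-corrected distances barely affects the outcome (the two
rank orderings agree at ρ > 0.95 in the simulated regime; asserted in the
test suite).

Testing pivots W into Friedman's χ² = p(n−1)W and references it against taxon
permutations: each permutation relabels a matrix's rows and columns
simultaneously, the Mantel-test convention, preserving the matrix's internal
structure while destroying cross-matrix alignment. The global test permutes
every matrix independently each round; the a posteriori test for matrix j
permutes only matrix j. A matrix congruent with others collapses the
statistic when permuted; an incongruent one barely moves it.

Implementation note: ranking commutes with taxon relabeling, so each matrix
is ranked once and a permutation round merely re-indexes rank vectors
through a pair-index map; the tie correction (hence the W denominator) is
permutation-invariant. This is algebraically identical to re-ranking
permuted matrices (property-tested against the naive route) and makes the
permutation loop a handful of vectorized array operations per matrix.

P-values use the add-one convention with the observed value included in the
reference distribution, p = (count≥ + 1)/(p_n + 1), the standard choice that
makes the minimum attainable p equal to 1/(p_n + 1) and keeps the test exact
at finite permutation counts. Ties between χ²* and χ²₀ count as exceedances.
A posteriori p-values are Holm-adjusted by default (Bonferroni and no
adjustment selectable); the per-matrix *congruence estimate* reported with
them is the matrix's mean rank (Mantel) correlation with the other p − 1
matrices.

Degenerate inputs are signalled, not silently absorbed: a matrix whose
distances are all tied has no defined ranking variance, and sets below four
taxa are rejected at load (the permutation distribution over 3 taxa is too
coarse to test anything).

## The simulation machinery

The Monte-Carlo harness reproduces a three-step replicate protocol:
(1) generate random additive distance matrices — one shared base matrix for
the congruent members of a set, independent matrices for the rest;
(2) infer a neighbor-joining tree from each matrix (exact recovery on
additive input, so this step matters only as pipeline fidelity);
(3) simulate one nucleotide alignment per matrix on its tree and recompute
distances at the configured level (corrected genetic distance by default;
path-length or topological distances skip steps of the chain).

**Random additive trees.** Topologies are uniform over the (2m−5)!! unrooted
binary labelled shapes, generated by sequential random leaf addition to a
uniformly chosen edge; taxon labels are then assigned by a uniform random
permutation (which also makes the tree's law exchangeable over taxa — the
property that guarantees the permutation test is exact under H₀ regardless
of every other generator choice). Branch lengths are i.i.d. exponential with
mean 0.1 substitutions per site by default. Real studies draw lengths from
the branch-length distribution of an empirical tree; the exponential is a
neutral stand-in for that unavailable multiset, and the sampler is
configurable (`branch_length_sampler`). Power — unlike validity — is
sensitive to this choice: heavy-tailed length distributions concentrate the
distance structure on a few splits, widening the permutation null and
shifting the power surface appreciably (see Limitations).

**Partial congruence.** A partially congruent matrix permutes a uniformly
chosen subset of k = round(q·m) taxa of the base matrix, relabeling rows and
columns by a uniform random permutation of the chosen labels — the classical
block permutation, under which some chosen taxa may keep their position. A
stricter derangement variant (every chosen taxon moves) is available via
`scheme="derangement"`; it destroys measurably more congruence at the same
nominal q, and the uniform reading is the package default.

**Neighbor joining.** Standard Saitou–Nei agglomeration on the Q-criterion;
exact ties break toward the lowest-index pair for determinism; negative
branch-length estimates are clamped to zero with the deficit transferred to
the sister branch so the joined pair's summed length is preserved (additive
inputs never trigger this).

**Sequence simulation.** GTR + Γ + I with empirical defaults: base
frequencies (0.1776, 0.3336, 0.2595, 0.2293) for A, C, G, T; exchangeabilities
rAC = 3.297, rAG = 12.55, rAT = 1.167, rCG = 2.060, rCT = 13.01, rGT = 1;
gamma shape α = 0.8168; invariant proportion I = 0.5447; these describe a
strongly transition-biased, rate-heterogeneous, GC-rich regime typical of
mammalian mitochondrial data. The generator is normalized to mean rate 1 at
equilibrium; the global mutation scale s (default 1, the conventional
branch-length scale) multiplies branch lengths, so s = 0.02 and s = 0.4
emulate slow and fast genes on the same history. Per-site rates are 0 with
probability I and otherwise continuous Γ(α, mean 1) draws shared across the
whole tree — gamma rates are *not* renormalized after the invariant class is
removed, the convention of mainstream simulators, and the corrected-distance
estimator uses the identical mixture so divergence estimates are internally
consistent (a two-leaf separation of 0.2 is recovered within 10% at
L = 20 000; asserted in the suite). α = 200 gives rate variance 0.005,
effectively homogeneous. Transition matrices come from the spectral
decomposition of the reversible generator in the π-weighted inner product;
the root sequence is drawn from equilibrium at an arbitrary internal node,
reversibility making the simulation law root-invariant (asserted).

**Corrected genetic distance.** "Correction with the generating parameters"
is implemented as fixed-parameter pairwise maximum likelihood: for each pair,
the log-likelihood of its 4 × 4 site-pattern count matrix under the
discrete-gamma (8 categories) + invariant mixture is maximized over the
single divergence t by a vectorized golden-section search on [10⁻⁹, 10]
(tolerance 10⁻⁸); all pairs are optimized simultaneously, so the cost per
matrix is a few dozen 4 × 4 batched exponentials regardless of taxon count.
Identical pairs are returned as exactly 0; pairs whose likelihood still
increases at the ceiling of 10 substitutions/site are capped there with a
warning. An analytic eigendecomposition-based GTR distance would be an
equally defensible reading; since the test is rank-based the two choices are
interchangeable in practice (the rank-agreement property above), and the
uncorrected p distance is available as a fast fallback.

## Experiment design and problem sizes

A grid cell fixes (m, L, M, CM, congruence kind, per-matrix model
parameters) and reports the rejection rate at α = 0.05 with the
normal-approximation 95% CI, rate ± 1.96·√(rate(1−rate)/replicates); an
exact Clopper–Pearson interval is selectable where rates sit on the 0/1
boundary. Replicates draw from independent child streams of a master seed
(NumPy `SeedSequence.spawn`), so cells are reproducible bit-for-bit and
parallelizable without changing results; failed replicates are counted and
reported, never dropped silently.

The package's own reference runs (`scripts/acceptance.py` and the
operating-characteristic tests) use 199 permutations per test and 150–500
replicates per cell — against the 999 × 1000 of a full study — keeping the
whole battery within minutes on one core at the cost of binomial noise of
roughly ±0.01–0.03 per rate. The permutation count affects only the
granularity of attainable p-values (minimum 1/200), not the validity of the
test.

## What the generator does and does not emulate

Simulated data are clean: no alignment error, no gaps or ambiguous bases, no
among-lineage rate variation, no model misspecification (distances are
corrected with the generating parameters). Passing tests therefore
demonstrate the statistical behaviour of the test under its own assumptions
— correct size, power ordering, rank-invariance — not robustness to the
pathologies of real alignments. Two further caveats:

* Validity (type-I error) is provably insensitive to the tree generator —
  label exchangeability alone makes the permutation test exact — and the
  measured rates confirm it. Power values, by contrast, are tied to the
  branch-length distribution and the taxon-permutation scheme; with a
  different empirical length multiset the power surface shifts while every
  qualitative law (monotone in m, in CM, in congruence level, in L) is
  preserved. Power figures quoted anywhere in this repository are therefore
  conditional on the generator defaults stated above.
* The congruence estimate from a posteriori tests is a mean rank correlation;
  for independent tree-distance matrices its null spread is far wider than
  for i.i.d. vectors (tree structure is low-dimensional), so moderate
  positive values alone do not imply congruence — the permutation p-value is
  the calibrated quantity.

## Numerical choices

Symmetry tolerance on input matrices 10⁻⁹ (then symmetrized exactly);
W clipped to [0, 1] only against floating noise (|overshoot| < 10⁻¹²,
anything larger raises); χ²-tie comparison uses a relative 10⁻¹² guard for
the different summation orders of observed and permuted statistics; NJ
Q-ties break to the lowest-index pair; Newick output is canonicalized
(children sorted by smallest descendant label, traversal rooted at the
neighbor of the smallest leaf) so equal trees serialize identically.
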