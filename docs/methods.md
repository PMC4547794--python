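# Methods

This note documents the models and procedures implemented in phylogeokit,
the conventions and defaults chosen where the methodology is genuinely
open, and what the synthetic-data tests do and do not demonstrate.

## Dispersal parsimony

The dispersal length *L* of a population labeling on a fixed tree is the
minimum, over all assignments of populations to internal nodes, of the
summed dispersal cost over edges. It is computed by the Sankoff dynamic
program: for node *v* and state *s*,

    S_v(s) = Σ_{c ∈ children(v)} min_t [ cost(s, t) + S_c(t) ],

with tips pinned to their observed population and *L* = min_s S_root(s).
This is mathematically identical to scoring the labeling as a single
multistate character under a step matrix in a parsimony program, but has no
ceiling on the number of populations and handles polytomies directly (the
sum runs over all children; no resolution is imposed). Branch lengths are
ignored. Only the optimal cost is reported — ties among optimal internal
reconstructions are common and no single reconstruction is privileged.

Properties relied on (and tested): with symmetric costs *L* is a property
of the unrooted tree, so rerooting never changes it; under a unit-cost
island matrix *L* equals the Fitch parsimony count; scaling all costs by
*c* scales *L* by *c*; *L* = 0 exactly when one population labels every
tip (for island and stepping-stone matrices).

### Cost-matrix builders

* **island** — cost 1 between any two distinct populations.
* **two_group** — cost 1 only across a two-set partition of populations
  (e.g. a trans-ocean crossing), 0 within.
* **stepping_stone** — populations ordered along a geographic chain; an
  adjacent step costs 1 and non-adjacent moves cost the number of
  intervening steps (|i − j| after collapsing zero-cost merges). The
  additivity convention follows step-matrix semantics: a long-range event
  is equivalent to a chain of single steps. Zero-cost merges are allowed
  only between chain-adjacent populations and collapse them into one
  effective deme.

All matrices must be symmetric with a zero diagonal. The triangle
inequality is *not* required (the DP stays valid) but a violation draws a
warning since it usually signals a mis-specified model.

## Monte Carlo randomization test

Null hypothesis: population labels are exchangeable across tips. Holding
the topology and the cost matrix fixed, the test draws label permutations
that preserve the observed per-population counts — every distinct
assignment of the label multiset is equally probable — scores each with
the batch Sankoff kernel, and reports:

* the replicate histogram of *L*, its min / mode / max (the smallest class
  is reported for a tied mode; the histogram retains the full information);
* the frequency of the observed class and the **inclusive lower tail**
  (fraction of replicates with L ≤ observed), which is the significance
  measure: structure is declared at the 5% level when the inclusive tail
  is ≤ 0.05;
* the raw tail frequency is reported as-is; the conservative estimate
  (r + 1)/(n + 1) is also included in the result record.

A single seeded generator drives all replicates and the seed is stored in
the result, so runs are exactly reproducible. Correctness is tested
against exhaustive enumeration on a 6-tip two-population case where all 20
distinct labelings can be scored directly.

## Cumulative mismatch curves and the K-S comparison

For a group of *g* individuals the curve maps a difference count *x* to
the fraction of the g(g−1)/2 within-group pairs differing by ≤ *x* sites.
Pooled groups are recomputed over the union of members, so between-sample
pairs contribute — a pooled curve is not an average of component curves.

The two-sample statistic D = max |F₁ − F₂| is evaluated exactly over the
union of both curves' step points (right-continuous step functions), never
on a grid. Critical values use the Smirnov asymptotic form

    D_a = c(α) · √((m₁ + m₂)/(m₁ m₂)),   c(α) = √(−ln(α/2)/2),

(c(0.05) ≈ 1.3581). Because the pairs within a group are built from only
*g* individuals they are not independent, so the effective sizes m are
computed under four criteria, all reported side by side rather than
privileging one: `pairs` (m = g(g−1)/2; anticonservative by construction),
`individuals` (m = g), `cross` (one pooled m = (n−1)(n′−1)/2 used for both
samples — how this criterion should split per-sample sizes is unstated in
the methodology it follows, so a single pooled m is used and documented),
and `pairs_adjusted` (m = (g−1)(g−2)/2). Simulation tests confirm the
`individuals` criterion holds its nominal type-I error on panmictic data
(it is in fact conservative); the `pairs` criterion is documented as
anticonservative and not asserted.

## Distance AMOVA

Pairwise nucleotide difference counts enter as squared Euclidean distances
(the haplotypic-distance convention). Sums of squares:

    SSD(total) = Σ_{i<j} d²_ij / N,
    SSD(within pops) = Σ_p Σ_{i<j∈p} d²_ij / n_p,

and analogously within groups; SSD is additive across strata. Variance
components come from the standard nested ANOVA expectations with unequal
sizes (coefficients n, n′, n″), giving φ_ST = (σ²_a+σ²_b)/σ²_tot,
φ_SC = σ²_b/(σ²_b+σ²_c), φ_CT = σ²_a/σ²_tot. Permutation schemes:
individuals among populations (φ_ST), individuals among populations within
groups (φ_SC), whole populations among groups (φ_CT); one-tailed
p = #(permuted ≥ observed)/n_perms with 10,000 permutations by default.
With few populations the φ_CT permutation space is tiny, so its p-values
are coarse — an inherent property of the design, not an implementation
artifact.

The degenerate haplotype-frequency case (every individual unique) is
provided as an explicit mode that reports F_ST = 1, F_SC = F_CT = 0
exactly; it exists to document why distance-based φ statistics are the
informative choice for fully resolved mitogenome data.

## Mismatch statistics

Tajima's D uses the 1989 variance constants (a₁, a₂, b₁, b₂, c₁, c₂, e₁,
e₂ from n); S = 0 is an explicit error, not zero. Fu & Li's D uses total
mutations and external-branch (outgroup-polarized singleton) mutations
with the 1993 constants; D* (no outgroup) uses minor-allele singletons
with the corrected constants. Singleton counting, like all site-level
computations, uses unambiguous A/C/G/T characters only.

### Sudden-expansion model

A pair of lineages in a population that grew from θ₀ to θ₁ at time τ in
the past (time in units of pairwise differences, τ = 2ut) either coalesces
in the current epoch — exponential with rate 1/θ₁ per unit τ, mutations
Poisson of the coalescence time — or survives to the old epoch with
probability exp(−τ/θ₁) and adds a geometric(θ₀) tail. Integrating gives
the exact expected mismatch probabilities

    F_i = Φ_i(θ₁)·P[Pois(λτ) > i] + e^{−τ/θ₁} Σ_{j≤i} Pois_j(τ)·Φ_{i−j}(θ₀),

with λ = (θ₁+1)/θ₁ and Φ_i(θ) = θ^i/(θ+1)^{i+1} the equilibrium
distribution. The limits check out analytically: τ = 0 gives Φ(θ₀), τ → ∞
gives Φ(θ₁), θ₁ → ∞ gives the classical Poisson-peak expansion curve.
This closed form is implemented directly (with the Poisson survival
function for numerical stability) rather than transcribed from secondary
sources.

Fitting minimizes the sum of squared deviations between observed relative
frequencies and F_i over (τ, θ₀, θ₁ ≥ θ₀), using a fixed multi-start grid
(τ anchored at the observed mean and fractions of it) feeding a
Nelder-Mead local search with θ₁ parametrized as θ₀ + e^δ to enforce the
expansion constraint. The procedure is deterministic; on histograms
generated exactly from the model it recovers τ to well within 1%. The τ
estimator is thus *defined* as the least-squares fit; "inflection-point"
style estimators used by some programs are not implemented. Conversion of
τ to an age is delegated to the clock module with the convention (d = τ or
d = τ/2) as an explicit user parameter, because the conversion is not
standardized.

## Power-curve clock

T = a·d^b is fitted by OLS of ln T on ln d ("power curve fit" does not fix
a fitting method; log-log OLS corresponds to multiplicative error, which
is the natural error model when r² is quoted for a power law). a = exp of
the intercept, b = the slope, r² from the same regression. Scale
covariance (T → cT gives a → ca, b and r² unchanged) and exact two-point
recovery are tested. Node dating evaluates the fitted curve at supplied
per-node distances — distances come from an upstream clock-constrained or
linearized tree and are *inputs*; dating checks monotonicity (child age ≤
parent age) when a labeled tree is supplied and warns on violations.
Calibration data (e.g. hominine mitogenome divergences) are supplied by
the user as (d, T, label) rows; none are bundled.

## Synthetic fixtures and what the tests show

* **Frozen toy trees (models A–E)** — balanced 16-tip binary trees over
  four areas spanning maximal structure (four monophyletic area clades,
  L = 3) to no clade-area correspondence (every cherry mixed, L = 12),
  with intermediate forms (L = 9, 7, 6). Model D realizes "minimal
  exchange" between the green and blue areas by placing a single blue tip
  inside the green clade (area counts 4/4/3/5); the other models have four
  tips per area. The Newick strings are frozen constants and byte-stable.
* **Clade trees + label swaps** — a perfect clade-per-population labeling
  whose dispersal length is k − 1 under island costs, perturbed by a
  tunable number of random label transpositions; used to verify that the
  randomization test's tail behaves monotonically in structure strength.
* **Jukes–Cantor simulator** — root sequence uniform over A/C/G/T;
  mutations placed as a Poisson process (rate = branch length × sites)
  with uniform choice among the three alternative bases. Mean pairwise
  differences follow the JC saturation curve L·(3/4)(1−e^{−4d/3}), which
  the tests verify within Monte Carlo error.
* **Coalescent fixtures** — neutral constant-size and growth scenarios are
  simulated with msprime in the test suite (haploid samples of n = 12–25,
  θ ≈ 8–20, 150–500 replicates), sizes chosen to mirror the tens-of-
  genomes scale the methods target while keeping the suite fast.

Passing these tests demonstrates correctness of the algorithms and their
calibration on data generated under the stated models. It does not
demonstrate robustness to features of real mitogenome data that the
generators omit: recombination-free but selection-affected loci, sequencing
error, alignment artifacts, or non-neutral demography beyond the sudden
expansion. The K-S criteria in particular inherit the non-independence of
within-group pairs; the package surfaces this rather than resolving it.

## Numerical conventions and degenerate inputs

* Pairwise deletion for ambiguity/gap characters: a site is skipped for a
  pair when either member is not an unambiguous A/C/G/T. Adding ambiguity
  can therefore only decrease a pair's count (tested as a property).
* Parsimony-informative site: ≥ 2 unambiguous states each carried by ≥ 2
  sequences.
* Ties: the randomization histogram reports the smallest tied mode; K-S
  reports every difference value attaining D.
* Degenerate inputs raise explicit errors rather than returning sentinel
  values: S = 0 for the neutrality tests, singleton groups for curves and
  mismatch histograms, empty histograms for the expansion fit, < 2 distinct
  distances for the clock.
* Unrooted input trees are accepted as trees with a multifurcating root;
  all engines score polytomies directly.

## Known limitations

* Dispersal costs must be symmetric; directional (asymmetric) dispersal is
  out of scope.
* The randomization test compares observed structure to a model-specific
  null; it does not rank competing biogeographic models against each other
  (their tails are reported side by side, but differences between tails
  are not themselves tested).
* K-S significance identifies the single maximum offset; ranges of the
  difference axis over which curves differ are not assessed.
* The AMOVA is single-locus; no multi-locus or likelihood-based
  demographic machinery is included.
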