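# Methods

## Problem and model

`hogimine` screens for *meta-markers*: OR-aggregations of binarized genetic
markers whose presence/absence is statistically associated with a binary
phenotype. The motivating phenomenon is genetic heterogeneity — distinct
loci with the same phenotypic effect — under which individual markers carry
too little signal but their aggregation does not.

A candidate meta-marker (a *pattern*) is constrained by two priors:

1. **Locality.** Markers are grouped into genes; within a gene only
   contiguous genomic intervals are aggregated (nearby variants are more
   likely to share an effect, e.g. through linkage disequilibrium).
2. **Interaction priors.** A pattern spans one interval per gene of a
   *gene interaction* — a gene set supplied by the user, typically
   connected subgraphs of a protein–protein interaction network up to a
   chosen size k, or small protein complexes.

For additive genotypes (0/1/2 minor-allele counts) each gene interval in a
pattern additionally carries an encoding: **dominant** (bit = 1 iff value
≥ 1) or **recessive** (bit = 1 iff value = 2). All markers in one interval
share one encoding, which bounds the encoding blow-up at 2^k per
interaction. For an interaction with gene sizes l_1..l_k the pattern class
has exactly ∏ l_i(l_i+1)/2 interval choices, times 2^k encodings in
additive mode.

The recessive bit is defined as "homozygous for the minor allele". This is
the standard genetics convention; it also makes every recessive support a
subset of the corresponding dominant support, which is what gives the
pattern class its partial order (descendants have superset supports) and
thereby makes pruning sound.

## Test statistic

Association is assessed with the Cochran–Mantel–Haenszel chi-square (1 df)
over C covariate strata. With stratum sizes n_j, case counts n1_j, pattern
carriers x_j and carrier-cases a_j:

    T = [ Σ_j (a_j − x_j n1_j / n_j) ]² /
        Σ_j x_j (n_j − x_j) n1_j (n_j − n1_j) / (n_j² (n_j − 1))

p = Pr[χ²₁ ≥ T], computed as erfc(√(T/2)). No continuity correction is
applied (the convention of the discrete-testability literature: the
corrected statistic would break the corner/envelope algebra below).
Degenerate strata contribute nothing; a fully degenerate table yields
T = 0, p = 1. With one stratum T reduces to ((n−1)/n) · Pearson χ².

## Multiple testing

Both correction methods maintain a threshold δ on a geometric grid
δ_i = α·γ^i (default γ = 0.9; smaller γ trades runtime for a slightly
tighter final threshold — the grid is a implementation constant, results
can differ between grids at grid-resolution level).

**Tarone.** Because T depends on the a_j only through Σ_j a_j, the
smallest p attainable under fixed margins is reached at one of two corner
totals (all a_j at their upper, or all at their lower, bounds). Patterns
with minimum attainable p-value above δ can never be significant and are
excluded from the correction; δ is the largest grid value with
δ · |{testable at δ}| ≤ α. Identical patterns arising from overlapping
interactions are counted once (canonical key), since they are literally
the same hypothesis.

**Westfall–Young.** K label permutations (default 10⁴, configurable) are
drawn *within* each covariate stratum, so all margins — and hence every
pattern's minimum attainable p-value and envelope — are identical across
permutations. One pruning decision is therefore valid simultaneously for
the observed labels and all K permutations. The FWER estimate at δ is the
fraction of permutations whose running minimum p-value (over processed
patterns) is ≤ δ; δ descends the grid until the estimate is ≤ α.
Permutation p-values need only the permuted case total, a popcount of the
support against each permutation's combined case mask, vectorised over K.
Patterns that are untestable at the current δ are skipped in the
permutation update: their permutation p-values all exceed δ and can never
contribute a minimum at or below any future (smaller) threshold.

## Search and pruning

Patterns are enumerated per interaction, breadth-first in total interval
length. Level k holds all single-marker-per-gene patterns; a child extends
exactly one gene's interval one position rightward, and gene i may be
extended only while all lower-indexed genes still have length-1 intervals.
This canonical rule generates each pattern exactly once, so child supports
are a single bitwise OR away from their unique parent and no cross-level
deduplication is needed.

The **envelope** of a pattern is a lower bound on the minimum attainable
p-value over every descendant, i.e. over the box {x′ : x_j ≤ x′_j ≤ n_j}
of superset supports. If the envelope exceeds the current δ the whole
subtree is pruned; monotonicity of the envelope along descent plus the
monotone decrease of δ make this permanently safe. The default computation
maximises the two corner statistics over the per-stratum candidate grid
{x_j, n1_j, n_j − n1_j, n_j} (clamped to [x_j, n_j]). This is exact: on
each linear piece of the clamped numerator the corner statistic is a ratio
of a convex quadratic to a positive concave quadratic, hence quasiconvex
coordinate-wise, so the box maximum sits on the grid of piece endpoints.
A strictly weaker but separable Cauchy–Schwarz bound
(Σu)²/(Σv) ≤ Σ u_j²/v_j is available via `envelope_method="separable"`.
Both variants are validated in the test suite against exhaustive
enumeration of the full descendant box.

Only **closed** patterns are reported: a significant pattern is dropped if
removing one marker from either end of any of its intervals leaves the
support unchanged. Closedness is checked within a pattern's own class
(interval shrinks with the same genes and encodings); gene-dropping or
encoding-flipping sub-patterns belong to other interactions' classes and
are corrected there.

Supports are packed bit vectors (sample i = bit i), stored as
arbitrary-precision integers whose machine-word representation gives
union, intersection and popcount at word granularity; the canonical
64-bit-word view is exposed for interoperability.

## Synthetic data

The generator reproduces the power-study design: an Erdős–Rényi G(n, m)
gene network (default 75 genes, 100 edges), per-gene SNP counts uniform on
[3, 10], i.i.d. genotypes with per-marker MAF uniform on [0.1, 0.4]
(Bernoulli(maf) in binary mode, Binomial(2, maf) in additive mode), and a
planted connected subgraph of k* genes with one short random interval per
gene (lengths uniform on [1, 3], grown by uniform BFS — both constants are
this package's documented choices) whose OR-aggregate z is the causal
signal.

Labels follow a symmetric shift model: carriers of the planted meta-marker
are cases with probability 0.5 + ρ/2, non-carriers with 0.5 − ρ/2. An
alternative that pins the overall prevalence at exactly 0.5 by solving for
the non-carrier rate q was considered and rejected: with the default MAF
range and planted design the meta-marker often covers the large majority
of samples, driving q below 0 for ρ ≳ 0.25 and making much of the
interesting ρ range infeasible. The symmetric model is feasible for every
ρ < 1, exactly null at ρ = 0, and monotone in ρ; its overall prevalence
drifts above 0.5 as ρ grows when carriers are common, which the CMH test
conditions away.

The covariate is uniform over C classes (default 2) and independent of
genotypes and labels; a `confounded` option shifts both the label odds and
one marker's frequency per class for demonstrating the stratified test.
What the generator deliberately omits: linkage disequilibrium, population
structure/kinship, genotyping error, and quantitative phenotypes. Passing
tests on these data show correctness of the machinery and qualitative
power behaviour, not calibrated performance on real cohorts.

A *true positive* is counted as a reported significant pattern whose
marker set overlaps the planted marker set (exact-match counting would
under-credit discoveries that straddle the planted interval).

## Problem sizes in the shipped studies

The test suite and `scripts/acceptance.py` run the simulation studies at
desk scale, as this package's own study design: null-FWER calibration on
20 genes / 30 edges / 300 samples with interactions up to k = 2 over
150–200 replicates (Westfall–Young with K = 100); power and encoding
trends on 30 genes / 35 edges / 1000 samples with 3–6 SNPs per gene,
interval cap l′ = 3, ρ ∈ {0, 0.1, 0.2, 0.3}, 30–50 replicates. Exhaustive
cross-checks (miner vs. brute-force enumeration, envelope vs. full
descendant box) use instances small enough for the oracles to enumerate
completely.

## Numerical and design notes

* p-values are computed through erfc; values below ~1e-300 underflow to 0,
  in which case the Westfall–Young grid descent stops at a hard floor
  (only reachable if a super-majority of permutations attain underflowing
  minima, which does not occur at the shipped sample sizes).
* Ties in the output ordering are broken by the canonical pattern key
  (genes, intervals, encodings), making every output file deterministic.
* Interactions are mined exactly as given; sub-interactions are not added
  automatically (feed singletons/edges/triangles explicitly if wanted).
* Covariate classes are re-indexed densely on read; a missing covariate
  file means a single stratum, i.e. the plain (uncorrected-for-structure)
  CMH/χ² screen.
* Missing genotypes are rejected rather than imputed; imputation is
  treated as preprocessing.

## Known limitations

* One encoding per interval (not per marker) — the per-marker
  generalisation explodes the hypothesis count and with it both runtime
  and the correction burden.
* FWER control only; no FDR mode.
* The testable-pattern ledger deduplicates identical hypotheses across
  overlapping interactions; an implementation that counts them multiply
  would also control FWER, slightly more conservatively.
* Interactions much larger than k ≈ 5 are impractical (pattern count grows
  as ∏ l_i(l_i+1)/2 · 2^k); the interval-length cap l′ mitigates but does
  not remove this.
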