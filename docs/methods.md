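# Methods

This document records the models implemented in `mscbench`, the numerical
conventions chosen, and the scope of what the package does and does not do.

## Scope

`mscbench` is a simulation and evaluation toolkit. It generates fully
synthetic data (species trees, gene trees, alignments), evaluates externally
produced posterior samples against the simulated truth, and analyses how
accuracy and sampling efficiency scale with the amount of data. It does not
run Bayesian inference itself: posterior tree logs and traces are inputs,
and for end-to-end testing a *surrogate* pseudo-posterior stands in for an
external sampler. All problem sizes used in tests and examples (5–13
species, 1–8 individuals, 2–256 loci) are the package's own choices for
desk-scale experimentation.

## Species tree simulation (`species_sim`)

**Yule trees.** A pure-birth tree conditioned on `n` extant tips is built
backward in time: while `j` lineages remain, the waiting time to the next
join is Exponential(`j·λ`) and the joined pair is chosen uniformly. This
yields the standard conditioned-Yule distribution with expected root height
`(H_n − 1)/λ` (H_n the n-th harmonic number) and expected mean branch length
`1/(2λ)`. `calibrated_birth_rate(R, n)` inverts the root-height expectation,
returning `λ = (H_n − 1)/R`.

**Birth–death trees.** Simulated forward with constant birth and death
rates; a replicate is accepted the first time the extant lineage count
dwells at exactly `n` when the simulation stops, extinct lineages are
pruned, and unifurcations are suppressed. Rejection is capped at 10⁶
attempts.

**Population sizes.** Each branch (including the root branch) carries an
effective population size `Ne`, either constant or drawn i.i.d. from a gamma
distribution parameterized by shape and mean.

**Coalescent units.** A branch of duration τ with population size Ne has
length `τ/(2Ne)` coalescent units. The closed-form calculator
`expected_mean_branch_length(R, n, invNe)` returns
`(1/4)·R/(H_n − 1)·invNe`, where `invNe` is the **mean reciprocal**
population size E[1/Ne] — the quantity that enters linearly when Ne varies
across branches.

## Gene tree simulation (`gene_sim`)

Gene trees are drawn under the multispecies coalescent: within a species
branch of population size Ne, each pair of gene lineages coalesces at rate
`1/(2Ne)` (equivalently, with `j` lineages the next event is
Exponential(`j(j−1)/2 · 1/(2Ne)`)); lineages not yet coalesced at the top of
a branch are passed to the parent branch, and the root branch extends to
infinity. Gene copies are labelled `<species>_<index>`.

**Deep coalescences** follow the standard parsimony-style cost: for every
non-root species branch, the number of gene lineages exiting rootward minus
one, summed over branches. A coalescence occurring exactly at a divergence
time counts as having happened below it (the merged lineage exits).

**Seeding.** Locus streams derive from `SeedSequence((seed, *path))`, so any
replicate or locus is regenerable in isolation and a larger locus set is a
prefix-extension of a smaller one at the same seed.

## Sequence simulation (`seq_sim`)

Nucleotide models JC, HKY and GTR are parameterized by exchangeabilities and
stationary frequencies; the rate matrix is normalized so the expected
substitution rate at stationarity is 1, and branch transition matrices are
matrix exponentials `expm(Q·t·μ)` with clock rate μ. Rate heterogeneity uses
the discrete-gamma approximation with four categories whose rates are the
category means of the gamma distribution (computed from regularized
incomplete gamma functions). Per-locus clock rates may be fixed, drawn
log-uniformly (with the first locus pinned to the base rate), or drawn from
a gamma distribution.

## Accuracy metrics (`metrics`)

**Rooted branch score (RBS).** For each tree, every node except the root
maps its clade (set of descendant leaf labels, tip singletons included) to
its rootward branch length; duplicate clades sum. The RBS is
`Σ_c |b₁(c) − b₂(c)|` over the union of clades, with absent clades
contributing length 0. **Relative error** is the mean RBS between the true
tree and each posterior sample, divided by the true tree's total branch
length; it is invariant to joint rescaling. **Error ratio** divides two
relative errors. **Rooted RF** is the size of the symmetric difference of
the two internal-clade sets. **Pendant-edge bias** is the mean over tips of
`100·(estimated/true − 1)` for pendant branch lengths.

**Aggregation.** Condition summaries use the 25% trimmed mean with a
percentile bootstrap confidence interval (clamped to bracket the point
estimate).

## Tree and alignment statistics (`treestats`)

Asymmetry is the population variance of tip edge-depths (topology-only).
Mutation counts use Fitch small parsimony, vectorized with 4-bit state masks
and generalized to multifurcations. Residual correlations are Spearman's ρ
(rank-then-Pearson) with Benjamini–Hochberg adjustment scaled to an external
family size (default 48 tests), so adjusted p-values are comparable across
sub-tables.

## Scaling analysis (`scaling`)

**ESS.** The autocorrelation function is computed by FFT; the integrated
autocorrelation time truncates the sum at the first negative *pair* of
consecutive autocorrelations (initial-positive-sequence rule), with maximum
lag N/3; ESS = min(N, N/τ). Note the truncation rule sees only short-lag
structure: a strictly periodic concatenation of an i.i.d. block is not
detected (nor is it by standard MCMC diagnostics), whereas contiguous
duplication of draws is.

**Regression.** `fit_loglog` fits `ln Y ~ ln nl + n + ni + 1` by OLS and
reports coefficient standard errors; rank-deficient designs (e.g. constant
`n` and `ni`) raise rather than silently pseudo-inverting. All power-law
arithmetic uses **natural logarithms**: prediction is
`exp(intercept + slope·ln nl)`, extrapolation multiplies by
`(nl₁/nl₀)^slope`, workload is `target ESS / ESS rate`, and the error
reduction for a fold-increase `f` at slope `s < 0` is `100·(1 − f^s)`.

**Crossover.** `find_crossover` smooths log(error ratio) against log(branch
length) with a degree-1 tricube local regression (validated against
statsmodels lowess), evaluates it on a 201-point grid, and refines the zero
crossing by bisection; it returns `None` when the smoothed curve never
crosses unity and requires at least 20 points.

## Pipeline (`pipeline`)

`ExperimentConfig` presets define three experiment families: a factorial
accuracy/performance sweep (`exp1`), a calibrated-Yule comparison design
with shared species trees across locus counts (`exp2`), and shallow/deep
empirical-style parameterizations (`exp3`) including gamma-distributed
per-branch Ne, per-locus clock rates, and (for the deep setting) variable
locus lengths. `generate` is fully deterministic given (config, seed);
`export_bundle` writes Newick/NEXUS/FASTA plus a JSON manifest with the
config hash. `filter_replicates` discards replicates whose posterior or
species-tree-height ESS falls below a threshold (default 200), reporting
reasons.

**Surrogate estimator.** `surrogate_estimate` perturbs the true species
tree: internal node-height gaps receive lognormal jitter with scale
`noise/√nl` and topology is disturbed by height-respecting nearest-neighbor
interchanges with probability `min(1, noise/nl)`, so error declines with the
locus count approximately as a power law — the qualitative behaviour the
evaluation stack must detect. `paired_surrogate_estimates` additionally
scales the "coalescent-like" member's noise by `√(b/crossover)` with `b` the
tree's mean branch length in coalescent units, so the pair's error ratio
crosses 1 near a constructed branch length. Both are synthetic devices for
exercising the pipeline; they make no inferential claims.

## Limitations

- No inference: results about estimator accuracy obtained with the
  surrogate characterize the evaluation pipeline, not any real sampler.
- The MSC simulator assumes one haploid sample per individual label, no
  migration, no recombination within loci, and free recombination between
  loci.
- Sequence simulation is strict-clock within a locus; no indels, no
  among-site model mixtures beyond discrete gamma.
- The birth–death simulator conditions on tip count by rejection, which
  becomes slow for high extinction fractions.
- ESS estimation shares the blind spots of truncation-based estimators
  (see above).
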