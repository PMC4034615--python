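# Methods

## The model

Counts `y_oijk` (OTU `o`, condition cell `i`, group `j`, sample `k`) follow
a Poisson-lognormal distribution `PLN(λ, σ²_o)`: conditional on a latent
Gaussian disturbance `ε ~ N(0, σ²_o)` on the log scale, the count is
Poisson with rate `exp(ψ + ε)`, `ψ = log λ`. Under this parameterization
`E[y] = λ·exp(σ²_o/2)`; we treat `λ` as the rate parameter of the latent
Poisson, not the marginal mean (the alternative reading of "rate
parameter"), and the residual log-variance is OTU-specific. The log-rate
decomposes additively into an OTU intercept `I_o`, OTU-by-condition fixed
effects `B_oi`, a per-sample coverage effect `c_k ~ N(0, v_c)` shared by
all OTUs, and optional OTU-by-group random effects `a_oj` with OTU-specific
variances. Technical replicates are assumed absent, so no separate
OTU-by-sample error term is carried: that variance is absorbed into
`σ²_o`.

The **sum-OTU** is an artificial unit whose count in each sample equals the
sample total. It is modeled jointly with its own intercept, fixed effects
and group effects, sharing only `c_k`. Reporting every OTU's effects as
`B_oi − B_i^s` nets out any systematic coverage bias that tracks the
experimental conditions, and makes `exp` of the relative intercept-plus-
effect the OTU's model-scale proportion of total counts. Because the
dominant OTU carries most of the total, the sum-OTU behaves almost like the
dominant OTU; condition effects on minor OTUs barely move the total, so
relative contrasts estimate the planted per-OTU effects.

Condition cells are the full cross of the declared fixed factors
(cell-means layout, equivalent to main effects plus all interactions),
reference-cell coded against the alphabetically first cell. Continuous
covariates and across-OTU residual covariance are out of scope.

## Priors

* Fixed effects and intercepts: `Normal(0, 1e8)` (effectively flat).
* Coverage and group variances: 1×1 inverse-Wishart ≡ scaled
  inverse-chi-square with `V = 1, ν = 0`. `ν = 0` is improper, so `ν` is
  clamped to 0.002 by default (configurable); posterior summaries are
  insensitive to the clamp at the data sizes exercised here.
* Residual log-variances: `V = 1, ν = U − 0.998` with `U` the number of
  units including the sum-OTU — weakly informative, which stabilizes
  chains for sparse OTUs.

## Sampler

Metropolis-within-Gibbs on the latent-log-rate representation
`η_n = ψ_n + ε_n` per observation:

1. `η` update: vectorized random-walk Metropolis, one independent proposal
   per observation (valid because the `η_n` are conditionally
   independent). A per-unit proposal scale is adapted toward 44%
   acceptance during burn-in only, so detailed balance holds for retained
   draws.
2. Location effects (`I, B, c, a` jointly): given `η`, the model is a
   Gaussian regression `η ~ N(Xβ, diag σ²_o)` with Gaussian priors, so `β`
   is drawn exactly from its multivariate-normal full conditional via a
   Cholesky solve. Per-unit Gram matrices are precomputed, making each
   sweep O(U·P²) rather than O(N·P²).
3. `c_k` are recentred to mean zero each sweep, with the shift absorbed
   into all unit intercepts (a pure reparameterization of `ψ`) — this pins
   the intercept/coverage ridge.
4. Variances: conjugate scaled-inverse-chi-square draws.

Defaults are 55,000 iterations, 5,000 burn-in, thinning 50 (1,000 retained
draws). The test-suite and acceptance runs use 6,000/1,000/5 — also 1,000
retained draws — which on the 58-sample reference dataset keeps every
fixed-effect effective sample size in the hundreds and one fit around two
seconds; this problem size is the package's own choice of test scale.
Chains are bit-reproducible given the seed. A fixed-effect ESS below 100
triggers a warning, never an error.

Because each unit carries its own latent residuals, an OTU and the sum-OTU
fitted to identical data (the single-OTU degenerate case) agree in
distribution but not draw-by-draw; relative effects vanish in posterior
mean within Monte-Carlo error. Similarly, multiplying one sample's counts
by a constant shifts that sample's `c_k` by approximately the log factor,
attenuated (~15% at the reference size) by the Gaussian shrinkage on
`c_k`; relative contrasts are unaffected, which is the property that
matters.

## Inference outputs

For every OTU and unordered pair of condition cells: the per-draw
difference of relative effects, its posterior mean, a 95% highest-density
interval (equal-tail optional), the two-sided MCMC p-value
`2·min(#{d>0}+1, #{d<0}+1)/(N+1)` (the `+1` correction keeps p > 0 on a
finite chain), and Benjamini–Hochberg q-values computed over the entire
table — all OTUs and all pairs as one family, the most conservative
reasonable scope. Proportion summaries exponentiate the relative log
abundance per draw; they are deliberately *not* renormalized across
retained OTUs, since the sum-OTU reference already defines share-of-total.

## Screening

1. **Outlier samples**: natural-log sample totals at or below
   `mean − 2.5·SD` (one-sided low; two-sided optional). Any log base gives
   identical z-scores. Note that with very few samples a single extreme
   value inflates the SD enough that it cannot reach −2.5 SD; the rule is
   meant for surveys with tens of samples.
2. **Quantifiable OTUs**: global share ≥ 0.1% of the grand total
   (inclusive), the practical detection limit for low-frequency amplicon
   haplotypes. Raising the threshold never grows the kept set.
3. **Unreliable OTUs (post-fit)**: any intercept or fixed-effect chain
   with lag-10 autocorrelation above 0.1 on the thinned draws flags the
   OTU for exclusion from contrast reporting; both lag and threshold are
   configurable, and chains shorter than 10× the lag are an error. The
   typical trigger is an OTU present in too few samples for its
   parameters to be identified.

## Transforms, PCA, paralog screen

Size factor for sample `k` is `mean(totals)/total_k`, so scaled totals all
equal the grand mean exactly. (Read literally, the source convention
"sample/mean" would amplify deep samples; the equalizing direction is the
default and the literal one sits behind `literal=True`.) The started-log
transform is `log10` of the normalized count with zeros replaced by 0.1
(so zero maps to −1); the log-linear hybrid is `log10(x)` above a knot `c`
and its tangent line below, continuous and once-differentiable at `c`,
with `c = 1` so only sub-single-count values fall on the linear branch.
The two transforms correlate > 0.99 on the data sizes used here.

PCA retains OTUs detected (raw count > 0) in strictly more than 10% of
samples, applies the started log, centers, and by default scales columns
to unit variance so Kaiser's criterion (component SD > 1, i.e. above the
average) is scale-free; covariance-matrix PCA is available via
`scale=False`.

Paralog screening correlates log abundances over samples where *both* OTUs
are nonzero (original zeros left undefined), Pearson by default, two-sided
p from the t distribution; pairs with fewer than 3 co-present samples are
not assessable. Significant positive correlation marks a candidate paralog
pair (same genome, co-varying copy number); significant negative
correlation supports distinct genomes competing for the same read pool.

## Reads pipeline

Filter (length ≥ 290, and where qualities exist at most 20% of bases below
Q20 — the length bound follows the marker's expected amplicon length; the
quality thresholds are this package's choices), dereplicate, greedy
centroid clustering at 97% identity in abundance order (ties lexicographic,
making the pipeline deterministic and permutation-invariant), and
unambiguous best-hit mapping: a read whose top two identities tie is left
unassigned. Identity is matching columns divided by alignment length
(internal gaps counted) of a global alignment with free end gaps; external
tools differ subtly in this definition, so one definition is fixed here.
No chimera removal or denoising is performed, and demultiplexing is out of
scope (inputs are per-sample files).

## Synthetic generator

`simulate_counts` runs the model forward from recorded truth.
The reference preset emulates a two-species × two-bank coral-symbiont
survey: 58 samples (cells of 15/15/14/14), seven quantifiable haplotypes
with expected shares 90%, 4.5%, 2.2%, 1.2%, 0.8%, 0.5%, 0.3%, ten noise
OTUs at 0.05% each (below the quantifiability threshold, so screening has
real work), coverage variance 0.25 (log-SD 0.5, matching roughly tenfold
depth variation with sums mostly in 250–5,400 around a median near 1,900),
residual log-variances 0.1 (dominant) and 0.35 (minor), and bank effects
of −1.2, +1.0, +1.4 natural-log units planted on three minor haplotypes —
the magnitude needed for minor-OTU detection at these depths. Intercepts
subtract `σ²_o/2` so expected shares equal the nominal ones.

The read simulator plants reference sequences with disjoint mutation
blocks (pairwise divergence ≥ the requested fraction), draws per-sample
multinomial reads, and applies i.i.d. substitution noise; the recorded
expected table is the exact multinomial draw.

What the generator does **not** emulate: PCR chimeras, platform-specific
indel/homopolymer error, taxonomic structure among OTUs, overdispersion
between technical replicates, and correlated residuals across OTUs.
Passing tests therefore demonstrate correctness of the estimator under the
model's own assumptions and robustness to coverage artifacts — not
robustness to chimeric or systematically biased reads.

## Numerical choices and limitations

* `pln_pmf` integrates the latent disturbance by adaptive quadrature over
  ±12 SD anchored at both integrand modes; the σ² = 0 branch returns the
  Poisson pmf exactly.
* MCMC p-values are discrete with floor `2/(N+1)`; with 1,000 retained
  draws the smallest attainable p is ≈ 0.002, which bounds achievable
  q-values in large families.
* Under all-null simulation the unadjusted rejection rate at 0.05 runs
  slightly conservative (~2–4%), as expected for posterior tail
  probabilities with shrinkage.
* The sampler is dense-matrix; it is comfortable to a few hundred OTUs and
  a few hundred samples, matching the method's intended scale, and is not
  meant for thousands of OTUs.
* Single-level fixed factors, zero-total samples, and sum-OTU id
  collisions are rejected with explicit errors.
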