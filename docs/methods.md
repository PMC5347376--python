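# Methods

## The generating model

`pleiosim` simulates the association between a single biallelic SNP and
K correlated phenotypes.  Genotypes `G ∈ {0, 1, 2}` count minor alleles
and follow Hardy–Weinberg equilibrium with probabilities
`{p², 2pq, q²}` (`q` = minor allele frequency, `p = 1 − q`).  Phenotypes
follow the additive model

    Y_ik = f(v_k) · G_i + ε_ik,        ε_i ~ MVN(0, c)

where `v_k ∈ [0, 1)` is the fraction of the variance of trait `k`
explained by the SNP and `c` is the residual correlation matrix (unit
diagonal, positive semi-definite).  With residual variance 1 and
`Var(G) = 2pq`, the per-allele coefficient that delivers exactly `v` is

    f(v) = sqrt( ve / (2pq) ),         ve = v / (1 − v).

`ve` is the variance explained rescaled against the unit residual
variance: for `v = 0.005` (a SNP explaining 0.5% of variance, a typical
strong GWAS signal), `ve = 0.005/0.995 = 0.005025`.  Because `f(v)` is
tiny at realistic effect sizes, `c` is also approximately the observed
phenotypic correlation matrix; the approximation error is `O(f²)` and
invisible at the effect sizes simulated here.

Assumptions worth keeping in mind: a single SNP in linkage equilibrium,
additive allelic effects, complete data, no covariates or population
structure, and homoscedastic Gaussian residuals.  None of these are
limitations of the *tests* (several are rank- or likelihood-based), only
of the generator.

### Indirect (mediated) effects

For a trait pair, `simulate_indirect` builds
`Y₁ = f(v)·G + ε₁`, `Y₂ = g(v′)·Y₁ + ε₂`, where `g(v′)` is the
coefficient under which Y₁ explains `v′` of the variance of Y₂.  We use
the theoretical `Var(Y₁) = 1 + f(v)²·2pq` in `g` rather than the ≈1
approximation; this makes the variance of Y₂ attributable to the SNP
exactly `v·v′` (the product of the path variances), which the test suite
verifies by brute-force regression.  Residuals of the two traits may be
correlated through `residual_corr` (default 0, i.e. all shared signal is
the mediated path).

### Case/control traits

`dichotomize_dataset` applies a liability-threshold model: trait `k`
becomes a case where the simulated liability exceeds the upper
`prev_k` quantile of its *theoretical* marginal (normal with mean
`f(v_k)·2q` and variance `1 + f(v_k)²·2pq`).  Using the theoretical
rather than the empirical quantile keeps the threshold deterministic and
the expected case fraction honest; at the simulated effect sizes the two
choices are numerically indistinguishable.  The marginal is strictly a
three-component normal mixture over genotypes; the normal approximation
errs by `O(f²)`.

## Scenario families

* **S1 (structured)**: canonical effect vectors crossed with
  equicorrelation matrices over r = −0.9 … 0.9 in steps of 0.1.  For two
  traits the vectors are v1 = (0.5%, 0.5%), v2 = (0.5%, 0.1%),
  v3 = (0.5%, 0); for K ≥ 4 (K divisible by 4) ten vectors assign one of
  {0.5%, 0.1%, 0} to each quarter of the traits.  Equicorrelation is
  positive definite iff `1 + (K−1)r > 0`, so e.g. the K = 4 grid is
  truncated at r = −0.3; inadmissible points are dropped, never repaired.
* **S2 (uniform)**: effects uniform on [0, 0.5%]; pairwise correlations
  uniform on (−1, 1), rejection-sampled until positive definite.  The PD
  acceptance rate decays super-exponentially in K (measured ≈ 0.18 at
  K = 4, 0.022 at K = 5, 9×10⁻⁴ at K = 6, < 10⁻⁶ at K = 8), so the
  sampler raises a `SamplingError` once its budget (default 10⁵ tries) is
  exhausted; in practice uniform rejection sampling is usable to K ≈ 6.
* **S3 (reflecting)**: correlations mirror the effect pattern — 0.6 for
  a trait pair with equal effects, 0.2 for unequal nonzero effects, 0.05
  when exactly one is affected.  Pairs where *neither* trait is affected
  have (trivially) equal effects and default to 0.6; this is exposed as
  the `both_zero` parameter since the rule set does not uniquely pin that
  case down.
* **S4a (mixture-informed)**: pairwise correlations drawn i.i.d. from a
  user-supplied univariate Gaussian mixture truncated to (−1, 1) —
  typically fitted to a real cohort's trait correlations — with PD
  rejection as in S2.
* **S4b (real-effect-informed)**: per-SNP, per-trait published
  coefficients are rescaled by `d_i = β*(v_max, q) / max_k |β_ik|`, where
  `β*` is the coefficient explaining the target maximum variance
  (default 0.5%), and converted back to variance fractions via the
  inverse of `f`.  The per-SNP maximum is exactly `v_max`, relative
  coefficient magnitudes and signs are preserved, and the transform is
  idempotent.  At most 20 SNPs per index trait are retained (strongest
  index-trait coefficients first) to avoid over-representing
  heavily-studied phenotypes.  The bundled table
  (`data/toy_betas.tsv`) is **synthetic** — 20 SNPs × 12 metabolic-style
  traits with a block structure chosen for test coverage — and stands in
  for real GWAS downloads, which users must supply themselves.

## The eight association tests

Summary-statistic tests consume per-trait simple-regression results
(logistic for binary traits); Wald p-values use the standard-normal
reference.

* **min-P**: Šidák-corrects the smallest trait p-value,
  `p_adj = 1 − (1 − p_min)^Meff`, with the Nyholt effective number of
  tests `Meff = 1 + (K−1)(1 − Var(λ)/K)` computed from the eigenvalues of
  the *phenotypic* correlation matrix (sample variance, divisor K−1).
* **TATES**: extended Simes over traits,
  `p = min_j Me_K · p_(j) / me_j`, with `me_j` the Nyholt count on the
  p-value correlation submatrix of the j most significant traits.  The
  p-value correlation matrix is estimated by seeded Monte Carlo (10⁴
  MVN(0, c) draws mapped through `2Φ(−|z|)`), cached per correlation
  matrix.  This sidesteps the published polynomial approximation at the
  price of Monte-Carlo noise ~1/√10⁴; consequently TATES (and S_Het,
  below) are permutation-invariant only to within that noise.
* **S_Hom**: `(1ᵀR⁻¹T)² / (1ᵀR⁻¹1)` for the Wald vector T, χ²₁
  reference.  `R` is the null correlation of the Wald statistics, which
  for a single fully-overlapping cohort equals the trait correlation
  matrix — the multi-cohort weighting of the general method cancels and
  is out of scope.  Maximal power for homogeneous effects; opposite
  effects cancel exactly.
* **S_Het**: the S_Hom form restricted to traits with `|T_j| > τ`,
  maximized over τ.  The included set changes only at observed `|T|`
  values, so the grid reduces to the nested top-m subsets by `|T|`;
  m = K reproduces the all-trait statistic, so S_Het ≥ the τ = 0 value
  by construction.  P-values come from a Gamma distribution
  moment-matched to 10⁵ seeded null draws of the same statistic
  (T ~ MVN(0, R)), cached per correlation matrix.  The null sampler
  groups draws by subset identity so each distinct submatrix is solved
  once; cost grows with the number of distinct subsets and is intended
  for K ≲ 12.
* **MANOVA**: Wilks' Λ from the multivariate regression of Y on G; with
  one predictor `F = (1−Λ)/Λ · (n−K−1)/K` is exact on (K, n−K−1) df.
* **CCA**: first canonical correlation between {G} and the trait set,
  `ρ² = S_gy' S_yy⁻¹ S_gy / S_gg`, tested by the same exact F.  MANOVA
  and CCA are the same test in exact arithmetic (`Λ = 1 − ρ²`); they are
  deliberately implemented through different numerical routes
  (determinants vs. a positive-definite solve) and their agreement to
  10⁻¹⁰ is asserted in the suite as an implementation cross-check.
* **Combined-PC**: PCA on the standardized traits, each PC regressed on
  G, the K squared Wald statistics summed, χ²_K reference (PCs are
  orthogonal, so the component tests are independent).
* **MultiPhen**: proportional-odds ordinal regression of G on all K
  phenotypes jointly (reversed regression), likelihood-ratio tested
  against the intercept-only model, χ²_K reference.  The MLE is found by
  BFGS on the analytic negative log-likelihood/gradient, started at the
  null optimum (cutpoints = logits of the cumulative genotype
  frequencies); non-monotone cutpoints are rejected by the line search.
  Convergence failure raises `ConvergenceError` with iteration
  diagnostics — no fallback model is silently substituted.  The
  implementation is cross-checked against `statsmodels`' `OrderedModel`
  in the test suite; the in-package solver exists because the engine
  fits this model tens of thousands of times per run.

All eight tests accept case/control (0/1) traits: binary traits enter
the summary tests through logistic Wald statistics and the
individual-level tests as 0/1 values; the reversed-regression tests are
agnostic to the predictor scale.  The exact-F calibration of MANOVA/CCA
formally assumes Gaussian traits and is only asymptotic for binary ones.

## Replicate engine and uncertainty

`run_replicates` simulates R cohorts per scenario point (replicate r
uses seed `base_seed + r`, so results are reproducible and
order-insensitive, and points share common random numbers), applies the
selected tests, and reports the proportion significant with a Wilson 95%
interval.  Method failures are counted and excluded from the denominator
— the counts travel with the result and are logged, never silently
dropped.  Quantities that depend only on the correlation structure (the
TATES p-value correlations, the S_Het null Gamma) are computed once per
scenario point from the *generating* matrix; per-replicate statistics
still use each dataset's empirical correlations.

Defaults follow the reference protocol: n = 5,000, R = 10,000,
significance at P < 5×10⁻⁸, MAF 0.3 (the allele frequency is a free
parameter of the framework; 0.3 is a typical common-variant value and
all frequency-sensitive checks state it explicitly).

The test suite runs the comparisons at desk scale, chosen so that every
assertion retains resolving power: null calibration at n = 2,000 with
R = 10⁴ at α = 0.05; power-structure checks at n = 5,000, R = 1,000,
α = 10⁻⁴; parameter-recovery checks at n = 10⁵.  Rejection-rate
assertions use a 3-binomial-SE band (per-comparison level ≈ 99.7%),
which keeps the family-wise false-alarm probability of the 32
simultaneous calibration checks below ~10% while still detecting the
known mild min-P/TATES inflation at high positive correlation (exact
computation gives a true level of ≈ 0.0535 at r = 0.5 for K ∈ {2, 4});
that documented inflation beyond r = 0.5 is reported, not asserted
against.

## What the synthetic data do and do not show

The generator reproduces exactly the conditions the tests are calibrated
for: HWE genotypes, Gaussian residuals, a single causal SNP, complete
data.  Passing tests therefore demonstrate correctness of the methods
and the engine *under the model*, and the relative power orderings match
what the model predicts.  They do not speak to robustness against LD,
genotyping error, missingness, non-Gaussian traits, relatedness or
stratification — none of which the framework models.

## Numerical choices

* PSD tolerance: smallest eigenvalue > 10⁻⁸ counts as positive definite;
  failures are rejected (resampled or raised), never repaired.
* MVN sampling uses an eigendecomposition square root, so exactly
  singular admissible matrices (e.g. r = ±1 pairs) still sample.
* p-values are floored at 10⁻³⁰⁰ to stay inside (0, 1].
* Ordinal regression: BFGS, gradient tolerance 10⁻⁸ per observation,
  max 100 iterations.
* Gamma fit for S_Het: method of moments (shape = m²/s², scale = s²/m);
  fewer than 10³ null draws triggers a warning.
* Ties in `cap_snps_per_trait` break by row order (stable sort).
* The correlation grid is built from integer steps and rounded to 10
  decimals, so −0.3 is exactly representable and the K = 4 PD boundary
  is decided deterministically.
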