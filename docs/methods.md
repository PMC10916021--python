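# Methods

## Model

A block of *L* neighbouring CpGs with beta values `Z = (Z_1, …, Z_L)` in
(0, 1)ᴸ is modelled with the Libby–Novick generalized beta distribution:
`Z_l = P_l/(P_l + Q)` with independent `P_l ~ Gamma(α_l, 1)` and a single
shared `Q ~ Gamma(β_b, 1)`. Its log-density is

    log Γ(Σα + β) − log Γ(β) − Σ log Γ(α_l)
      + Σ[(α_l − 1)·log(z_l/(1−z_l)) − 2·log(1−z_l)]
      − (Σα + β)·log(1 + Σ z_l/(1−z_l)),

computed entirely with `gammaln`/`log1p` so it is finite for any argument
representable strictly inside (0, 1). For L = 1 it reduces exactly to
`Beta(α, β)`; for L ≥ 2 each marginal is `Beta(α_l, β)` and the shared
denominator induces positive dependence.

Covariates enter through the logit mean link. Since
`E(Z_l) = α_l/(α_l + β_b)`, the link `logit E(Z_il) = γ_0l + x_iᵀγ` is
equivalent to `log α_il − log β_b = γ_0l + x_iᵀγ`, i.e.

    α_il = β_b · exp(γ_0l + x_iᵀγ),

the unique parameterization consistent with the link. One dispersion
`β_b` is shared across samples and CpGs of a block: a per-sample
dispersion would make the reparameterization from `(α, β)` to `(γ, β)`
under-determined. Intercepts `γ_0l` are CpG-specific; slopes are shared
across the block — the block's phenotype effect is a single parameter
`γ_1`, which is what makes a one-degree-of-freedom region test possible.

Assumptions: beta values strictly inside (0, 1) (the pipeline clips to
`[1e-6, 1 − 1e-6]` and logs the count — the density is undefined at the
boundaries); samples independent; within a block, dependence of the
exchangeable positive form the shared denominator generates.

## Segmentation

CpGs are ordered by chromosome (natural order chr1 … chr22, chrX, chrY)
and base-pair position, ties broken by CpG ID. Pearson correlations of
adjacent pairs are computed on the beta scale, pairwise-complete over
samples; pairs that span a chromosome boundary or involve a
zero-variance CpG receive a sentinel of −2 (below any admissible
threshold, with a warning for the degenerate case). Maximal runs whose
internal correlations are all **strictly** greater than the threshold
(default 0.5; a tie at the threshold breaks the chain) become blocks;
everything else is a singleton. Blocks always partition the CpGs. No
base-pair distance cap is applied by default — correlation is the
criterion — but `max_gap` is available for users who want one.
Internal coordinates are 1-based inclusive (manifest convention); BED
export converts to 0-based half-open.

## Estimation and testing

Each block is fitted by maximizing the log-likelihood over
`(γ_01…γ_0L, γ_1…γ_p, log β_b)` with Nelder–Mead (function tolerance
1e-8, parameter tolerance 1e-6, at most 200·dim iterations, identical
settings for full and null fits so the LRT difference is not a stopping
artifact). The starting point comes from per-CpG method-of-moments beta
fits — `log β_b` starts at the log of the mean moment estimate of β,
`γ_0l` at `log α̂_l − log β̂`, slopes at 0 — plus two seeded jittered
restarts (SD 0.2) against local optima. For binary designs the
likelihood is accumulated over the distinct design rows (two groups
instead of n samples), which makes an objective evaluation O(G·L) and
the genome-scale runs cheap. A test verifies that the Nelder–Mead
optimum coincides with a Powell optimum to 1e-4, so the reported optimum
is a property of the objective, not the optimizer.

The null fit fixes `γ_1 = 0` and removes it from the free parameters.
The full fit is additionally warm-started from the null optimum — a
feasible point of the nested full model — which enforces
`loglik_full ≥ loglik_null` numerically. The LRT statistic
`2(loglik_full − loglik_null)` is floored at 0; a pre-floor value below
−1e-4 is declared a convergence failure, and non-convergent blocks carry
a missing p-value plus a flag rather than being dropped silently.
P-values come from the upper tail of χ²(1) and are adjusted across
blocks (Bonferroni `min(1, p·B)` by default with B the number of
non-missing tests; Holm and Benjamini–Hochberg available, plus a
per-test "none" mode for power experiments). Significant blocks with
L ≥ 2 are labelled DMR, singletons DMP.

Block tasks are pure functions of (block data, per-block seed derived by
`SeedSequence(seed, spawn_key=(block_id,))`), so results are independent
of the joblib worker count and of the input CpG order.

## Comparators

*EWAS*: per-CpG OLS of M-values (`M = log2(z/(1−z))`; the base-2
convention only rescales coefficients, never t statistics or p-values)
on the same design, two-sided t test on the phenotype coefficient.

*Simplified IVW region statistic*: with per-CpG estimates `β̂`, standard
errors `se` and inter-CpG correlation `R` (estimated from the block's
M-values with a 1e-8 diagonal ridge), `Ω = diag(se)·R·diag(se)` and the
region effect is `A = (1ᵀΩ⁻¹1)⁻¹1ᵀΩ⁻¹β̂` with SE `√((1ᵀΩ⁻¹1)⁻¹)` and a
normal two-sided p-value. This is the known-σ meta-analysis core of
distance-window region detectors, without candidate-region search or
shrinkage of the EWAS statistics; it is exactly the statistic whose
closed-form power the `theory` module computes. When Ω is numerically
singular (perfectly correlated CpGs) the weights fall back to the
pseudo-inverse, whose limit gives the correct single-effective-CpG
answer; an undefined statistic raises with the condition number.

*Analytic power*: under compound symmetry,
`(1ᵀΩ⁻¹1)^(−1/2) = √(σ_n²(1+(L−1)ρ)/L)`, and the two-sided level-α
power at true effect γ₁ is
`P(Z > −γ₁/SE + z_{1−α/2}) + P(Z < −γ₁/SE + z_{α/2})`. It equals α
exactly at γ₁ = 0 and is strictly decreasing in ρ — the analytic form of
the meta-analytic power decay with correlation.

## Synthetic data generator

The generator emulates array-style methylation of a case/control study:
single CpGs are `Beta(a, b)` with shapes solved from a target
(mean, SD); the two phenotype groups share the SD and differ in mean by
`signal_strength · SD` (signal strength = group separation in SD units).
Defaults: 253/253 samples (with a 422/84 unbalanced option), baseline
mean 0.3 and SD 0.05 — an intermediate-methylation CpG with typical
array-scale noise; both are configuration fields. A continuous-phenotype
mode links each sample's mean to a standardized phenotype through the
same shift.

Correlated chains are grown one column at a time with a Gaussian copula
AR step: normal-score the predecessor, mix with fresh noise at a latent
correlation, back-transform through the Beta quantile function. The
latent correlation is calibrated with the Hermite-polynomial expansion
of the quantile transform (`Cov = Σ c_k² r^k/k!`, solved by bisection),
so each column keeps its beta marginal **exactly** while the realized
Pearson correlation on the beta scale hits the target (contract:
±0.05 at n = 506). Blocks are laid on one synthetic chromosome with
100 bp intra-block spacing and 10 kb inter-block gaps; the gaps exceed
the 500 bp window of distance-based region detectors, so the contiguity
blocks coincide with distance-window regions, and the IVW comparator is
evaluated on those blocks (evaluating it on correlation-threshold blocks
would collapse it to per-CpG EWAS at low ρ and make the low-correlation
comparison meaningless).

What the generator does **not** emulate: bimodal genome-wide beta-value
distributions, probe-type and batch artifacts, covariate confounding,
long-range correlation decay, missing values. Passing tests therefore
demonstrate correctness of the statistical machinery under controlled
dependence, not end-to-end performance on real arrays.

The harness counts, per replicate, significant CpGs among truth-signal
blocks (power numerator) and truth-null blocks (FPR numerator), each
over the corresponding CpG total — the "DMR CpGs over total CpGs"
convention — and reports replicate-level Monte Carlo standard errors.

## Calibration and the correlation ceiling

A structural property of the Libby–Novick family, verified empirically
by direct sampling of the gamma-ratio construction: the inter-CpG
correlation it can express is pinned to the marginal mean —
`corr(Z_1, Z_2) ≈ α/(α+β) = μ`, nearly independent of the
concentration. Consequences, measured on copula-simulated null data
(506 samples, size-2 blocks):

- at data correlation ρ ≈ μ the LRT is well calibrated (mean statistic
  ≈ 1.05, KS test against χ²(1) passes);
- at ρ well **below** μ the test is conservative (mean ≈ 0.76 at ρ = 0,
  μ = 0.3);
- at ρ well **above** μ it is anticonservative (mean ≈ 1.7 at ρ = 0.8,
  μ = 0.3, which yields roughly two Bonferroni-significant blocks per
  1,000 null blocks at family-wise level 0.05).

The same mismatch that inflates the null statistic also inflates power
at high ρ: the joint model under-accounts the shared noise, so the
high-correlation power advantage over per-CpG EWAS and the mild
genome-wide null inflation at ρ ≫ μ are two faces of one phenomenon. At
a high baseline mean (μ = 0.85, where the expressible range covers 0.8)
the test is calibrated-to-conservative and the high-ρ power advantage
disappears. Users should treat block calls at adjacent correlations far
above the block's mean methylation level with corresponding care. The
LRT calibration experiment in the acceptance suite simulates from the
model's own null (where the χ²(1) reference is the right one); the
genome-wide null specificity experiment uses the copula generator at
ρ = 0.8 and exhibits the mild inflation described above.

## Numerical choices and degenerate inputs

- Beta clipping constant 1e-6 at the boundaries; clipped cells logged.
- Non-finite parameter vectors get an infinite objective value
  (optimizer-safe), as do overflowing linear predictors (|η| > 500).
- Zero-variance CpGs: correlation sentinel + warning, never NaN
  propagation; rank-deficient designs (e.g. constant phenotype) raise
  immediately.
- Correlation estimates are clipped to [−1, 1]; the ridge on estimated R
  is 1e-8 of the mean diagonal.
- Method-of-moments starts clamp the per-CpG variance into a feasible
  range before inverting to shape parameters.
- Compound-symmetry ρ is accepted on the full positive-definite range
  `(−1/(L−1), 1]`, with ρ = 1 as the continuous limit.

## Problem sizes used in the shipped experiments

The acceptance experiments use 1,000 null blocks (specificity and LRT
calibration), 500 signal blocks (power saturation), 1,500 Monte Carlo
replicates per grid point for the IVW-versus-theory check, and 15–40
replicates of 20–25-block datasets for the power-comparison checks;
together they complete in a few minutes on one CPU. Unit tests use
smaller sanity bands (e.g. 200-block calibration windows). All
randomness flows from explicit seeds through `numpy.random.Generator`
objects; no global state is used.

## Known limitations

- One shared dispersion per block; no dispersion covariates, no robust
  (sandwich) standard errors, no Wald/score tests.
- The expressible inter-CpG correlation is tied to the mean (see above);
  negative adjacent dependence cannot be represented at all.
- The IVW comparator is deliberately the simplified known-σ statistic,
  not a full re-implementation of published distance-window detectors.
- Preprocessing (normalization, batch correction, cell-type
  deconvolution) is out of scope: the pipeline consumes preprocessed
  beta matrices.
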