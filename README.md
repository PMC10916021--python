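# gbdmr — DMR detection with generalized beta regression

`gbdmr` identifies **differentially methylated regions (DMRs)** — runs of
neighbouring CpG sites whose DNA-methylation levels are jointly associated
with a phenotype — directly on Illumina 450k/EPIC **beta values**, without
the normality assumption behind linear-model pipelines.

It is written for epigenetics researchers who have a preprocessed
CpG-by-sample beta matrix, a sample phenotype table and a manifest-style
annotation, and who want region calls plus the benchmarking machinery
(per-CpG EWAS, an inverse-variance-weighted region statistic, analytic
power curves and a simulation harness) in one package.

## The model

A beta value is a ratio in (0, 1), so each CpG is modelled marginally as a
beta variate. A block of *L* neighbouring CpGs is modelled jointly with the
*L*-variate **generalized beta (Libby–Novick) distribution**: with
independent gamma variates `P_l ~ Gamma(α_l, 1)` and one shared
`Q ~ Gamma(β_b, 1)`,

    Z_l = P_l / (P_l + Q),  l = 1, …, L.

Every marginal is `Beta(α_l, β_b)` and the shared denominator induces
positive dependence between neighbours. The detector has three steps:

1. **Segment.** CpGs are ordered by chromosome and position; maximal runs
   whose adjacent Pearson correlations all exceed a threshold (default 0.5)
   form blocks, all other CpGs are singleton blocks.
2. **Regress.** Per block, the mean of each CpG is tied to the design
   through a logit link, `logit E(Z_il) = γ_0l + x_iᵀγ`, which under the
   Libby–Novick parameterization is exactly
   `log α_il − log β_b = γ_0l + x_iᵀγ` (CpG-specific intercepts, slopes
   shared across the block). Parameters are estimated by maximum likelihood
   (Nelder–Mead with seeded restarts).
3. **Test.** The phenotype coefficient `γ_1` is tested per block with a
   likelihood-ratio statistic referred to χ²(1); p-values are adjusted
   across blocks (Bonferroni by default). Significant multi-CpG blocks are
   DMRs, significant singletons are DMPs.

The package also implements the comparison methods used to benchmark
region detectors: per-CpG EWAS (OLS on M-values, `M = log2(z/(1−z))`), a
simplified inverse-variance-weighted (IVW) region statistic
`A = (1ᵀΩ⁻¹1)⁻¹1ᵀΩ⁻¹β̂` with `Ω = diag(se)·R·diag(se)`, and the
closed-form power of that statistic under compound-symmetric correlation —
which shows analytically why meta-analytic region statistics *lose* power
as inter-CpG correlation grows (at ρ = 1 a region of L CpGs carries one
effective observation).

## Worked example

Simulate ten size-2 blocks (506 samples, 253 per group, adjacent
correlation 0.8) with the first two blocks carrying a one-SD group shift,
then run the detector genome-wide with Bonferroni correction:

```python
from gbdmr import SimConfig, simulate_dataset, run_gbdmr, results_to_frame

config = SimConfig(signal_strength=1.0, rho=0.8, block_size=2, n_blocks=10,
                   n_signal_blocks=2, seed=7)
sim = simulate_dataset(config, seed=7)
results = run_gbdmr(sim.to_methylation_dataset(), "phenotype",
                    correction="bonferroni", alpha_level=0.05, seed=7)
print(results_to_frame(results).round(4).to_string(index=False))
```

```
 block_id chromosome  start   end  block_size  gamma1_estimate  lrt_statistic  p_value  p_adjusted label
        0       chr1   1000  1100           2           0.1946       174.1145   0.0000      0.0000   DMR
        1       chr1  11100 11200           2           0.2421       225.1312   0.0000      0.0000   DMR
        2       chr1  21200 21300           2           0.0045         0.0822   0.7743      1.0000  null
        3       chr1  31300 31400           2          -0.0044         0.0802   0.7770      1.0000  null
        4       chr1  41400 41500           2          -0.0084         0.2850   0.5934      1.0000  null
        5       chr1  51500 51600           2          -0.0170         1.1631   0.2808      1.0000  null
        6       chr1  61600 61700           2           0.0086         0.3240   0.5692      1.0000  null
        7       chr1  71700 71800           2          -0.0481        10.5781   0.0011      0.0114   DMR
        8       chr1  81800 81900           2           0.0182         1.2939   0.2553      1.0000  null
        9       chr1  91900 92000           2           0.0309         3.9007   0.0483      0.4827  null
```

Both planted blocks are recovered with enormous LRT statistics and
positive effect estimates (`γ_1 ≈ 0.2` on the log-odds scale matches the
simulated 0.30 → 0.35 mean shift). Block 7 is a false call: at ρ = 0.8,
far above this baseline's mean of 0.3, the block test is mildly
anticonservative — a structural property of the model family discussed in
`docs/methods.md` ("Calibration and the correlation ceiling").

The same run is available from a shell:

```bash
gbdmr run --beta beta.tsv --pheno pheno.tsv --annot manifest.tsv \
      --phenotype sex --covariates age --correction bonferroni \
      --out results.tsv --bed results.bed --seed 1
gbdmr theory --gamma-grid 0:1:0.01 --rho 0,0.5,0.9 --out curve.tsv
gbdmr power-curve --vary rho --grid 0.1,0.5,0.9 --reps 100 --seed 1 --out power.tsv
```

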