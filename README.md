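# wssgwas

Weighted single-step GWAS for pedigreed populations with repeated
records — QTL mapping when many animals are phenotyped but few are
genotyped.

Animal-breeding datasets routinely pair a deep pedigree and thousands
of repeated performance records (e.g. repeated semen evaluations of AI
boars) with SNP-array genotypes on only a subset of recent animals.
Single-step GBLUP handles that structure in one mixed-model analysis by
blending the pedigree relationship matrix **A** with the genomic matrix
**G**; the *weighted* single-step GWAS (wssGWAS) extension back-solves
the estimated breeding values into per-SNP effects, re-weights the SNPs
by the variance they carry, and reports the share of additive genetic
variance explained by fixed 0.4 Mb genome windows. This package
implements that entire workflow — simulation, quality control, AI-REML,
ssGBLUP, the weighting loop and the window scan — for geneticists who
want a transparent, tested, pure-Python alternative to the classical
Fortran toolchains.

## The model

Records follow a repeatability animal model

    y = Xb + Za + Wp + e,
    a ~ N(0, H sigma2_a),   p ~ N(0, I sigma2_pe),   e ~ N(0, I sigma2_e)

with fixed year–season classes plus age and collection-interval
covariates in `b`, and the single-step inverse relationship

    H^-1 = A^-1 + [[0, 0], [0, G_w^-1 - A22^-1]],
    G_w = 0.9 G + 0.1 A22,
    G = Z D Z' / sum_i 2 p_i (1 - p_i).

Variance components come from average-information REML on the pedigree;
heritability is `h2 = sigma2_a / (sigma2_a + sigma2_pe + sigma2_e)`.
The weighting loop runs for three iterations: solve for GEBVs `a_hat`,
back-solve marker effects `g_hat = lambda D Z' G_w^-1 a_hat`, set
`d_i = g_hat_i^2 2 p_i (1 - p_i)`, renormalize `tr(D) = m`, rebuild
`G`. Windows of 0.4 Mb are scored by `Var(sum_j z_j g_hat_j) /
sigma2_a x 100%`; windows above 1% are candidate QTL regions, nearby
selected windows merge, and the top three are extended by ±0.4 Mb.
See `docs/methods.md` for assumptions, numerical choices and
limitations.

## Worked example

Simulate a small nucleus herd (one 10% QTL plus 50 background QTLs,
progressive-motility-like variances, 40% of animals ungenotyped), run
QC and the full weighted analysis:

```python
from wssgwas import SimConfig, simulate_dataset, WssGwas, apply_qc

cfg = SimConfig(n_founders=120, n_generations=4, litter_size=2,
                n_chromosomes=3, chrom_length_bp=40_000_000,
                n_snps=1200, n_qtl=51,
                qtl_var_fractions=(0.10,) + (0.9 / 50,) * 50,
                var_a=0.00757, var_pe=0.00248, var_e=0.03695,
                records_per_animal=12, genotyped_fraction=0.6,
                n_burnin_generations=60, burnin_pop_size=80, seed=42)
pedigree, genotypes, records, truth = simulate_dataset(cfg)

genotypes_qc, report = apply_qc(genotypes)
print(f"QC: {report.n_snps_in} -> {report.n_snps_out} SNPs")

model = WssGwas(records, pedigree, genotypes_qc)
result = model.fit(n_iter=3)      # pedigree AI-REML, then 3 iterations
print(result.summary())
```

```
QC: 1200 -> 866 SNPs
Weighted single-step GWAS
==================================================
SNPs                               866
genotyped animals                  360
iterations                           3
h2                              0.1516
windows                            287
selected (> 1.0%)                   20
variance in selected (%)         45.71
--------------------------------------------------
top regions (midpoint +- 0.4 Mb):
  chr2 6.60-7.40 Mb  5.23% (5 SNPs)
  chr2 39.40-40.20 Mb  4.54% (7 SNPs)
  chr2 25.00-25.80 Mb  3.20% (4 SNPs)
```

Reading the output: AI-REML on the pedigree estimated a heritability of
0.15 for the simulated trait (truth 0.16). After three weighting
iterations the genome was cut into 287 windows of 0.4 Mb; 20 of them
each explain more than 1% of the additive genetic variance and jointly
account for 45.7% of it. The strongest region — 5.23% of the genetic
variance from five SNPs around 7.0 Mb on chromosome 2 — is the window
holding the planted 10% QTL, shrunken as expected for a back-solved
estimate. `result.window_scan()`, `result.marker_frame()` and
`result.gebv` expose the underlying tables; `result.plot_manhattan()`
draws the window scan.

The variance-component half of the workflow is a model object of its
own:

```python
from wssgwas import RepeatabilityModel
reml = RepeatabilityModel(records, pedigree).fit()
print(reml.summary())      # components, SEs, h2, fixed effects
```

A `wssgwas` command-line tool (`simulate`, `qc`, `reml`, `gwas`,
`windows`, `all`) drives the same pipeline from YAML configs and writes
TSV/JSON artifacts plus a reproducibility manifest.

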