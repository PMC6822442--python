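# Methods

## The model

All analyses are built around the repeatability animal model for record
`r` of animal `i`:

    y_ir = ys_j(i,r) + beta_age * Age_ir + beta_intv * Intv_ir
           + a_i + p_i + e_ir

* `ys_j` — fixed year–season class of the record (plus an overall mean;
  one class level is absorbed into the mean).
* `Age` (months) and `Intv` (collection interval, days) — linear
  covariates.
* `a ~ N(0, K * sigma2_a)` — additive genetic effects, with `K` either
  the pedigree numerator matrix `A` or the single-step matrix `H`.
* `p ~ N(0, I * sigma2_pe)` — permanent-environment effect of the
  animal, constant over its repeated records.
* `e ~ N(0, I * sigma2_e)` — record-level residual.

Heritability is `h2 = sigma2_a / (sigma2_a + sigma2_pe + sigma2_e)` and
repeatability `(sigma2_a + sigma2_pe)` over the same total.

### Relationship matrices

`A` is built by the tabular method; `A^-1` directly by Henderson's rules
with Meuwissen–Luo inbreeding coefficients (deep overlapping pedigrees
make inbreeding non-negligible, so it is always accounted for). The
genomic matrix is VanRaden's

    G = Z D Z' / sum_i 2 p_i (1 - p_i),

with `Z` the dosage matrix centered by `2 p_i`, `p_i` the observed
frequency of the counted allele among genotyped animals (flipping allele
labels leaves `G` unchanged), and `D` a diagonal of per-SNP weights.
`G` is blended as `G_w = 0.9 G + 0.1 A22` — compatibility with the
pedigree base and a guarantee of invertibility — and enters the
evaluation through

    H^-1 = A^-1 + [[0, 0], [0, G_w^-1 - A22^-1]].

No additional rescaling of `G` to `mean(diag(A22))` is applied: only the
0.9/0.1 blend.

### Variance components: AI-REML

`(sigma2_a, sigma2_pe, sigma2_e)` are estimated by average-information
REML on the mixed-model equations. Each iterate factorizes the
(sigma2_e-scaled) coefficient matrix, obtains the solutions, the
residual, and the traces `tr(A^-1 C^aa)` and `tr(C^pp)` from the dense
inverse; the gradient uses the standard trace identities and the AI
matrix is assembled from the working variates `Z a / sigma2_a`,
`W p / sigma2_pe`, `e / sigma2_e` (each requiring one extra solve).
Newton steps are halved up to five times if they leave the parameter
space, then replaced by the EM-REML update, which is always valid.
Components collapsing below `1e-5` of the phenotypic variance are pinned
to a floor of `1e-8 * var(y)` so the geometric EM decay near a zero
boundary cannot stall convergence. Start values are equal thirds of the
phenotypic variance; convergence is a relative parameter change below
`1e-8`. Standard errors come from the inverse AI matrix at convergence,
and `SE(h2)` by the delta method. The implementation was verified
against a direct Nelder–Mead optimization of the V-based restricted
likelihood (exact agreement on interior optima) and against a
finite-difference check of the gradient identities.

The MME solver uses dense Cholesky up to ~6,000 unknowns and sparse LU
beyond; a Jacobi-preconditioned conjugate-gradient path exists for very
large systems. Rank deficiency in the fixed block is handled by
drop-first coding plus a QR-based removal of any remaining confounded
columns (with a warning).

### The weighting loop

Variance components are estimated once, by *pedigree* AI-REML, and held
fixed. The loop (default three iterations, the convention in weighted
single-step GWAS) then alternates:

1. `t = 1`, `D = I`, `lambda = 1 / sum 2 p_i (1 - p_i)` (fixed).
2. GEBVs by ssGBLUP with `H^-1` built from `G_w = 0.9 G_(t) + 0.1 A22`.
3. Marker effects `g_hat = lambda D_(t) Z' G_w^-1 a_hat` over the
   genotyped animals.
4. Raw weights `d_i = g_hat_i^2 * 2 p_i (1 - p_i)`.
5. Trace normalization `D <- D * m / tr(D)` (total genetic variance
   constant; asserted to 1e-10 in every run).
6. Rebuild `G` and repeat.

A numerical note on step 3: the textbook formulation inverts the
*unweighted-blend* `G_(t)` itself. With allele frequencies estimated
from the data, `G 1 = 0` exactly, and once the weights concentrate the
weak eigen-tail of `G_(t)` amplifies GEBV noise catastrophically (we
observed window-variance totals exploding by iteration 3). The pipeline
therefore inverts the blended `G_w` — the same matrix the GEBVs were
estimated with, which is also what production implementations of the
marker back-solve do; the pedigree share lifts the weak directions. The
raw formulation (plus an optional diagonal ridge, default off) remains
available in `backsolve_snp_effects` and is exercised by the algebraic
reconstruction tests (`Z_c g_hat = a_hat` for full-rank `G`). When a
raw `G` is singular, the Moore–Penrose solution is used: it back-solves
the component of the GEBVs in the markers' row space (the arbitrary GEBV
mean lies in the null space).

### Windows

Marker effects from the final iteration are aggregated in fixed,
non-overlapping 0.4 Mb bins anchored at position 0 of each chromosome
(the anchoring is a reproducibility convention; empty bins are
dropped). The share of a window is the sample variance (n-1
denominator), across genotyped individuals, of its genetic score
`sum_j z_ij g_hat_j`, divided by `sigma2_a`, times 100. Selection takes
windows strictly above 1%; consecutive selected windows merge when
their midpoints are strictly less than 0.4 Mb apart (adjacent *full*
windows are exactly 0.4 Mb apart and do not merge — only truncated
terminal windows can; an `inclusive` flag flips the rule); the top
three windows are reported with a ±0.4 Mb flank around their midpoints,
keeping the window's own share (the extended span is reported
separately, not re-scored). Ranks break ties by genome order. The sum
of selected shares is reported but carries no closed-form identity
(between-window covariances exist).

## The synthetic-data generator

No real data ship with the package, so every study runs on simulated
herds designed to emulate a closed pig nucleus population:

* **Pedigree** — discrete generations; founders with alternating sexes;
  each generation pairs the previous generation's males and females at
  random, `litter_size` offspring per mating.
* **Genotypes** — biallelic SNPs gene-dropped with Haldane
  recombination at 1 Morgan per 100 Mb. Founder haplotypes are drawn
  either in linkage equilibrium at frequencies `U(0.05, 0.5)`, or — for
  window-mapping studies — from a closed random-mating burn-in herd
  (default size 100, 100 generations) whose drift builds local LD with
  a realistic decay (measured r² ≈ 0.5 within 0.1 Mb, ≈ 0.3 at
  0.1–0.4 Mb, < 0.02 beyond 5 Mb). The burn-in is the minimal device
  that produces the haploblock structure fixed-window analysis relies
  on; it is not calibrated to any empirical LD curve.
* **Breeding values** — a QTL part (each QTL's effect scaled so its
  dosage variance among founders matches its requested share of
  `sigma2_a`; QTL placed uniformly among SNPs with founder MAF above
  `min_qtl_maf`) plus a polygenic remainder transmitted down the
  pedigree with Mendelian-sampling variance `0.5 sigma2_poly` (0.75
  with one parent unknown).
* **Records** — `max(1, Poisson(records_per_animal))` per phenotyped
  animal (the record-count distribution is an assumption; only the mean
  is anchored in real designs); year–season drawn uniformly over
  `n_yearseason` classes with `N(0, var_yearseason)` effects; Age ~
  `U(8, 60)` months and Intv ~ `U(2, 14)` days with small non-zero
  slopes so covariate estimation is exercised; permanent-environment
  and residual draws complete the record.

What the generator does **not** emulate: empirical LD/haplotype
frequencies, selection and assortative mating, genotyping error,
year-season confounding with contemporary-group structure, and
non-Gaussian trait distributions. Passing tests therefore demonstrate
the estimator's correctness and its behaviour under a *plausible*
covariance structure, not performance guarantees on any particular real
herd.

### Benchmark study designs

Two fixed designs drive the headline checks (`simulate.
recovery_study_config` / `detection_study_config`):

* **Recovery** — 1,500 animals (250 founders, 5 generations), ~5
  records each, at variance components 0.05172 / 0.03682 / 0.19380
  (h² = 0.183, the log sperm-cell count setting). Twenty replicates;
  AI-REML means recover all three components within two empirical
  standard errors and the mean h² falls in [0.15, 0.22].
* **Detection** — 5,000 SNPs on a 260 Mb, 5-chromosome genome (the SNP
  density of a 50K porcine array, ≈ 650 windows of 0.4 Mb), 2,400
  pedigree animals with the most recent 1,000 genotyped, burn-in LD,
  progressive-motility variance components (0.00757 / 0.00248 /
  0.03695) with ~23 records per animal, one common (founder MAF ≥ 0.2)
  QTL at 5% of `sigma2_a` and the remaining 95% spread over 300 small
  background QTLs so the genetic variance resides on the genome.

In the detection study the QTL window's estimated share sits in the
2–6% range when the window is found — the same regime reported for top
windows on real data — and ranks among the first few windows in most
replicates, but first in only about half of them. A ceiling experiment
that feeds the *true* breeding values to the back-solve localizes the
QTL in 9/10 replicates: the gap is carried entirely by GEBV prediction
error, which at h² ≈ 0.16 and repeatability ≈ 0.21 caps single-step
GEBV accuracy near 0.8 regardless of record counts (permanent
environment is confounded with the animal effect within animal). The
back-solve spreads that error over all windows, and its upper tail
competes with a 5% QTL. This is a property of the information content
of such designs, not of the implementation.

## Numerical conventions

* Genotype dosages count the B allele; missing as NaN until imputation
  (frequency-sampling, or deterministic mean dosage `2p`).
* The exact Hardy–Weinberg test enumerates heterozygote counts
  conditional on allele counts in log space and sums probabilities no
  greater than the observed table's (ties included with a 1e-12
  relative slack); a chi-square variant is available.
* MAF and HWE are computed on retained individuals after the sample
  call-rate filter, mirroring plink's order; each SNP is attributed to
  the first filter it fails (unmapped → sex chromosome → call rate →
  MAF → HWE).
* PSD checks tolerate eigenvalues down to -1e-8; symmetric matrices are
  symmetrized after assembly to remove float drift.
* All randomness flows from explicit integer seeds; identical inputs
  give byte-identical outputs.

## Known limitations

* Single-trait analyses only; no maternal effects, no heterogeneous
  residual variances, no multi-breed G, no metafounders or APY.
* Dense factorizations bound practical problem sizes to a few thousand
  animals per analysis (REML needs the dense inverse of the coefficient
  matrix for its traces).
* The imputer is a placeholder for LD-aware phasing tools and should
  not be used at high missing rates.
* Window-share estimates are shrunken relative to a QTL's realized
  variance share; they localize signal rather than estimate effect
  sizes unbiasedly.
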