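"""Marker and sample quality control.

Filter chain (applied in this order, each SNP attributed to the first
filter it fails): unmapped -> sex chromosomes -> SNP call rate -> minor
allele frequency -> Hardy-Weinberg exact test.  Sample call-rate filtering
runs before SNP filters, matching plink's conventional order, so MAF and
HWE are computed on retained individuals only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np

from .kinship import GenotypeMatrix

__all__ = [
    "QcConfig",
    "QcReport",
    "filter_samples",
    "filter_snps",
    "apply_qc",
    "hwe_pvalue",
    "hwe_chisq_pvalue",
    "impute_missing",
]

SEX_CHROM_LABELS = {"X", "Y", "XY", "MT", "23", "24", "25", "26",
                    "chrX", "chrY", "chrM"}


@dataclass
class QcConfig:
    min_ind_callrate: float = 0.90
    min_snp_callrate: float = 0.90
    min_maf: float = 0.01
    hwe_p_min: float = 1e-6
    autosomes_only: bool = True
    hwe_method: str = "exact"  # or "chisq"

    def __post_init__(self):
        for name in ("min_ind_callrate", "min_snp_callrate", "min_maf",
                     "hwe_p_min"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")


@dataclass
class QcReport:
    """Per-filter removal bookkeeping; each SNP/individual counted once."""

    n_snps_in: int = 0
    removed_unmapped: int = 0
    removed_sex_chrom: int = 0
    removed_snp_callrate: int = 0
    removed_maf: int = 0
    removed_hwe: int = 0
    n_snps_out: int = 0
    n_ind_in: int = 0
    removed_ind_callrate: int = 0
    n_ind_out: int = 0

    def validate(self) -> None:
        snp_removed = (self.removed_unmapped + self.removed_sex_chrom
                       + self.removed_snp_callrate + self.removed_maf
                       + self.removed_hwe)
        if self.n_snps_out != self.n_snps_in - snp_removed:
            raise AssertionError(
                f"SNP bookkeeping broken: {self.n_snps_in} - {snp_removed} "
                f"!= {self.n_snps_out}")
        if self.n_ind_out != self.n_ind_in - self.removed_ind_callrate:
            raise AssertionError("individual bookkeeping broken")

    def as_dict(self) -> dict:
        return asdict(self)


def expected_survivors(n_in: int, removals) -> int:
    """Survivor count from a starting total and per-filter removal counts
    (each unit removed by exactly one filter)."""
    return int(n_in) - int(sum(removals))


def filter_samples(genotypes: GenotypeMatrix, config: QcConfig = None):
    """Drop individuals whose genotype call rate is below threshold."""
    config = config or QcConfig()
    if genotypes.n_ind == 0 or genotypes.n_snps == 0:
        raise ValueError("empty genotype matrix")
    cr = genotypes.ind_call_rate()
    keep = cr >= config.min_ind_callrate
    report = QcReport(n_ind_in=genotypes.n_ind,
                      removed_ind_callrate=int((~keep).sum()),
                      n_ind_out=int(keep.sum()))
    return genotypes.subset(ind_mask=keep), report


def filter_snps(genotypes: GenotypeMatrix, config: QcConfig = None,
                report: QcReport = None):
    """Apply the SNP filter chain; each SNP attributed to its first failure.

    Chromosome labels: positive integers (or their strings) are autosomes;
    X/Y/XY/MT and plink codes 23-26 are sex/mito; position <= 0 or
    chromosome 0 counts as unmapped.  Unknown labels raise.
    """
    config = config or QcConfig()
    report = report or QcReport(n_ind_in=genotypes.n_ind,
                                n_ind_out=genotypes.n_ind)
    report.n_snps_in = genotypes.n_snps
    m = genotypes.n_snps
    removed = np.zeros(m, dtype=bool)

    chrom = np.asarray([str(c) for c in genotypes.chrom])
    autosome = np.zeros(m, dtype=bool)
    unmapped = np.zeros(m, dtype=bool)
    sex = np.zeros(m, dtype=bool)
    for j, c in enumerate(chrom):
        if c in ("0", "", "NA", "nan", "None"):
            unmapped[j] = True
        elif c in SEX_CHROM_LABELS:
            sex[j] = True
        elif c.isdigit():
            autosome[j] = True
        else:
            raise ValueError(f"unknown chromosome label {c!r} at SNP "
                             f"{genotypes.snp_ids[j]!r}")
    unmapped |= genotypes.pos <= 0

    report.removed_unmapped = int((unmapped & ~removed).sum())
    removed |= unmapped
    if config.autosomes_only:
        report.removed_sex_chrom = int((sex & ~removed).sum())
        removed |= sex

    cr = genotypes.snp_call_rate()
    fail_cr = cr < config.min_snp_callrate
    report.removed_snp_callrate = int((fail_cr & ~removed).sum())
    removed |= fail_cr

    p = genotypes.allele_freq()
    with np.errstate(invalid="ignore"):
        maf = np.minimum(p, 1.0 - p)
    fail_maf = ~(maf >= config.min_maf)  # nan (all-missing) fails too
    report.removed_maf = int((fail_maf & ~removed).sum())
    removed |= fail_maf

    fail_hwe = np.zeros(m, dtype=bool)
    g = genotypes.dosages
    test = hwe_pvalue if config.hwe_method == "exact" else hwe_chisq_pvalue
    for j in np.flatnonzero(~removed):
        col = g[:, j]
        col = col[~np.isnan(col)]
        n_aa = int((col == 0).sum())
        n_ab = int((col == 1).sum())
        n_bb = int((col == 2).sum())
        if test(n_aa, n_ab, n_bb) < config.hwe_p_min:
            fail_hwe[j] = True
    report.removed_hwe = int(fail_hwe.sum())
    removed |= fail_hwe

    report.n_snps_out = int((~removed).sum())
    report.validate()
    return genotypes.subset(snp_mask=~removed), report


def apply_qc(genotypes: GenotypeMatrix, config: QcConfig = None):
    """Sample filter then SNP filter chain; returns (matrix, full report)."""
    config = config or QcConfig()
    kept, report = filter_samples(genotypes, config)
    return filter_snps(kept, config, report)


def hwe_pvalue(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Exact Hardy-Weinberg test p-value (Wigginton-style enumeration).

    Sums the probabilities, conditional on allele counts, of all
    heterozygote counts no more likely than the observed one.  Symmetric
    in allele labels: hwe_pvalue(a, b, c) == hwe_pvalue(c, b, a).
    """
    if min(n_AA, n_Aa, n_aa) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_AA + n_Aa + n_aa
    if n == 0:
        raise ValueError("all-zero genotype counts")
    n_rare = 2 * min(n_AA, n_aa) + n_Aa  # rare-allele copies
    # log-probability of each possible heterozygote count given allele counts
    hets = np.arange(n_rare % 2, n_rare + 1, 2)
    n_A = n_rare
    n_a = 2 * n - n_rare
    logp = np.array([
        _log_table_prob(h, (n_A - h) // 2, n, n_A, n_a) for h in hets])
    logp -= logp.max()
    probs = np.exp(logp)
    probs /= probs.sum()
    obs = np.flatnonzero(hets == n_Aa)[0]
    return float(min(1.0, probs[probs <= probs[obs] * (1 + 1e-12)].sum()))


def _log_table_prob(n_het: int, n_rarehom: int, n: int, n_A: int,
                    n_a: int) -> float:
    """log P(het count | allele counts) under random union of gametes."""
    n_comhom = n - n_het - n_rarehom
    return (n_het * math.log(2.0)
            + math.lgamma(n + 1)
            - math.lgamma(n_het + 1) - math.lgamma(n_rarehom + 1)
            - math.lgamma(n_comhom + 1)
            + math.lgamma(n_A + 1) + math.lgamma(n_a + 1)
            - math.lgamma(2 * n + 1))


def hwe_chisq_pvalue(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """One-degree-of-freedom chi-square HWE test (no continuity correction)."""
    from scipy.stats import chi2

    n = n_AA + n_Aa + n_aa
    if n == 0:
        raise ValueError("all-zero genotype counts")
    p = (2 * n_AA + n_Aa) / (2 * n)
    q = 1.0 - p
    exp = np.array([n * p * p, 2 * n * p * q, n * q * q])
    obs = np.array([n_AA, n_Aa, n_aa], dtype=float)
    if (exp == 0).any():
        return 1.0
    stat = float(((obs - exp) ** 2 / exp).sum())
    return float(chi2.sf(stat, df=1))


def impute_missing(genotypes: GenotypeMatrix, seed: int | None = None,
                   mode: str = "sample") -> GenotypeMatrix:
    """Fill missing calls from per-SNP genotype frequencies.

    ``mode='sample'`` draws genotype codes from the observed per-SNP
    genotype distribution (seeded); ``mode='mean'`` substitutes the mean
    dosage 2p deterministically.
    """
    g = genotypes.dosages.copy()
    miss = np.isnan(g)
    if not miss.any():
        return genotypes
    if miss.all(axis=0).any():
        bad = np.flatnonzero(miss.all(axis=0))
        raise ValueError(
            f"SNPs {bad[:5].tolist()} have no observed genotypes; filter "
            "them before imputing")
    if mode == "mean":
        fill = np.nanmean(g, axis=0)
        idx = np.where(miss)
        g[idx] = fill[idx[1]]
    elif mode == "sample":
        rng = np.random.default_rng(seed)
        for j in np.flatnonzero(miss.any(axis=0)):
            obs = g[~miss[:, j], j]
            counts = np.array([(obs == k).sum() for k in (0, 1, 2)],
                              dtype=float)
            probs = counts / counts.sum()
            g[miss[:, j], j] = rng.choice(
                [0.0, 1.0, 2.0], size=miss[:, j].sum(), p=probs)
    else:
        raise ValueError("mode must be 'sample' or 'mean'")
    return GenotypeMatrix(g, genotypes.ids.copy(), genotypes.chrom.copy(),
                          genotypes.pos.copy(), genotypes.snp_ids.copy())
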