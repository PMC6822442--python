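"""Synthetic pedigree / genotype / phenotype generator.

Emulates the data structure of a closed nucleus herd with repeated
semen-type records: a multi-generation pedigree in which only recent
animals are genotyped, biallelic autosomal SNPs dropped through the
pedigree under Mendelian transmission with recombination (Haldane map,
1 Morgan per 100 Mb), additive QTL plus a pedigree-transmitted polygenic
remainder, and repeated records

    y = mu + yearseason + beta_age * Age + beta_intv * Intv + a + p + e

with user-set additive (var_a), permanent-environment (var_pe) and
residual (var_e) variances.  Generative choices the data model does not
pin down (Poisson record counts, uniform founder allele frequencies,
uniform Age/Intv covariates, alternating sexes) are deliberate simulator
decisions documented here and in docs/methods.md.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .kinship import GenotypeMatrix, Pedigree, UNKNOWN

__all__ = [
    "SimConfig",
    "SimTruth",
    "simulate_pedigree",
    "drop_genotypes",
    "simulate_phenotypes",
    "simulate_dataset",
    "records_per_individual",
]

BP_PER_MORGAN = 100_000_000  # 1 cM per Mb


@dataclass
class SimConfig:
    """Simulation settings.

    Default variances are the magnitudes reported for log sperm-cell count
    in Duroc boars (var_a = 0.05172, var_pe = 0.03682, var_e = 0.19380,
    h2 ~ 0.18); the trait scale is arbitrary.
    """

    n_founders: int = 40
    n_generations: int = 5
    litter_size: int = 2
    n_chromosomes: int = 5
    chrom_length_bp: int = 100_000_000
    n_snps: int = 1000
    n_qtl: int = 1
    qtl_var_fractions: tuple = (0.05,)
    var_a: float = 0.05172
    var_pe: float = 0.03682
    var_e: float = 0.19380
    mu: float = 27.2
    beta_age: float = 0.005
    beta_intv: float = 0.01
    var_yearseason: float = 0.01
    n_yearseason: int = 8
    records_per_animal: float = 5.0
    genotyped_fraction: float = 0.5
    phenotyped_fraction: float = 1.0
    n_burnin_generations: int = 0
    burnin_pop_size: int = 100
    min_qtl_maf: float = 0.05
    age_range_months: tuple = (8.0, 60.0)
    intv_range_days: tuple = (2.0, 14.0)
    founder_maf_range: tuple = (0.05, 0.5)
    seed: int = 0

    def __post_init__(self):
        for name in ("var_a", "var_pe", "var_e", "var_yearseason"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        fr = np.asarray(self.qtl_var_fractions, dtype=float)
        if fr.size != self.n_qtl:
            raise ValueError("qtl_var_fractions must have n_qtl entries")
        if (fr < 0).any() or fr.sum() > 1.0 + 1e-12:
            raise ValueError("QTL variance fractions must be >= 0 and sum "
                             "to at most 1 (the polygenic term tops up "
                             "var_a)")
        if self.n_snps < self.n_qtl:
            raise ValueError("need n_snps >= n_qtl")
        if self.n_founders < 2:
            raise ValueError("need at least 2 founders to form matings")
        if self.n_generations < 1:
            raise ValueError("need at least 1 generation")


@dataclass
class SimTruth:
    """Ground truth for parameter-recovery tests."""

    true_breeding_values: np.ndarray
    qtl_snp_indices: np.ndarray
    qtl_effects: np.ndarray
    realized_h2: float
    yearseason_effects: np.ndarray = None

    def to_json(self, path) -> None:
        payload = {
            "true_breeding_values": self.true_breeding_values.tolist(),
            "qtl_snp_indices": self.qtl_snp_indices.tolist(),
            "qtl_effects": self.qtl_effects.tolist(),
            "realized_h2": self.realized_h2,
            "yearseason_effects": (
                self.yearseason_effects.tolist()
                if self.yearseason_effects is not None else None),
        }
        Path(path).write_text(json.dumps(payload, indent=1))


def simulate_pedigree(config: SimConfig) -> Pedigree:
    """Discrete-generation pedigree with alternating sexes.

    Founders (generation 0) have unknown parents.  Each next generation is
    produced by pairing the males and females of the previous generation
    at random (each mating yields ``litter_size`` offspring), so parents
    always precede offspring and every mating is between distinct, sexed
    animals of the previous generation.
    """
    rng = np.random.default_rng(config.seed)
    sires, dams, sexes = [], [], []
    for i in range(config.n_founders):
        sires.append(UNKNOWN)
        dams.append(UNKNOWN)
        sexes.append(i % 2)  # alternate so both sexes exist
    prev = list(range(config.n_founders))
    if not any(sexes[i] == 0 for i in prev) or not any(
            sexes[i] == 1 for i in prev):
        raise ValueError("founder set must contain both sexes")
    for _ in range(config.n_generations):
        males = [i for i in prev if sexes[i] == 0]
        females = [i for i in prev if sexes[i] == 1]
        rng.shuffle(males)
        rng.shuffle(females)
        n_pairs = min(len(males), len(females))
        cur = []
        for k in range(n_pairs):
            for _ in range(config.litter_size):
                idx = len(sires)
                sires.append(males[k])
                dams.append(females[k])
                sexes.append(len(cur) % 2)
                cur.append(idx)
        prev = cur
    n = len(sires)
    ids = np.arange(1, n + 1)
    return Pedigree(ids=ids, sire=np.asarray(sires), dam=np.asarray(dams),
                    sex=np.asarray(sexes))


def _snp_map(config: SimConfig, rng: np.random.Generator):
    """Random SNP positions, sorted within chromosomes."""
    per_chrom = np.full(config.n_chromosomes,
                        config.n_snps // config.n_chromosomes)
    per_chrom[: config.n_snps % config.n_chromosomes] += 1
    chrom, pos = [], []
    for c in range(config.n_chromosomes):
        p = np.sort(rng.choice(config.chrom_length_bp, size=per_chrom[c],
                               replace=False))
        chrom.append(np.full(per_chrom[c], c + 1))
        pos.append(p)
    return np.concatenate(chrom), np.concatenate(pos)


def _gamete(hap: np.ndarray, chrom_slices, morgan_pos, rng) -> np.ndarray:
    """One meiosis: recombine the two parental haplotypes (Haldane model,
    crossover count ~ Poisson(chromosome length in Morgans))."""
    out = np.empty(hap.shape[1], dtype=np.int8)
    for sl, mpos in zip(chrom_slices, morgan_pos):
        length = mpos[-1] if mpos.size else 0.0
        n_x = rng.poisson(length)
        start = rng.integers(2)
        if n_x == 0:
            out[sl] = hap[start, sl]
            continue
        xpos = np.sort(rng.uniform(0.0, length, size=n_x))
        phase = (start + np.searchsorted(xpos, mpos)) % 2
        seg = hap[:, sl]
        out[sl] = np.where(phase == 0, seg[0], seg[1])
    return out


def drop_genotypes(pedigree: Pedigree, config: SimConfig,
                   founder_freqs: np.ndarray | None = None,
                   rng: np.random.Generator | None = None,
                   return_haplotypes: bool = False):
    """Gene-drop biallelic SNPs through the pedigree.

    Founder haplotypes are drawn from Hardy–Weinberg proportions at allele
    frequencies ~ Uniform(founder_maf_range) (or user-supplied); offspring
    gametes are Mendelian samples of parental haplotypes with Haldane
    recombination on the bp map at 1 Morgan per 100 Mb.

    With ``n_burnin_generations > 0`` the pedigree founders instead sample
    their gametes from a closed random-mating population of
    ``burnin_pop_size`` animals evolved for that many discrete
    generations.  Drift in the small burn-in herd builds local linkage
    disequilibrium (haploblocks), the hallmark of commercial livestock
    lines that fixed-size window analysis relies on; without it every
    marker segregates independently of the causal loci.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    chrom, pos = _snp_map(config, rng)
    m = len(pos)
    if founder_freqs is None:
        lo, hi = config.founder_maf_range
        founder_freqs = rng.uniform(lo, hi, size=m)
    founder_freqs = np.asarray(founder_freqs, dtype=float)

    chrom_slices, morgan_pos = [], []
    for c in np.unique(chrom):
        w = np.flatnonzero(chrom == c)
        chrom_slices.append(slice(w[0], w[-1] + 1))
        morgan_pos.append(pos[w].astype(float) / BP_PER_MORGAN)

    pool = None
    if config.n_burnin_generations > 0:
        pool = _burnin_pool(config, founder_freqs, chrom_slices, morgan_pos,
                            rng, m)

    def founder_hap():
        if pool is None:
            return (rng.random(m) < founder_freqs).astype(np.int8)
        parent = rng.integers(pool.shape[0])
        return _gamete(pool[parent], chrom_slices, morgan_pos, rng)

    n = pedigree.n
    haps = np.empty((n, 2, m), dtype=np.int8)
    for i in range(n):
        s, d = pedigree.sire[i], pedigree.dam[i]
        for k, parent in enumerate((s, d)):
            if parent == UNKNOWN:
                haps[i, k] = founder_hap()
            else:
                haps[i, k] = _gamete(haps[parent], chrom_slices,
                                     morgan_pos, rng)
    dosages = haps.sum(axis=1).astype(float)
    gm = GenotypeMatrix(dosages=dosages, ids=pedigree.ids.copy(),
                        chrom=chrom, pos=pos)
    if return_haplotypes:
        return gm, haps
    return gm


def _burnin_pool(config: SimConfig, founder_freqs: np.ndarray, chrom_slices,
                 morgan_pos, rng: np.random.Generator,
                 m: int) -> np.ndarray:
    """Closed random-mating herd evolved to build drift LD.

    Returns the final generation's haplotypes (pop_size x 2 x m).  The
    effective size (= ``burnin_pop_size``) and generation count control
    the LD extent: at equilibrium E[r^2] ~ 1/(1 + 4 Ne c)."""
    size = config.burnin_pop_size
    haps = (rng.random((size, 2, m)) < founder_freqs).astype(np.int8)
    for _ in range(config.n_burnin_generations):
        nxt = np.empty_like(haps)
        sires = rng.integers(size // 2, size=size)
        dams = rng.integers(size // 2, size, size=size)
        for i in range(size):
            nxt[i, 0] = _gamete(haps[sires[i]], chrom_slices, morgan_pos,
                                rng)
            nxt[i, 1] = _gamete(haps[dams[i]], chrom_slices, morgan_pos,
                                rng)
        haps = nxt
    return haps


def simulate_phenotypes(pedigree: Pedigree, genotypes: GenotypeMatrix,
                        config: SimConfig,
                        rng: np.random.Generator | None = None):
    """Repeated records under the repeatability animal model.

    True breeding values are a QTL part (centered genotype score scaled so
    its founder variance matches ``sum(qtl_var_fractions) * var_a``) plus a
    pedigree-transmitted polygenic remainder topping up to var_a.  Each
    animal gets max(1, Poisson(records_per_animal)) records; permanent
    environment is one draw per animal, residual one per record.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 2)
    n = pedigree.n
    founders = pedigree.is_founder
    fractions = np.asarray(config.qtl_var_fractions, dtype=float)
    qtl_var_target = float(fractions.sum()) * config.var_a
    if qtl_var_target > config.var_a + 1e-12:
        raise ValueError("QTL variance request exceeds var_a")

    # --- QTL component ---------------------------------------------------
    if config.n_qtl > 0 and qtl_var_target > 0:
        base = founders if founders.sum() >= 10 else np.ones(n, dtype=bool)
        # QTL must segregate in the base population to carry variance
        base_p = genotypes.dosages[base].mean(axis=0) / 2.0
        base_maf = np.minimum(base_p, 1.0 - base_p)
        candidates = np.flatnonzero(base_maf >= config.min_qtl_maf)
        if candidates.size < config.n_qtl:
            raise ValueError(
                f"only {candidates.size} SNPs segregate at MAF >= "
                f"{config.min_qtl_maf} in the base population; cannot "
                f"place {config.n_qtl} QTL")
        # unsorted draw: fraction k belongs to a uniformly placed SNP
        # (sorting here would pin the first fraction to the lowest index)
        qtl_idx = rng.choice(candidates, size=config.n_qtl, replace=False)
        raw = rng.standard_normal(config.n_qtl)
        # per-QTL scaling so each contributes its requested variance share
        # in the founder (base) population
        effects = np.zeros(config.n_qtl)
        score = np.zeros(n)
        for k, j in enumerate(qtl_idx):
            z = genotypes.dosages[:, j]
            v = z[base].var(ddof=1)
            target_k = fractions[k] * config.var_a
            if v <= 0:
                effects[k] = 0.0  # monomorphic in base: no contribution
                continue
            effects[k] = raw[k] / abs(raw[k]) * np.sqrt(target_k / v) \
                if raw[k] != 0 else np.sqrt(target_k / v)
            score += z * effects[k]
        score -= score[base].mean()
        realized_qtl_var = score[base].var(ddof=1)
    else:
        qtl_idx = np.array([], dtype=int)
        effects = np.array([])
        score = np.zeros(n)
        realized_qtl_var = 0.0

    # --- polygenic remainder, transmitted down the pedigree --------------
    var_poly = max(config.var_a - qtl_var_target, 0.0)
    poly = np.zeros(n)
    for i in range(n):
        s, d = pedigree.sire[i], pedigree.dam[i]
        if s == UNKNOWN and d == UNKNOWN:
            poly[i] = rng.normal(0.0, np.sqrt(var_poly)) if var_poly else 0.0
        else:
            pa = poly[s] if s != UNKNOWN else 0.0
            pb = poly[d] if d != UNKNOWN else 0.0
            n_known = int(s != UNKNOWN) + int(d != UNKNOWN)
            mendel_var = var_poly * (1.0 - 0.25 * n_known)
            poly[i] = 0.5 * (pa + pb) + (
                rng.normal(0.0, np.sqrt(mendel_var)) if mendel_var else 0.0)
    tbv = score + poly

    # --- records ----------------------------------------------------------
    phenotyped = rng.random(n) < config.phenotyped_fraction
    if not phenotyped.any():
        phenotyped[0] = True
    n_rec = np.maximum(1, rng.poisson(config.records_per_animal,
                                      size=n)) * phenotyped
    ys_eff = (rng.normal(0.0, np.sqrt(config.var_yearseason),
                         size=config.n_yearseason)
              if config.var_yearseason > 0
              else np.zeros(config.n_yearseason))
    pe = (rng.normal(0.0, np.sqrt(config.var_pe), size=n)
          if config.var_pe > 0 else np.zeros(n))

    total = int(n_rec.sum())
    owner = np.repeat(np.arange(n), n_rec)
    starts = np.concatenate([[0], np.cumsum(n_rec)[:-1]])
    rec_no = np.arange(total) - np.repeat(starts, n_rec) + 1
    ys = rng.integers(config.n_yearseason, size=total)
    age = rng.uniform(*config.age_range_months, size=total)
    intv = rng.uniform(*config.intv_range_days, size=total)
    e = (rng.normal(0.0, np.sqrt(config.var_e), size=total)
         if config.var_e > 0 else np.zeros(total))
    y = (config.mu + ys_eff[ys] + config.beta_age * age
         + config.beta_intv * intv + tbv[owner] + pe[owner] + e)
    table = pd.DataFrame({
        "id": pedigree.ids[owner], "record": rec_no,
        "yearseason": np.char.add("ys", ys.astype(str)),
        "age": age, "intv": intv, "trait": y})

    total = config.var_a + config.var_pe + config.var_e
    realized_h2 = config.var_a / total if total > 0 else np.nan
    truth = SimTruth(true_breeding_values=tbv, qtl_snp_indices=qtl_idx,
                     qtl_effects=effects,
                     realized_h2=float(realized_h2),
                     yearseason_effects=ys_eff)
    return table, truth


def simulate_dataset(config: SimConfig):
    """Full bundle: pedigree (recent generations genotyped), genotypes,
    phenotypes and truth, all reproducible from ``config.seed``."""
    pedigree = simulate_pedigree(config)
    genotypes_all = drop_genotypes(pedigree, config)
    rng = np.random.default_rng(config.seed + 2)
    phen, truth = simulate_phenotypes(pedigree, genotypes_all, config, rng)
    n = pedigree.n
    n_geno = int(round(config.genotyped_fraction * n))
    mask = np.zeros(n, dtype=bool)
    mask[n - n_geno:] = True  # most recent animals are the genotyped ones
    pedigree.genotyped = mask
    genotypes = genotypes_all.subset(ind_mask=mask)
    return pedigree, genotypes, phen, truth


def recovery_study_config(seed: int) -> SimConfig:
    """Benchmark design for variance-component recovery.

    1,500 animals (250 founders, 5 discrete generations, litter size 2),
    ~5 records each, simulated at the log sperm-cell count components
    (var_a=0.05172, var_pe=0.03682, var_e=0.19380, h2 = 0.1832).  Only a
    token marker panel is generated — the study exercises pedigree
    AI-REML.
    """
    return SimConfig(n_founders=250, n_generations=5, litter_size=2,
                     n_chromosomes=2, chrom_length_bp=50_000_000,
                     n_snps=10, n_qtl=0, qtl_var_fractions=(),
                     var_a=0.05172, var_pe=0.03682, var_e=0.19380,
                     records_per_animal=5, genotyped_fraction=0.0,
                     seed=seed)


def detection_study_config(seed: int) -> SimConfig:
    """Benchmark design for single-QTL window mapping.

    A 5,000-SNP array on a 260 Mb genome (5 chromosomes; the SNP density
    of a 50K porcine array scaled down, ~650 windows of 0.4 Mb), dropped
    through 2,400 pedigree animals of which the most recent 1,000 are
    genotyped.  Haploblock structure comes from a 100-generation burn-in
    herd of effective size 100.  One common (founder MAF >= 0.2) QTL
    carries 5% of the additive variance; the remaining 95% is spread over
    300 small background QTLs so that, as in real data, the genetic
    variance resides on the genome.  Trait settings follow progressive
    motility: variances 0.00757/0.00248/0.03695 and ~23 records per
    animal.
    """
    n_bg = 300
    fractions = (0.05,) + tuple([0.95 / n_bg] * n_bg)
    return SimConfig(n_founders=400, n_generations=5, litter_size=2,
                     n_chromosomes=5, chrom_length_bp=52_000_000,
                     n_snps=5000, n_qtl=1 + n_bg,
                     qtl_var_fractions=fractions,
                     var_a=0.00757, var_pe=0.00248, var_e=0.03695,
                     records_per_animal=23, genotyped_fraction=1000 / 2400,
                     n_burnin_generations=100, burnin_pop_size=100,
                     min_qtl_maf=0.2, seed=seed)


def records_per_individual(n_records: int, n_individuals: int) -> int:
    """Average record count per individual, rounded to the nearest integer
    (e.g. 143,113 ejaculates over 2,693 boars -> 53)."""
    if n_individuals <= 0:
        raise ValueError("need at least one individual")
    return int(round(n_records / n_individuals))
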