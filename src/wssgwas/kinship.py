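"""Relationship matrices for single-step evaluation.

Implements the pedigree numerator relationship matrix A (tabular method),
its sparse inverse (Henderson's rules with Meuwissen–Luo inbreeding
coefficients), the genotyped submatrix A22, the (weighted) genomic
relationship matrix G = Z D Z' / sum(2 p_i (1 - p_i)) with centered dosage
coding, the blend G_w = w*G + (1-w)*A22, and the single-step inverse

    H^-1 = A^-1 + [[0, 0], [0, G_w^-1 - A22^-1]]

restricted to the genotyped block.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg as sla
import scipy.sparse as sp

__all__ = [
    "Pedigree",
    "GenotypeMatrix",
    "SnpWeightState",
    "a_matrix",
    "a_inverse",
    "inbreeding_coefficients",
    "a22",
    "g_matrix",
    "blend_gw",
    "h_inverse",
]

UNKNOWN = -1  # parent pointer for unknown sire/dam


@dataclass
class Pedigree:
    """Topologically ordered pedigree (parents precede offspring).

    Parameters
    ----------
    ids : array of animal identifiers, in processing order.
    sire, dam : integer arrays of parent *positions* in ``ids``
        (``-1`` when unknown).
    genotyped : boolean mask, True for animals with marker data.
    sex : optional array, 0 = male, 1 = female (simulation bookkeeping).
    """

    ids: np.ndarray
    sire: np.ndarray
    dam: np.ndarray
    genotyped: np.ndarray = None
    sex: np.ndarray = None

    def __post_init__(self):
        self.ids = np.asarray(self.ids)
        self.sire = np.asarray(self.sire, dtype=np.int64)
        self.dam = np.asarray(self.dam, dtype=np.int64)
        n = len(self.ids)
        if self.genotyped is None:
            self.genotyped = np.zeros(n, dtype=bool)
        self.genotyped = np.asarray(self.genotyped, dtype=bool)
        if len(self.sire) != n or len(self.dam) != n:
            raise ValueError("sire/dam arrays must match ids length")
        idx = np.arange(n)
        for parent in (self.sire, self.dam):
            bad = (parent >= idx) & (parent != UNKNOWN)
            if bad.any():
                raise ValueError(
                    "pedigree is not topologically ordered: animals at "
                    f"positions {idx[bad][:5].tolist()} have a parent that "
                    "does not precede them"
                )
            if ((parent < UNKNOWN) | (parent >= n)).any():
                raise ValueError("parent index out of range")

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def is_founder(self) -> np.ndarray:
        return (self.sire == UNKNOWN) & (self.dam == UNKNOWN)

    @property
    def genotyped_indices(self) -> np.ndarray:
        return np.flatnonzero(self.genotyped)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, id_col: str = "id",
                       sire_col: str = "sire", dam_col: str = "dam",
                       unknown=(0, "0", "", None)) -> "Pedigree":
        """Build from 3-column records (animal, sire, dam); 0/blank = unknown.

        Rows are re-sorted topologically if needed (parents before
        offspring); raises on cycles.
        """
        ids = df[id_col].to_numpy()
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate animal ids in pedigree")
        pos = {v: i for i, v in enumerate(ids)}
        unknown_set = set(unknown)

        def lookup(col):
            out = np.empty(len(df), dtype=np.int64)
            for i, v in enumerate(df[col].to_numpy()):
                if v in unknown_set or (isinstance(v, float) and np.isnan(v)):
                    out[i] = UNKNOWN
                else:
                    if v not in pos:
                        raise ValueError(f"parent id {v!r} not in pedigree")
                    out[i] = pos[v]
            return out

        sire, dam = lookup(sire_col), lookup(dam_col)
        order = _topological_order(sire, dam)
        inv = np.empty_like(order)
        inv[order] = np.arange(len(order))
        remap = np.where(sire == UNKNOWN, UNKNOWN, inv[np.maximum(sire, 0)])
        remap_d = np.where(dam == UNKNOWN, UNKNOWN, inv[np.maximum(dam, 0)])
        return cls(ids=ids[order], sire=remap[order], dam=remap_d[order])

    def to_dataframe(self) -> pd.DataFrame:
        def name(parent):
            return [self.ids[p] if p != UNKNOWN else 0 for p in parent]

        return pd.DataFrame(
            {"id": self.ids, "sire": name(self.sire), "dam": name(self.dam)})


def _topological_order(sire: np.ndarray, dam: np.ndarray) -> np.ndarray:
    """Kahn ordering so that parents precede offspring; raises on cycles."""
    n = len(sire)
    children: list[list[int]] = [[] for _ in range(n)]
    indeg = np.zeros(n, dtype=np.int64)
    for i in range(n):
        for p in (sire[i], dam[i]):
            if p != UNKNOWN:
                children[p].append(i)
                indeg[i] += 1
    queue = [i for i in range(n) if indeg[i] == 0]
    order = []
    while queue:
        nxt = []
        for i in queue:
            order.append(i)
            for c in children[i]:
                indeg[c] -= 1
                if indeg[c] == 0:
                    nxt.append(c)
        queue = nxt
    if len(order) != n:
        raise ValueError("pedigree contains a cycle (an animal is its own "
                         "ancestor)")
    return np.asarray(order)


def save_triplet(matrix, path) -> None:
    """Persist a (sparse or dense) relationship matrix as gzipped
    row/col/value text; only nonzeros are written."""
    import gzip

    coo = sp.coo_matrix(matrix)
    with gzip.open(path, "wt") as fh:
        fh.write(f"# shape {coo.shape[0]} {coo.shape[1]}\n")
        for r, c, v in zip(coo.row, coo.col, coo.data):
            fh.write(f"{r}\t{c}\t{float(v)!r}\n")


def load_triplet(path) -> sp.csr_matrix:
    import gzip

    with gzip.open(path, "rt") as fh:
        header = fh.readline().split()
        shape = (int(header[2]), int(header[3]))
        rows, cols, vals = [], [], []
        for line in fh:
            r, c, v = line.split("\t")
            rows.append(int(r))
            cols.append(int(c))
            vals.append(float(v))
    return sp.csr_matrix(sp.coo_matrix((vals, (rows, cols)), shape=shape))


def a_matrix(pedigree: Pedigree) -> np.ndarray:
    """Numerator relationship matrix by the tabular method.

    ``A[i, i] = 1 + F_i`` with F the inbreeding coefficient; founders have
    diagonal 1.  O(n^2) memory — intended for pedigrees up to a few
    thousand animals.
    """
    n = pedigree.n
    A = np.zeros((n, n))
    s, d = pedigree.sire, pedigree.dam
    for i in range(n):
        row = np.zeros(i)
        if s[i] != UNKNOWN:
            row += 0.5 * A[s[i], :i]
        if d[i] != UNKNOWN:
            row += 0.5 * A[d[i], :i]
        A[i, :i] = row
        A[:i, i] = row
        aii = 1.0
        if s[i] != UNKNOWN and d[i] != UNKNOWN:
            aii += 0.5 * A[s[i], d[i]]
        A[i, i] = aii
    return A


def inbreeding_coefficients(pedigree: Pedigree) -> np.ndarray:
    """Inbreeding coefficients F by the Meuwissen–Luo recursion.

    Uses the convention F = -1 for an unknown parent so that the
    within-family variance is d_i = 0.5 - 0.25 (F_s + F_d): 1 for founders,
    0.75 - 0.25 F_s when one parent is known.
    """
    n = pedigree.n
    s, d = pedigree.sire, pedigree.dam
    F = np.zeros(n)

    def f_of(p):
        return F[p] if p != UNKNOWN else -1.0

    for i in range(n):
        if s[i] == UNKNOWN or d[i] == UNKNOWN:
            F[i] = 0.0
            continue
        # accumulate L coefficients down the ancestor lists of i
        L = np.zeros(i + 1)
        L[i] = 1.0
        aii = 0.0
        for j in range(i, -1, -1):
            lj = L[j]
            if lj == 0.0:
                continue
            if s[j] != UNKNOWN:
                L[s[j]] += 0.5 * lj
            if d[j] != UNKNOWN:
                L[d[j]] += 0.5 * lj
            dj = 0.5 - 0.25 * (f_of(s[j]) + f_of(d[j]))
            aii += lj * lj * dj
        F[i] = aii - 1.0
    return F


def a_inverse(pedigree: Pedigree, inbreeding: bool = True) -> sp.csr_matrix:
    """Sparse A^-1 via Henderson's rules with inbreeding accounted.

    Matches ``inv(a_matrix(p))`` to numerical tolerance; O(n) nonzeros.
    """
    n = pedigree.n
    s, d = pedigree.sire, pedigree.dam
    F = inbreeding_coefficients(pedigree) if inbreeding else np.zeros(n)

    rows, cols, vals = [], [], []

    def add(r, c, v):
        rows.append(r)
        cols.append(c)
        vals.append(v)

    for i in range(n):
        fs = F[s[i]] if s[i] != UNKNOWN else -1.0
        fd = F[d[i]] if d[i] != UNKNOWN else -1.0
        b = 1.0 / (0.5 - 0.25 * (fs + fd))  # inverse Mendelian-sampling var
        add(i, i, b)
        for p in (s[i], d[i]):
            if p != UNKNOWN:
                add(i, p, -0.5 * b)
                add(p, i, -0.5 * b)
        for p in (s[i], d[i]):
            if p != UNKNOWN:
                for q in (s[i], d[i]):
                    if q != UNKNOWN:
                        add(p, q, 0.25 * b)
    return sp.csr_matrix(
        sp.coo_matrix((vals, (rows, cols)), shape=(n, n)))


def a22(pedigree: Pedigree) -> np.ndarray:
    """Pedigree relationships among the genotyped animals (submatrix of A)."""
    idx = pedigree.genotyped_indices
    if idx.size == 0:
        raise ValueError("pedigree has no genotyped animals")
    return a_matrix(pedigree)[np.ix_(idx, idx)]


@dataclass
class GenotypeMatrix:
    """Dosage matrix (individuals x SNPs) with its genome map.

    ``dosages`` holds counts of the B allele in {0, 1, 2}; missing calls are
    ``nan`` until imputation.  The map (``chrom``, ``pos``) must be sorted
    by (chromosome, bp).
    """

    dosages: np.ndarray
    ids: np.ndarray
    chrom: np.ndarray
    pos: np.ndarray
    snp_ids: np.ndarray = None

    def __post_init__(self):
        self.dosages = np.asarray(self.dosages, dtype=float)
        self.ids = np.asarray(self.ids)
        self.chrom = np.asarray(self.chrom)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        if self.snp_ids is None:
            self.snp_ids = np.array(
                [f"snp{c}_{p}" for c, p in zip(self.chrom, self.pos)])
        self.snp_ids = np.asarray(self.snp_ids)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be 2-D (individuals x SNPs)")
        if self.dosages.shape != (len(self.ids), len(self.pos)):
            raise ValueError("dosage shape inconsistent with ids/map")
        with np.errstate(invalid="ignore"):
            valid = np.isnan(self.dosages) | np.isin(self.dosages, (0, 1, 2))
        if not valid.all():
            # imputed matrices may carry fractional mean dosages in [0, 2]
            if ((self.dosages < 0) | (self.dosages > 2)).any():
                raise ValueError("dosages must lie in [0, 2] or be nan")

    @property
    def n_ind(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    @property
    def snp_map(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"snp": self.snp_ids, "chrom": self.chrom, "pos": self.pos})

    def allele_freq(self) -> np.ndarray:
        """Frequency of the counted (B) allele from non-missing calls."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.dosages, axis=0) / 2.0

    def ind_call_rate(self) -> np.ndarray:
        return 1.0 - np.mean(np.isnan(self.dosages), axis=1)

    def snp_call_rate(self) -> np.ndarray:
        return 1.0 - np.mean(np.isnan(self.dosages), axis=0)

    def subset(self, ind_mask=None, snp_mask=None) -> "GenotypeMatrix":
        g = self.dosages
        ids = self.ids
        if ind_mask is not None:
            g = g[ind_mask]
            ids = ids[ind_mask]
        chrom, pos, snp_ids = self.chrom, self.pos, self.snp_ids
        if snp_mask is not None:
            g = g[:, snp_mask]
            chrom, pos, snp_ids = chrom[snp_mask], pos[snp_mask], snp_ids[snp_mask]
        return GenotypeMatrix(g.copy(), ids.copy(), chrom.copy(), pos.copy(),
                              snp_ids.copy())

    def centered(self, freqs: np.ndarray | None = None) -> np.ndarray:
        """Dosages centered as z = dosage - 2p (VanRaden coding)."""
        p = self.allele_freq() if freqs is None else np.asarray(freqs)
        return self.dosages - 2.0 * p


@dataclass
class SnpWeightState:
    """Diagonal SNP weights D of the weighted genomic relationship matrix.

    The trace is kept equal to the SNP count m across re-weighting
    iterations so total genetic variance is preserved.
    """

    weights: np.ndarray
    iteration: int = 1

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float)
        if (self.weights < 0).any():
            raise ValueError("SNP weights must be non-negative")

    @property
    def m(self) -> int:
        return self.weights.size

    @property
    def trace(self) -> float:
        return float(self.weights.sum())

    @classmethod
    def identity(cls, m: int) -> "SnpWeightState":
        return cls(np.ones(m), iteration=1)


def scaling_factor(freqs: np.ndarray) -> float:
    """lambda = 1 / sum(2 p_i (1 - p_i)), the VanRaden denominator."""
    freqs = np.asarray(freqs, dtype=float)
    denom = float(np.sum(2.0 * freqs * (1.0 - freqs)))
    if denom <= 0:
        raise ValueError("all SNPs monomorphic: scaling factor undefined")
    return 1.0 / denom


def g_matrix(genotypes: GenotypeMatrix,
             weights: SnpWeightState | np.ndarray | None = None,
             freqs: np.ndarray | None = None) -> np.ndarray:
    """Weighted genomic relationship matrix G = Z D Z' / sum 2p(1-p).

    Z is the centered dosage matrix; D the diagonal SNP weights (identity
    by default).  Monomorphic SNPs (p in {0, 1}) are rejected: they carry
    no information and corrupt the denominator.
    """
    if np.isnan(genotypes.dosages).any():
        raise ValueError("missing dosages: impute before building G")
    p = genotypes.allele_freq() if freqs is None else np.asarray(freqs)
    if ((p <= 0) | (p >= 1)).any():
        bad = np.flatnonzero((p <= 0) | (p >= 1))
        raise ValueError(
            f"monomorphic SNPs at indices {bad[:5].tolist()} — run MAF QC "
            "before building G")
    d = weights.weights if isinstance(weights, SnpWeightState) else weights
    Zc = genotypes.centered(p)
    lam = scaling_factor(p)
    if d is None:
        G = (Zc @ Zc.T) * lam
    else:
        d = np.asarray(d, dtype=float)
        if d.size != genotypes.n_snps:
            raise ValueError("weight vector length must equal SNP count")
        G = ((Zc * d) @ Zc.T) * lam
    return 0.5 * (G + G.T)  # enforce exact symmetry


def blend_gw(G: np.ndarray, A22: np.ndarray, g_share: float = 0.9) -> np.ndarray:
    """Blend G_w = g_share * G + (1 - g_share) * A22.

    The default 0.9/0.1 blend scales genomic information to be compatible
    with the pedigree and guarantees invertibility when A22 is full rank.
    """
    G = np.asarray(G)
    A22 = np.asarray(A22)
    if G.shape != A22.shape:
        raise ValueError(f"shape mismatch: G {G.shape} vs A22 {A22.shape}")
    if not (0.0 < g_share <= 1.0):
        raise ValueError("g_share must be in (0, 1]")
    return g_share * G + (1.0 - g_share) * A22


def h_inverse(a_inv: sp.spmatrix, A22: np.ndarray, G_w: np.ndarray,
              pedigree: Pedigree) -> sp.csr_matrix:
    """Single-step inverse H^-1 = A^-1 + genotyped-block (G_w^-1 - A22^-1).

    Returns a sparse matrix over the full pedigree; with zero genotyped
    animals this is exactly A^-1.
    """
    idx = pedigree.genotyped_indices
    H = sp.csr_matrix(a_inv, copy=True)
    if idx.size == 0:
        return H
    if G_w.shape != (idx.size, idx.size) or A22.shape != G_w.shape:
        raise ValueError("G_w / A22 must be square over the genotyped set")
    try:
        cf = sla.cho_factor(G_w)
        Gw_inv = sla.cho_solve(cf, np.eye(idx.size))
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "G_w is singular; blend with A22 (g_share < 1) before "
            "inverting") from exc
    A22_inv = sla.cho_solve(sla.cho_factor(A22), np.eye(idx.size))
    corr = Gw_inv - A22_inv
    corr = 0.5 * (corr + corr.T)
    block = sp.coo_matrix(
        (corr.ravel(),
         (np.repeat(idx, idx.size), np.tile(idx, idx.size))),
        shape=H.shape)
    return sp.csr_matrix(H + block)
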