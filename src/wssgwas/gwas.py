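"""Iterative SNP weighting (weighted single-step GWAS).

The loop (default 3 iterations) alternates between GEBV estimation and
marker-effect back-solving:

1. t = 1, D = I, lambda = 1 / sum(2 p_i (1 - p_i))  (lambda fixed here)
2. GEBVs a_hat by ssGBLUP with H^-1 built from the blended
   G_w = 0.9 * G_(t) + 0.1 * A22
3. marker effects g_hat = lambda * D_(t) * Z' * G_(t)^-1 * a_hat
   (unblended weighted G, genotyped animals only)
4. raw weights d_i = g_hat_i^2 * 2 p_i (1 - p_i)
5. renormalize so trace(D) = m (total genetic variance preserved)
6. rebuild G with the new D, loop to 2.

Variance components are estimated once, by pedigree AI-REML, before the
loop and held fixed; marker effects from the final iteration feed the
window variance scan.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg as sla
import scipy.sparse as sp

from .kinship import (GenotypeMatrix, Pedigree, SnpWeightState, a22,
                      a_inverse, blend_gw, g_matrix, h_inverse,
                      scaling_factor)
from .mme import (ModelSpec, RepeatabilityModel, Solutions,
                  VarianceComponents, ai_reml)
from . import windows as _windows

__all__ = [
    "IterationTrace",
    "backsolve_snp_effects",
    "update_weights",
    "normalize_weights",
    "run_wssgwas",
    "WssGwas",
    "WssGwasResults",
]


@dataclass
class IterationRecord:
    iteration: int
    weight_min: float
    weight_max: float
    weight_trace: float
    gebv_corr_prev: float
    marker_effects: np.ndarray
    weights: np.ndarray
    gebv: pd.Series


@dataclass
class IterationTrace:
    """Per-iteration log of the weighting loop."""

    records: list = field(default_factory=list)

    def append(self, rec: IterationRecord) -> None:
        self.records.append(rec)

    def __len__(self):
        return len(self.records)

    def __getitem__(self, i):
        return self.records[i]

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame([
            {"iteration": r.iteration, "weight_min": r.weight_min,
             "weight_max": r.weight_max, "weight_trace": r.weight_trace,
             "gebv_corr_prev": r.gebv_corr_prev}
            for r in self.records])


def backsolve_snp_effects(gebv_genotyped: np.ndarray,
                          genotypes: GenotypeMatrix,
                          weights: SnpWeightState | np.ndarray,
                          lam: float | None = None,
                          freqs: np.ndarray | None = None,
                          ridge: float = 0.0,
                          G: np.ndarray | None = None) -> np.ndarray:
    """Marker effects g_hat = lambda * D * Z' * G^-1 * a_hat.

    ``gebv_genotyped`` must be restricted to the genotyped animals; G is
    the *unblended* weighted genomic relationship matrix.  When allele
    frequencies are estimated from the genotyped animals themselves, G is
    rank-deficient by construction (centered dosages sum to zero, so
    G 1 = 0) and the Moore–Penrose solution G+ a_hat is used; it back-
    solves the component of a_hat in the row space of the markers (the
    arbitrary GEBV mean lies in the null space).  A ridge epsilon on the
    diagonal is available as an alternative (off by default).

    Passing ``G`` overrides the relationship matrix inverted on the right
    hand side (e.g. the blended G_w actually used for GEBV estimation,
    which is what the weighting pipeline does — see ``run_wssgwas``);
    the left factor lambda * D * Z' is always the weighted marker map.
    """
    d = (weights.weights if isinstance(weights, SnpWeightState)
         else np.asarray(weights, dtype=float))
    p = genotypes.allele_freq() if freqs is None else np.asarray(freqs)
    if lam is None:
        lam = scaling_factor(p)
    a_hat = np.asarray(gebv_genotyped, dtype=float)
    if a_hat.size != genotypes.n_ind:
        raise ValueError("GEBV vector must match the genotyped animals")
    Zc = genotypes.centered(p)
    if G is None:
        G = ((Zc * d) @ Zc.T) * lam
    if ridge:
        G = G + np.eye(G.shape[0]) * ridge
    try:
        x = sla.cho_solve(sla.cho_factor(G), a_hat)
    except np.linalg.LinAlgError:
        x = np.linalg.pinv(G, hermitian=True) @ a_hat
    return lam * d * (Zc.T @ x)


def update_weights(marker_effects: np.ndarray,
                   freqs: np.ndarray) -> np.ndarray:
    """Raw weights d_i = g_hat_i^2 * 2 p_i (1 - p_i) (variance contributed
    by SNP i)."""
    g = np.asarray(marker_effects, dtype=float)
    p = np.asarray(freqs, dtype=float)
    if g.shape != p.shape:
        raise ValueError("marker effects and frequencies must align")
    return g ** 2 * 2.0 * p * (1.0 - p)


def normalize_weights(raw: np.ndarray, iteration: int = 1) -> SnpWeightState:
    """Rescale so trace(D) = m = trace(I), preserving proportions."""
    raw = np.asarray(raw, dtype=float)
    total = raw.sum()
    if total <= 0:
        raise ValueError("all-zero SNP weights: marker effects degenerate")
    return SnpWeightState(raw * (raw.size / total), iteration=iteration)


def run_wssgwas(pedigree: Pedigree, genotypes: GenotypeMatrix,
                records: pd.DataFrame, spec: ModelSpec,
                var: VarianceComponents, n_iter: int = 3,
                g_share: float = 0.9, solver: str = "auto",
                ridge: float = 0.0, backsolve_blended: bool = True):
    """Run the full weighting loop.

    Returns ``(trace, marker_effects, weights)`` where the marker effects
    and weights are those of the final iteration.  ``pedigree.genotyped``
    must mark exactly the rows of ``genotypes`` (same order).

    By default the back-solve inverts the blended G_w — the matrix the
    GEBVs were actually estimated with.  The unweighted tail of G's
    spectrum is lifted by the pedigree share, which keeps the solve
    stable once the weights concentrate; ``backsolve_blended=False``
    inverts the raw weighted G instead (the textbook step formula),
    which is only advisable on well-conditioned fixtures.
    """
    idx = pedigree.genotyped_indices
    if idx.size != genotypes.n_ind:
        raise ValueError("genotyped mask size does not match genotype matrix")
    if n_iter < 1:
        raise ValueError("need at least one iteration")
    p = genotypes.allele_freq()
    lam = scaling_factor(p)  # fixed at step 1, reused across iterations
    A_inv = a_inverse(pedigree)
    A22 = a22(pedigree)
    state = SnpWeightState.identity(genotypes.n_snps)
    trace = IterationTrace()
    prev_gebv = None
    g_hat = None
    for t in range(1, n_iter + 1):
        G_t = g_matrix(genotypes, state, freqs=p)
        G_w = blend_gw(G_t, A22, g_share=g_share)
        H_inv = h_inverse(A_inv, A22, G_w, pedigree)
        model = RepeatabilityModel(records, pedigree,
                                   relationship_inv=H_inv, spec=spec)
        sol = model.solve(var, solver=solver)
        gebv_g = sol.gebv.to_numpy()[idx]
        g_hat = backsolve_snp_effects(
            gebv_g, genotypes, state, lam=lam, freqs=p, ridge=ridge,
            G=G_w if backsolve_blended else None)
        corr = (float(np.corrcoef(prev_gebv, sol.gebv.to_numpy())[0, 1])
                if prev_gebv is not None else np.nan)
        trace.append(IterationRecord(
            iteration=t, weight_min=float(state.weights.min()),
            weight_max=float(state.weights.max()),
            weight_trace=state.trace, gebv_corr_prev=corr,
            marker_effects=g_hat.copy(), weights=state.weights.copy(),
            gebv=sol.gebv))
        prev_gebv = sol.gebv.to_numpy()
        if t < n_iter:
            state = normalize_weights(update_weights(g_hat, p),
                                      iteration=t + 1)
    return trace, g_hat, state


class WssGwas:
    """Weighted single-step GWAS bound to pedigree + genotypes + records.

    ``fit()`` estimates variance components by pedigree AI-REML (unless
    supplied), runs the weighting loop, and returns a results object with
    the iteration trace, final marker effects, and window scan methods.
    """

    def __init__(self, records: pd.DataFrame, pedigree: Pedigree,
                 genotypes: GenotypeMatrix, spec: ModelSpec | None = None,
                 **spec_kwargs):
        self.records = records
        self.pedigree = pedigree
        self.genotypes = genotypes
        self.spec = spec or ModelSpec(**spec_kwargs)

    def fit(self, var: VarianceComponents | None = None, n_iter: int = 3,
            g_share: float = 0.9, solver: str = "auto",
            backsolve_blended: bool = True,
            **reml_kwargs) -> "WssGwasResults":
        if var is None:
            var = ai_reml(self.records, self.spec,
                          a_inverse(self.pedigree), self.pedigree.ids,
                          **reml_kwargs)
        trace, g_hat, weights = run_wssgwas(
            self.pedigree, self.genotypes, self.records, self.spec, var,
            n_iter=n_iter, g_share=g_share, solver=solver,
            backsolve_blended=backsolve_blended)
        return WssGwasResults(self, var, trace, g_hat, weights)


class WssGwasResults:
    """Fitted wssGWAS: marker effects, weights, GEBVs and window scans."""

    def __init__(self, model: WssGwas, var: VarianceComponents,
                 trace: IterationTrace, marker_effects: np.ndarray,
                 weights: SnpWeightState):
        self.model = model
        self.varcomp = var
        self.trace = trace
        self.marker_effects = marker_effects
        self.weights = weights

    @property
    def gebv(self) -> pd.Series:
        return self.trace[-1].gebv

    def marker_frame(self) -> pd.DataFrame:
        g = self.model.genotypes
        return pd.DataFrame({
            "snp": g.snp_ids, "chrom": g.chrom, "pos": g.pos,
            "effect": self.marker_effects, "weight": self.weights.weights})

    def window_scan(self, size_bp: int = 400_000) -> pd.DataFrame:
        """Percent of additive variance explained per 0.4 Mb window."""
        wins = _windows.make_windows(self.model.genotypes.snp_map,
                                     size_bp=size_bp)
        return _windows.scan(wins, self.model.genotypes,
                             self.marker_effects, self.varcomp.var_a)

    def summary(self, threshold_pct: float = 1.0, k_top: int = 3) -> str:
        res = self.window_scan()
        selected = _windows.select_windows(res, threshold_pct)
        top = _windows.top_regions(res, k=k_top)
        v = self.varcomp
        lines = [
            "Weighted single-step GWAS",
            "=" * 50,
            f"{'SNPs':<28}{self.model.genotypes.n_snps:>10}",
            f"{'genotyped animals':<28}{self.model.genotypes.n_ind:>10}",
            f"{'iterations':<28}{len(self.trace):>10}",
            f"{'h2':<28}{v.h2:>10.4f}",
            f"{'windows':<28}{len(res):>10}",
            f"{'selected (> {0}%)'.format(threshold_pct):<28}"
            f"{len(selected):>10}",
            f"{'variance in selected (%)':<28}"
            f"{selected['pct_var'].sum():>10.2f}",
            "-" * 50,
            "top regions (midpoint +- 0.4 Mb):",
        ]
        for _, row in top.iterrows():
            lines.append(
                f"  chr{row['chrom']} {row['region_start'] / 1e6:.2f}-"
                f"{row['region_end'] / 1e6:.2f} Mb  "
                f"{row['pct_var']:.2f}% ({row['n_snps']} SNPs)")
        return "\n".join(lines)

    def plot_manhattan(self, ax=None, size_bp: int = 400_000,
                       threshold_pct: float = 1.0):
        """Window-level Manhattan-style plot (x = genome position,
        y = % variance explained)."""
        import matplotlib.pyplot as plt

        res = self.window_scan(size_bp=size_bp)
        if ax is None:
            _, ax = plt.subplots(figsize=(9, 3))
        offset = 0
        for i, (chrom, grp) in enumerate(res.groupby("chrom", sort=False)):
            x = (grp["start"] + grp["end"]) / 2 + offset
            ax.scatter(x, grp["pct_var"], s=8,
                       color="C0" if i % 2 == 0 else "C1")
            offset += grp["end"].max()
        ax.axhline(threshold_pct, color="red", ls="--", lw=0.8)
        ax.set_xlabel("genome position (bp, concatenated)")
        ax.set_ylabel("% genetic variance")
        return ax
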