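"""Genomic window variance analysis.

Partitions each chromosome into fixed non-overlapping bins (default
0.4 Mb, anchored at position 0), computes the share of additive genetic
variance explained by each window as

    Var(sum_j z_ij * g_hat_j) / sigma2_a * 100%

(sample variance across genotyped individuals, centered dosage coding),
then applies the selection rules: windows explaining > 1% are candidate
QTL regions, consecutive selected windows with midpoints < 0.4 Mb apart
merge, and the top-k windows are extended by 0.4 Mb on both sides of
their midpoints.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .kinship import GenotypeMatrix

__all__ = [
    "make_windows",
    "window_variance",
    "scan",
    "expected_window_share",
    "select_windows",
    "merge_windows",
    "top_regions",
]

WINDOW_BP = 400_000


def make_windows(snp_map: pd.DataFrame, size_bp: int = WINDOW_BP
                 ) -> pd.DataFrame:
    """Assign every SNP to a fixed-size bin; empty bins are dropped.

    ``snp_map`` needs columns ``chrom`` and ``pos``, sorted by
    (chromosome, bp).  Returns one row per non-empty window with
    half-open [start, end) coordinates clipped at the last SNP's bin and
    the member SNP indices (positions in the map).
    """
    chrom = snp_map["chrom"].to_numpy()
    pos = snp_map["pos"].to_numpy()
    for c in pd.unique(chrom):
        p = pos[chrom == c]
        if (np.diff(p) < 0).any():
            raise ValueError(f"map not sorted by position on chromosome {c}")
    bin_id = pos // size_bp
    rows = []
    order = np.arange(len(pos))
    df = pd.DataFrame({"chrom": chrom, "bin": bin_id, "idx": order,
                       "pos": pos})
    for (c, b), grp in df.groupby(["chrom", "bin"], sort=False):
        start = int(b) * size_bp
        rows.append({
            "chrom": c, "start": start, "end": start + size_bp,
            "midpoint": start + size_bp / 2,
            "n_snps": len(grp), "snp_indices": grp["idx"].to_numpy()})
    wins = pd.DataFrame(rows)
    return wins.reset_index(drop=True)


def window_variance(snp_indices: np.ndarray, genotypes: GenotypeMatrix,
                    marker_effects: np.ndarray, var_a: float,
                    freqs: np.ndarray | None = None) -> float:
    """% of sigma2_a explained by the window's SNPs.

    Empirical (n-1 denominator) variance across genotyped individuals of
    the window genetic score sum_j z_ij g_j with centered coding.
    """
    idx = np.asarray(snp_indices)
    if idx.size == 0:
        return 0.0
    if var_a <= 0:
        raise ValueError("sigma2_a must be positive")
    Zc = genotypes.centered(freqs)[:, idx]
    score = Zc @ np.asarray(marker_effects)[idx]
    return float(score.var(ddof=1) / var_a * 100.0)


def scan(windows: pd.DataFrame, genotypes: GenotypeMatrix,
         marker_effects: np.ndarray, var_a: float) -> pd.DataFrame:
    """Window variance for every window + rank (ties broken by genome
    order) and the > 1% selection flag left unset until selection."""
    freqs = genotypes.allele_freq()
    pct = [window_variance(w, genotypes, marker_effects, var_a, freqs)
           for w in windows["snp_indices"]]
    out = windows.copy()
    out["pct_var"] = pct
    order = np.lexsort((np.arange(len(out)), -out["pct_var"].to_numpy()))
    rank = np.empty(len(out), dtype=int)
    rank[order] = np.arange(1, len(out) + 1)
    out["rank"] = rank
    return out


def expected_window_share(n_windows: int) -> float:
    """Uniform expectation: 100% / number of windows (e.g. 3707 windows
    -> 0.027% per window)."""
    if n_windows <= 0:
        raise ValueError("need at least one window")
    return 100.0 / n_windows


def select_windows(results: pd.DataFrame,
                   threshold_pct: float = 1.0) -> pd.DataFrame:
    """Candidate QTL windows: strictly more than ``threshold_pct`` % of
    the genetic variance."""
    out = results.copy()
    out["selected"] = out["pct_var"] > threshold_pct
    return out[out["selected"]].reset_index(drop=True)


def merge_windows(selected: pd.DataFrame,
                  max_midpoint_gap_bp: int = WINDOW_BP,
                  inclusive: bool = False) -> pd.DataFrame:
    """Chain-merge selected windows whose midpoints are < 0.4 Mb apart.

    Strict inequality by default (adjacent full windows, midpoints exactly
    0.4 Mb apart, do NOT merge); ``inclusive=True`` switches to <=.
    Merged region spans min(start)..max(end); pct is the sum of member
    windows with the per-window detail kept in ``members``.
    """
    if selected.empty:
        return pd.DataFrame(columns=["chrom", "start", "end", "n_snps",
                                     "pct_var", "n_windows", "members"])
    sel = selected.sort_values(["chrom", "start"],
                               kind="stable").reset_index(drop=True)
    rows = []
    cur = None
    for _, w in sel.iterrows():
        gap = (w["midpoint"] - cur["last_mid"]) if cur is not None else None
        close = (gap <= max_midpoint_gap_bp if inclusive
                 else gap < max_midpoint_gap_bp) if gap is not None else False
        if cur is not None and w["chrom"] == cur["chrom"] and close:
            cur["end"] = max(cur["end"], w["end"])
            cur["n_snps"] += w["n_snps"]
            cur["pct_var"] += w["pct_var"]
            cur["n_windows"] += 1
            cur["members"].append(w["pct_var"])
            cur["last_mid"] = w["midpoint"]
        else:
            if cur is not None:
                rows.append(cur)
            cur = {"chrom": w["chrom"], "start": w["start"], "end": w["end"],
                   "n_snps": int(w["n_snps"]), "pct_var": float(w["pct_var"]),
                   "n_windows": 1, "members": [float(w["pct_var"])],
                   "last_mid": w["midpoint"]}
    rows.append(cur)
    out = pd.DataFrame(rows).drop(columns="last_mid")
    return out


def write_bed(regions: pd.DataFrame, path,
              start_col: str = "start", end_col: str = "end") -> None:
    """Write regions as BED (0-based half-open): chrom, start, end, name,
    score = % variance scaled to an integer 0-1000 (capped)."""
    with open(path, "w") as fh:
        for i, row in regions.iterrows():
            score = min(1000, int(round(10 * row["pct_var"])))
            fh.write(f"{row['chrom']}\t{int(row[start_col])}\t"
                     f"{int(row[end_col])}\twin{i}\t{score}\n")


def top_regions(results: pd.DataFrame, k: int = 3,
                flank_bp: int = WINDOW_BP,
                chrom_ends: dict | None = None) -> pd.DataFrame:
    """Top-k windows by % variance, extended to midpoint +- 0.4 Mb.

    The extended span (0.8 Mb total) is reported alongside the window's
    own pct_var; regions are clipped at 0 and, when ``chrom_ends`` is
    given, at the chromosome end.
    """
    import warnings

    if k <= 0:
        return results.head(0).assign(region_start=pd.Series(dtype=int),
                                      region_end=pd.Series(dtype=int))
    if k > len(results):
        warnings.warn(f"asked for top {k} of {len(results)} windows; "
                      "returning all")
        k = len(results)
    top = results.sort_values("rank", kind="stable").head(k).copy()
    start = np.maximum(top["midpoint"] - flank_bp, 0).astype(int)
    end = (top["midpoint"] + flank_bp).astype(int)
    if chrom_ends is not None:
        end = np.minimum(
            end, top["chrom"].map(chrom_ends).to_numpy(dtype=int))
    top["region_start"] = start
    top["region_end"] = end
    return top.reset_index(drop=True)
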