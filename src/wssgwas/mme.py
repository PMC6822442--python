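"""Repeatability animal model: mixed-model equations and AI-REML.

The model for record r of animal i is

    y_ir = yearseason + beta_age * Age_ir + beta_intv * Intv_ir
           + a_i + p_i + e_ir,

with a ~ N(0, K sigma2_a) for a relationship matrix K (pedigree A or the
single-step H), p ~ N(0, I sigma2_pe) the permanent-environment effect and
e ~ N(0, I sigma2_e).  Henderson's mixed-model equations are

    [ X'X        X'Z              X'W        ] [b]   [X'y]
    [ Z'X   Z'Z + K^-1 k_a        Z'W        ] [a] = [Z'y]
    [ W'X        W'Z         W'W + I k_p     ] [p]   [W'y]

with variance ratios k_a = sigma2_e/sigma2_a, k_p = sigma2_e/sigma2_pe.
Variance components are estimated by average-information REML with EM
fallback whenever a Newton step leaves the parameter space; standard
errors come from the inverse AI matrix at convergence.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg as sla
import scipy.sparse as sp
from scipy.linalg.lapack import dpotrf, dpotri

from .kinship import Pedigree, a_inverse

__all__ = [
    "ModelSpec",
    "VarianceComponents",
    "Solutions",
    "MixedModelSystem",
    "build_design",
    "build_mme",
    "solve_mme",
    "ai_reml",
    "heritability",
    "repeatability",
    "RepeatabilityModel",
    "RemlResults",
]


@dataclass
class ModelSpec:
    """Column mapping and effect structure of the repeatability model.

    Set ``yearseason_col``/``age_col``/``intv_col`` to None to drop that
    term; ``permanent_env=False`` drops the p block (only valid when no
    animal repeats records or repeats are to be absorbed by e).
    """

    trait: str = "trait"
    animal_col: str = "id"
    yearseason_col: str | None = "yearseason"
    age_col: str | None = "age"
    intv_col: str | None = "intv"
    permanent_env: bool = True
    transform: str | None = None  # "log" for count-like traits


@dataclass
class VarianceComponents:
    var_a: float
    var_pe: float
    var_e: float
    se_a: float = np.nan
    se_pe: float = np.nan
    se_e: float = np.nan
    se_h2: float = np.nan
    converged: bool = True
    n_iter: int = 0

    def __post_init__(self):
        if min(self.var_a, self.var_pe, self.var_e) < 0:
            raise ValueError("variance components must be >= 0")

    @property
    def total(self) -> float:
        return self.var_a + self.var_pe + self.var_e

    @property
    def h2(self) -> float:
        return heritability(self)

    @property
    def repeatability(self) -> float:
        return repeatability(self)

    def as_dict(self) -> dict:
        return {"var_a": self.var_a, "var_pe": self.var_pe,
                "var_e": self.var_e, "se_a": self.se_a, "se_pe": self.se_pe,
                "se_e": self.se_e, "h2": self.h2, "se_h2": self.se_h2,
                "repeatability": self.repeatability,
                "converged": self.converged, "n_iter": self.n_iter}


def heritability(var: VarianceComponents) -> float:
    """h2 = sigma2_a / (sigma2_a + sigma2_pe + sigma2_e)."""
    total = var.var_a + var.var_pe + var.var_e
    if total <= 0:
        raise ValueError("zero total variance")
    return var.var_a / total


def repeatability(var: VarianceComponents) -> float:
    """(sigma2_a + sigma2_pe) / total — upper bound on h2."""
    total = var.total
    if total <= 0:
        raise ValueError("zero total variance")
    return (var.var_a + var.var_pe) / total


@dataclass
class Solutions:
    fixed: pd.Series
    gebv: pd.Series
    pe: pd.Series
    residuals: np.ndarray
    residual_norm: float


@dataclass
class MixedModelSystem:
    """Assembled (sigma2_e-scaled) MME, ready to factorize."""

    coef: sp.csr_matrix
    rhs: np.ndarray
    n_fixed: int
    n_animal: int
    n_pe: int
    fixed_labels: list
    animal_ids: np.ndarray
    pe_ids: np.ndarray
    X: sp.csr_matrix
    Z: sp.csr_matrix
    W: sp.csr_matrix | None
    y: np.ndarray

    @property
    def size(self) -> int:
        return self.coef.shape[0]


class _Design:
    """Record-level design matrices shared by MME assembly and REML."""

    def __init__(self, records: pd.DataFrame, spec: ModelSpec,
                 animal_ids: np.ndarray):
        if spec.trait not in records.columns:
            raise ValueError(f"trait column {spec.trait!r} missing")
        y = records[spec.trait].to_numpy(dtype=float)
        if spec.transform == "log":
            if (y <= 0).any():
                raise ValueError("log transform requires positive records")
            y = np.log(y)
        n = len(records)

        cols = [np.ones(n)]
        labels = ["mean"]
        if spec.yearseason_col is not None:
            ys = records[spec.yearseason_col].astype(str).to_numpy()
            levels = sorted(pd.unique(ys))
            if len(levels) > 1:
                for lev in levels[1:]:  # drop first level: estimable with mean
                    cols.append((ys == lev).astype(float))
                    labels.append(f"yearseason[{lev}]")
        for covname, col in (("age", spec.age_col), ("intv", spec.intv_col)):
            if col is not None:
                cols.append(records[col].to_numpy(dtype=float))
                labels.append(covname)
        X = np.column_stack(cols)
        # guard against confounded/empty columns
        keep = np.ones(X.shape[1], dtype=bool)
        r = np.linalg.matrix_rank(X)
        if r < X.shape[1]:
            q, rr, piv = sla.qr(X, mode="economic", pivoting=True)
            keep = np.zeros(X.shape[1], dtype=bool)
            keep[piv[:r]] = True
            dropped = [labels[k] for k in range(len(labels)) if not keep[k]]
            warnings.warn(f"dropping confounded fixed columns: {dropped}")
            X = X[:, keep]
            labels = [l for l, k in zip(labels, keep) if k]
        self.X = sp.csr_matrix(X)
        self.X_dense = X
        self.fixed_labels = labels
        self.rank_x = X.shape[1]

        pos = {v: i for i, v in enumerate(animal_ids)}
        rec_animals = records[spec.animal_col].to_numpy()
        try:
            aidx = np.array([pos[v] for v in rec_animals])
        except KeyError as exc:
            raise ValueError(
                f"record refers to unknown animal id {exc.args[0]!r}"
            ) from None
        q_a = len(animal_ids)
        self.Z = sp.csr_matrix(
            (np.ones(n), (np.arange(n), aidx)), shape=(n, q_a))
        self.animal_ids = np.asarray(animal_ids)

        if spec.permanent_env:
            pe_levels = pd.unique(rec_animals)
            pe_pos = {v: i for i, v in enumerate(pe_levels)}
            pidx = np.array([pe_pos[v] for v in rec_animals])
            self.W = sp.csr_matrix(
                (np.ones(n), (np.arange(n), pidx)),
                shape=(n, len(pe_levels)))
            self.pe_ids = np.asarray(pe_levels)
        else:
            self.W = None
            self.pe_ids = np.array([])
        self.y = y
        self.n = n

    def cross_products(self):
        """All fixed cross-products needed to assemble the MME."""
        X, Z, W, y = self.X, self.Z, self.W, self.y
        out = {
            "XtX": (X.T @ X).toarray(), "XtZ": X.T @ Z,
            "ZtZ": Z.T @ Z, "Xty": X.T @ y, "Zty": Z.T @ y,
            "yty": float(y @ y),
        }
        if W is not None:
            out.update({"XtW": X.T @ W, "ZtW": Z.T @ W, "WtW": W.T @ W,
                        "Wty": W.T @ y})
        return out


def build_design(records: pd.DataFrame, spec: ModelSpec,
                 animal_ids: np.ndarray) -> _Design:
    return _Design(records, spec, animal_ids)


def build_mme(records: pd.DataFrame, spec: ModelSpec, h_inv: sp.spmatrix,
              var: VarianceComponents,
              animal_ids: np.ndarray | None = None) -> MixedModelSystem:
    """Assemble the sigma2_e-scaled mixed-model equations."""
    if animal_ids is None:
        animal_ids = np.asarray(
            pd.unique(records[spec.animal_col].to_numpy()))
    if h_inv.shape[0] != len(animal_ids):
        raise ValueError(
            f"relationship inverse is {h_inv.shape[0]}x{h_inv.shape[1]} but "
            f"there are {len(animal_ids)} animals")
    if var.var_a <= 0 or var.var_e <= 0:
        raise ValueError("var_a and var_e must be positive to form ratios")
    if spec.permanent_env and var.var_pe <= 0:
        raise ValueError("var_pe must be positive when the permanent-"
                         "environment term is in the model")
    design = _Design(records, spec, animal_ids)
    return _assemble(design, h_inv, var)


def _assemble(design: _Design, k_inv: sp.spmatrix,
              var: VarianceComponents) -> MixedModelSystem:
    cp = design.cross_products()
    k_a = var.var_e / var.var_a
    blocks_coef = [
        [sp.csr_matrix(cp["XtX"]), cp["XtZ"]],
        [cp["XtZ"].T, cp["ZtZ"] + sp.csr_matrix(k_inv) * k_a],
    ]
    rhs = [cp["Xty"], cp["Zty"]]
    if design.W is not None:
        k_p = var.var_e / var.var_pe
        q_p = design.W.shape[1]
        blocks_coef[0].append(cp["XtW"])
        blocks_coef[1].append(cp["ZtW"])
        blocks_coef.append([cp["XtW"].T, cp["ZtW"].T,
                            cp["WtW"] + sp.identity(q_p) * k_p])
        rhs.append(cp["Wty"])
    coef = sp.csr_matrix(sp.bmat(blocks_coef))
    return MixedModelSystem(
        coef=coef, rhs=np.concatenate(rhs),
        n_fixed=design.rank_x, n_animal=design.Z.shape[1],
        n_pe=design.W.shape[1] if design.W is not None else 0,
        fixed_labels=design.fixed_labels, animal_ids=design.animal_ids,
        pe_ids=design.pe_ids, X=design.X, Z=design.Z, W=design.W,
        y=design.y)


def _chol_inverse(C: np.ndarray):
    """Cholesky factor and full inverse of a dense SPD matrix via LAPACK."""
    L, info = dpotrf(C, lower=1, overwrite_a=0)
    if info != 0:
        raise np.linalg.LinAlgError(
            f"MME coefficient matrix not positive definite (info={info})")
    inv, info = dpotri(L, lower=1)
    if info != 0:
        raise np.linalg.LinAlgError("dpotri failed")
    inv = np.tril(inv) + np.tril(inv, -1).T
    return L, inv


def solve_mme(system: MixedModelSystem, method: str = "auto",
              tol: float = 1e-10, maxiter: int = 5000) -> Solutions:
    """Solve the assembled MME.

    Dense Cholesky below ~6000 unknowns, sparse LU above ("auto"); a
    Jacobi-preconditioned conjugate-gradient path ("cg") is available for
    very large systems.
    """
    n = system.size
    if method == "auto":
        method = "dense" if n <= 6000 else "sparse"
    if method == "dense":
        C = system.coef.toarray()
        c, low = sla.cho_factor(C, lower=True)
        sol = sla.cho_solve((c, low), system.rhs)
    elif method == "sparse":
        lu = sp.linalg.splu(system.coef.tocsc())
        sol = lu.solve(system.rhs)
    elif method == "cg":
        d = system.coef.diagonal()
        M = sp.diags(1.0 / np.where(d > 0, d, 1.0))
        sol, info = sp.linalg.cg(system.coef, system.rhs, rtol=tol,
                                 maxiter=maxiter, M=M)
        if info != 0:
            raise RuntimeError(
                f"PCG failed to converge (info={info}); residual norm "
                f"{np.linalg.norm(system.coef @ sol - system.rhs):.3e}")
    else:
        raise ValueError(f"unknown solver {method!r}")
    resid = system.coef @ sol - system.rhs
    nf, na, npe = system.n_fixed, system.n_animal, system.n_pe
    b = sol[:nf]
    a = sol[nf:nf + na]
    p = sol[nf + na:nf + na + npe]
    yhat = system.X @ b + system.Z @ a
    if system.W is not None:
        yhat = yhat + system.W @ p
    return Solutions(
        fixed=pd.Series(b, index=system.fixed_labels),
        gebv=pd.Series(a, index=system.animal_ids),
        pe=pd.Series(p, index=system.pe_ids),
        residuals=system.y - yhat,
        residual_norm=float(np.linalg.norm(resid)))


def ai_reml(records: pd.DataFrame, spec: ModelSpec, k_inv: sp.spmatrix,
            animal_ids: np.ndarray, start: tuple | None = None,
            max_iter: int = 60, tol: float = 1e-8,
            verbose: bool = False) -> VarianceComponents:
    """Average-information REML for (sigma2_a, sigma2_pe, sigma2_e).

    Newton steps on the AI matrix with EM-REML fallback whenever a step
    would leave the parameter space; convergence when the relative
    parameter change drops below ``tol``.  Start values default to equal
    thirds of the phenotypic variance.
    """
    design = _Design(records, spec, animal_ids)
    if design.W is None:
        raise ValueError("AI-REML here estimates (a, pe, e); set "
                         "permanent_env=True or use a 2-component model")
    counts = np.asarray(design.W.sum(axis=0)).ravel()
    if not (counts >= 2).any():
        raise ValueError(
            "no animal has repeated records: sigma2_pe is not identifiable")

    y = design.y
    n = design.n
    vary = float(np.var(y, ddof=1))
    if vary <= 0:
        raise ValueError("records have zero variance")
    theta = np.array(start if start is not None
                     else [vary / 3.0, vary / 3.0, vary / 3.0])
    floor = 1e-8 * vary
    theta = np.maximum(theta, floor)

    q_a = design.Z.shape[1]
    q_p = design.W.shape[1]
    r_x = design.rank_x
    K_inv = sp.csr_matrix(k_inv)
    X, Z, W = design.X, design.Z, design.W

    def mme_pieces(th):
        var = VarianceComponents(*th)
        system = _assemble(design, K_inv, var)
        C = system.coef.toarray()
        L, Cinv = _chol_inverse(C)
        sol = Cinv @ system.rhs
        nf = system.n_fixed
        b, a, p = sol[:nf], sol[nf:nf + q_a], sol[nf + q_a:]
        ehat = y - X @ b - Z @ a - W @ p
        Caa = Cinv[nf:nf + q_a, nf:nf + q_a]
        Cpp_diag = np.diag(Cinv[nf + q_a:, nf + q_a:])
        tr_a = float(np.sum(K_inv.multiply(Caa)))
        tr_p = float(Cpp_diag.sum())
        return system, Cinv, b, a, p, ehat, tr_a, tr_p

    last = None
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        sa, sp_, se = theta
        system, Cinv, b, a, p, ehat, tr_a, tr_p = mme_pieces(theta)
        aKa = float(a @ (K_inv @ a))
        pp = float(p @ p)
        ee = float(ehat @ ehat)
        k_a, k_p = se / sa, se / sp_

        # restricted-likelihood gradient via MME trace identities
        tr_P = (n - r_x - (q_a - k_a * tr_a) - (q_p - k_p * tr_p)) / se
        grad = np.array([
            -0.5 * (q_a / sa - se * tr_a / sa ** 2 - aKa / sa ** 2),
            -0.5 * (q_p / sp_ - se * tr_p / sp_ ** 2 - pp / sp_ ** 2),
            -0.5 * (tr_P - ee / se ** 2),
        ])

        # average-information matrix from working variates f_i = dV/dtheta_i Py
        f = np.column_stack([
            (Z @ a) / sa,
            (W @ p) / sp_,
            ehat / se,
        ])
        Pf = np.empty_like(f)
        nf = system.n_fixed
        for j in range(3):
            rhs_f = np.concatenate([X.T @ f[:, j], Z.T @ f[:, j],
                                    W.T @ f[:, j]])
            sol_f = Cinv @ rhs_f
            Pf[:, j] = (f[:, j] - X @ sol_f[:nf]
                        - Z @ sol_f[nf:nf + q_a]
                        - W @ sol_f[nf + q_a:]) / se
        AI = 0.5 * (f.T @ Pf)
        AI = 0.5 * (AI + AI.T)

        # EM updates (always valid; used as fallback)
        em = np.array([
            (aKa + se * tr_a) / q_a,
            (pp + se * tr_p) / q_p,
            (float(y @ ehat)) / (n - r_x),
        ])

        try:
            step = np.linalg.solve(AI, grad)
        except np.linalg.LinAlgError:
            step = None
        new = None
        if step is not None:
            cand = theta + step
            halve = 0
            while (cand <= 0).any() and halve < 5:
                step *= 0.5
                cand = theta + step
                halve += 1
            if (cand > 0).all():
                new = cand
        if new is None:
            new = em
        new = np.maximum(new, floor)
        # pin components collapsing toward zero to the boundary so the
        # slow geometric EM decay does not stall convergence
        boundary = new < 1e-5 * vary
        new[boundary] = floor
        active = ~boundary
        if active.any():
            rel = float(np.max(np.abs(new[active] - theta[active])
                               / np.maximum(np.abs(theta[active]), floor)))
        else:
            rel = 0.0
        if verbose:
            print(f"iter {it}: theta={theta}, rel={rel:.3e}")
        theta = new
        last = (AI, grad)
        if rel < tol:
            converged = True
            break

    # SEs from the inverse AI matrix at the final parameter values
    AI, _ = last
    try:
        AIinv = np.linalg.inv(AI)
        ses = np.sqrt(np.maximum(np.diag(AIinv), 0.0))
        sa, sp_, se = theta
        T = theta.sum()
        gh = np.array([(sp_ + se) / T ** 2, -sa / T ** 2, -sa / T ** 2])
        se_h2 = float(np.sqrt(max(gh @ AIinv @ gh, 0.0)))
    except np.linalg.LinAlgError:
        ses = np.full(3, np.nan)
        se_h2 = np.nan
    return VarianceComponents(
        var_a=float(theta[0]), var_pe=float(theta[1]), var_e=float(theta[2]),
        se_a=float(ses[0]), se_pe=float(ses[1]), se_e=float(ses[2]),
        se_h2=se_h2, converged=converged, n_iter=it)


class RepeatabilityModel:
    """Repeatability animal model bound to records + pedigree.

    Parameters
    ----------
    records : DataFrame of repeated records (one row per record).
    pedigree : Pedigree covering every animal in the records.
    relationship_inv : optional sparse inverse relationship matrix over
        the pedigree (H^-1 for single-step); defaults to the pedigree
        A^-1.
    spec : ModelSpec (or pass its fields as keyword arguments).
    """

    def __init__(self, records: pd.DataFrame, pedigree: Pedigree,
                 relationship_inv: sp.spmatrix | None = None,
                 spec: ModelSpec | None = None, **spec_kwargs):
        self.spec = spec or ModelSpec(**spec_kwargs)
        self.records = records
        self.pedigree = pedigree
        self.k_inv = (sp.csr_matrix(relationship_inv)
                      if relationship_inv is not None
                      else a_inverse(pedigree))
        known = set(pedigree.ids.tolist())
        missing = [v for v in records[self.spec.animal_col].unique()
                   if v not in known]
        if missing:
            raise ValueError(
                f"records refer to animals not in the pedigree: "
                f"{missing[:5]}")

    @classmethod
    def from_dataframe(cls, records: pd.DataFrame, pedigree_df: pd.DataFrame,
                       **kwargs) -> "RepeatabilityModel":
        return cls(records, Pedigree.from_dataframe(pedigree_df), **kwargs)

    def estimate_variances(self, **reml_kwargs) -> VarianceComponents:
        return ai_reml(self.records, self.spec, self.k_inv,
                       self.pedigree.ids, **reml_kwargs)

    def solve(self, var: VarianceComponents,
              solver: str = "auto") -> Solutions:
        system = build_mme(self.records, self.spec, self.k_inv, var,
                           animal_ids=self.pedigree.ids)
        return solve_mme(system, method=solver)

    def fit(self, var: VarianceComponents | None = None,
            solver: str = "auto", **reml_kwargs) -> "RemlResults":
        if var is None:
            var = self.estimate_variances(**reml_kwargs)
        sol = self.solve(var, solver=solver)
        return RemlResults(self, var, sol)


class RemlResults:
    """Fitted repeatability model: variance components + MME solutions."""

    def __init__(self, model: RepeatabilityModel, var: VarianceComponents,
                 solutions: Solutions):
        self.model = model
        self.varcomp = var
        self.solutions = solutions

    @property
    def params(self) -> pd.Series:
        v = self.varcomp
        return pd.Series({"var_a": v.var_a, "var_pe": v.var_pe,
                          "var_e": v.var_e})

    @property
    def bse(self) -> pd.Series:
        v = self.varcomp
        return pd.Series({"var_a": v.se_a, "var_pe": v.se_pe,
                          "var_e": v.se_e})

    @property
    def h2(self) -> float:
        return self.varcomp.h2

    @property
    def gebv(self) -> pd.Series:
        return self.solutions.gebv

    @property
    def fixed_effects(self) -> pd.Series:
        return self.solutions.fixed

    def summary(self) -> str:
        v = self.varcomp
        lines = [
            "Repeatability animal model (AI-REML)",
            "=" * 44,
            f"{'records':<22}{len(self.model.records):>12}",
            f"{'animals in pedigree':<22}{self.model.pedigree.n:>12}",
            f"{'REML iterations':<22}{v.n_iter:>12}",
            f"{'converged':<22}{str(v.converged):>12}",
            "-" * 44,
            f"{'component':<12}{'estimate':>14}{'SE':>14}",
            f"{'var_a':<12}{v.var_a:>14.5f}{v.se_a:>14.5f}",
            f"{'var_pe':<12}{v.var_pe:>14.5f}{v.se_pe:>14.5f}",
            f"{'var_e':<12}{v.var_e:>14.5f}{v.se_e:>14.5f}",
            "-" * 44,
            f"{'h2':<12}{v.h2:>14.5f}{v.se_h2:>14.5f}",
            f"{'repeatability':<14}{v.repeatability:>12.5f}",
        ]
        for name, val in self.solutions.fixed.items():
            lines.append(f"{name:<22}{val:>14.5f}")
        return "\n".join(lines)
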