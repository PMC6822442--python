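"""Mixed-model equations, BLUP solutions, AI-REML and heritability."""

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
from scipy.optimize import minimize

from wssgwas.kinship import Pedigree, UNKNOWN, a_inverse, a_matrix
from wssgwas.mme import (ModelSpec, RepeatabilityModel, VarianceComponents,
                         ai_reml, build_mme, heritability, repeatability,
                         solve_mme, build_design)
from wssgwas.simulate import (SimConfig, drop_genotypes, simulate_pedigree,
                              simulate_phenotypes)

from conftest import random_pedigree

MEAN_ONLY = ModelSpec(yearseason_col=None, age_col=None, intv_col=None)


def small_records(rng, ped, min_rec=1, max_rec=4, with_classes=True):
    rows = []
    for i in range(ped.n):
        for _ in range(rng.integers(min_rec, max_rec + 1)):
            rows.append((ped.ids[i], f"ys{rng.integers(3)}",
                         rng.uniform(8, 60), rng.uniform(2, 14),
                         rng.normal()))
    df = pd.DataFrame(rows, columns=["id", "yearseason", "age", "intv",
                                     "trait"])
    if not with_classes:
        df = df.drop(columns=["yearseason", "age", "intv"])
    return df


def signal_pedigree_records(seed=7, n_founders=20, n_generations=3):
    cfg = SimConfig(n_founders=n_founders, n_generations=n_generations,
                    litter_size=3, n_snps=30, n_qtl=0, qtl_var_fractions=(),
                    var_a=0.5, var_pe=0.3, var_e=1.0, records_per_animal=4,
                    seed=seed)
    ped = simulate_pedigree(cfg)
    gm = drop_genotypes(ped, cfg)
    rec, truth = simulate_phenotypes(ped, gm, cfg)
    return ped, rec, truth, cfg


class TestBuildAndSolve:
    def test_ridge_regression_oracle(self, rng):
        """Mean-only model, identity relationship, k_a = 1, no
        permanent environment: MME solution equals the closed form
        (C'C + diag(0, I))^-1 C'y."""
        ped = Pedigree(ids=np.array([1, 2, 3]),
                       sire=np.full(3, UNKNOWN), dam=np.full(3, UNKNOWN))
        rec = pd.DataFrame({"id": [1, 2, 3],
                            "trait": [1.0, 2.0, 4.0]})
        spec = ModelSpec(yearseason_col=None, age_col=None, intv_col=None,
                        permanent_env=False)
        var = VarianceComponents(var_a=1.0, var_pe=0.0, var_e=1.0)
        system = build_mme(rec, spec, sp.identity(3, format="csr"), var,
                           animal_ids=ped.ids)
        sol = solve_mme(system)
        C = np.column_stack([np.ones(3), np.eye(3)])
        penalty = np.diag([0.0, 1.0, 1.0, 1.0])
        oracle = np.linalg.solve(C.T @ C + penalty,
                                 C.T @ rec["trait"].to_numpy())
        np.testing.assert_allclose(
            np.concatenate([sol.fixed.to_numpy(), sol.gebv.to_numpy()]),
            oracle, atol=1e-10)

    def test_scalar_blup_shrinkage(self):
        """Two unrelated animals, one record each, no permanent
        environment: deviations from the mean shrink by
        var_a / (var_a + var_e)."""
        ped = Pedigree(ids=np.array([1, 2]), sire=np.full(2, UNKNOWN),
                       dam=np.full(2, UNKNOWN))
        rec = pd.DataFrame({"id": [1, 2], "trait": [-1.0, 1.0]})
        spec = ModelSpec(yearseason_col=None, age_col=None, intv_col=None,
                        permanent_env=False)
        var = VarianceComponents(var_a=0.5, var_pe=0.0, var_e=1.5)
        model = RepeatabilityModel(rec, ped, spec=spec)
        sol = model.solve(var)
        shrink = var.var_a / (var.var_a + var.var_e)
        np.testing.assert_allclose(sol.gebv.to_numpy(),
                                   shrink * np.array([-1.0, 1.0]),
                                   atol=1e-10)

    def test_record_permutation_invariance(self, rng):
        ped = random_pedigree(rng, n_founders=6, n_total=15)
        rec = small_records(rng, ped)
        var = VarianceComponents(0.4, 0.3, 1.0)
        model = RepeatabilityModel(rec, ped)
        sol1 = model.solve(var)
        shuffled = rec.sample(frac=1.0, random_state=1).reset_index(
            drop=True)
        sol2 = RepeatabilityModel(shuffled, ped).solve(var)
        np.testing.assert_allclose(sol1.gebv.to_numpy(),
                                   sol2.gebv.to_numpy(), atol=1e-8)
        np.testing.assert_allclose(sol1.fixed.to_numpy(),
                                   sol2.fixed.to_numpy(), atol=1e-8)

    def test_gls_oracle_fixed_effects(self, rng):
        """MME fixed effects equal direct GLS with
        V = Z A Z' var_a + W W' var_pe + I var_e on a small fixture."""
        ped = random_pedigree(rng, n_founders=5, n_total=12)
        rec = small_records(rng, ped, min_rec=1, max_rec=3)
        assert len(rec) <= 50
        var = VarianceComponents(0.5, 0.3, 1.0)
        model = RepeatabilityModel(rec, ped)
        sol = model.solve(var)
        design = build_design(rec, model.spec, ped.ids)
        X = design.X_dense
        Z = design.Z.toarray()
        W = design.W.toarray()
        y = design.y
        A = a_matrix(ped)
        V = (Z @ A @ Z.T * var.var_a + W @ W.T * var.var_pe
             + np.eye(len(y)) * var.var_e)
        Vi = np.linalg.inv(V)
        beta = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ y)
        np.testing.assert_allclose(sol.fixed.to_numpy(), beta, atol=1e-6)
        # GEBVs are the BLUP var_a * A Z' V^-1 (y - X beta)
        gebv = var.var_a * A @ Z.T @ Vi @ (y - X @ beta)
        np.testing.assert_allclose(sol.gebv.to_numpy(), gebv, atol=1e-6)

    def test_duplicating_records_refit_oracle(self, rng):
        """Duplicating every record doubles all data cross-products, which
        is algebraically a refit of the original data with the residual
        variance halved (both variance ratios halve)."""
        ped = random_pedigree(rng, n_founders=5, n_total=12)
        rec = small_records(rng, ped, min_rec=1, max_rec=2)
        var = VarianceComponents(0.5, 0.3, 1.0)
        sol1 = RepeatabilityModel(rec, ped).solve(var)
        doubled = pd.concat([rec, rec], ignore_index=True)
        sol2 = RepeatabilityModel(doubled, ped).solve(var)
        half_e = VarianceComponents(0.5, 0.3, 0.5)
        oracle = RepeatabilityModel(rec, ped).solve(half_e)
        np.testing.assert_allclose(sol2.fixed.to_numpy(),
                                   oracle.fixed.to_numpy(), atol=1e-8)
        np.testing.assert_allclose(sol2.gebv.to_numpy(),
                                   oracle.gebv.to_numpy(), atol=1e-8)
        # more records per animal -> GEBVs track the data more closely
        assert sol2.gebv.to_numpy().var() > sol1.gebv.to_numpy().var()

    def test_constant_phenotypes_zero_random_effects(self, rng):
        ped = random_pedigree(rng, n_founders=4, n_total=10)
        rec = small_records(rng, ped, with_classes=False)
        rec["trait"] = 3.25
        spec = ModelSpec(yearseason_col=None, age_col=None, intv_col=None)
        sol = RepeatabilityModel(rec, ped, spec=spec).solve(
            VarianceComponents(0.5, 0.3, 1.0))
        np.testing.assert_allclose(sol.gebv.to_numpy(), 0.0, atol=1e-9)
        np.testing.assert_allclose(sol.pe.to_numpy(), 0.0, atol=1e-9)
        assert sol.fixed["mean"] == pytest.approx(3.25)

    def test_unknown_animal_id_error(self, trio, rng):
        rec = pd.DataFrame({"id": [99], "trait": [1.0]})
        with pytest.raises(ValueError, match="not in the pedigree"):
            RepeatabilityModel(rec, trio, spec=MEAN_ONLY)


class TestHeritability:
    @pytest.mark.parametrize("components, expected", [
        ((0.00757, 0.00248, 0.03695), 0.16105),  # progressive motility
        ((0.05172, 0.03682, 0.19380), 0.18320),  # log sperm-cell count
        ((1.0, 0.0, 0.0), 1.0),
    ])
    def test_ratio_of_components(self, components, expected):
        var = VarianceComponents(*components)
        assert heritability(var) == pytest.approx(expected, abs=5e-4)

    def test_repeatability_exceeds_h2(self):
        var = VarianceComponents(0.00757, 0.00248, 0.03695)
        assert repeatability(var) > heritability(var)

    def test_zero_total_variance(self):
        with pytest.raises(ValueError):
            heritability(VarianceComponents(0.0, 0.0, 0.0))


def direct_reml_oracle(rec, spec, ped, start):
    """Nelder-Mead on the restricted log-likelihood computed from the
    dense phenotypic covariance V (independent of the MME path)."""
    design = build_design(rec, spec, ped.ids)
    X, Z, W, y = (design.X_dense, design.Z.toarray(), design.W.toarray(),
                  design.y)
    A = a_matrix(ped)
    n = len(y)

    def negll(logth):
        sa, spp, se = np.exp(logth)
        V = Z @ A @ Z.T * sa + W @ W.T * spp + np.eye(n) * se
        Vi = np.linalg.inv(V)
        XtViX = X.T @ Vi @ X
        P = Vi - Vi @ X @ np.linalg.inv(XtViX) @ X.T @ Vi
        _, ld = np.linalg.slogdet(V)
        _, ld2 = np.linalg.slogdet(XtViX)
        return 0.5 * (ld + ld2 + y @ P @ y)

    res = minimize(negll, np.log(start), method="Nelder-Mead",
                   options=dict(xatol=1e-9, fatol=1e-11, maxiter=3000))
    return np.exp(res.x)


class TestAiReml:
    def test_matches_direct_likelihood_oracle(self):
        ped, rec, _, _ = signal_pedigree_records(seed=7, n_founders=14,
                                                 n_generations=2)
        spec = ModelSpec()
        vc = ai_reml(rec, spec, a_inverse(ped), ped.ids)
        # warm-started simplex search on the independent V-based
        # restricted likelihood; the optimum does not depend on the start
        start = np.array([vc.var_a * 1.5, vc.var_pe * 0.6, vc.var_e * 1.3])
        oracle = direct_reml_oracle(rec, spec, ped, start)
        np.testing.assert_allclose(
            [vc.var_a, vc.var_pe, vc.var_e], oracle, rtol=2e-3)

    def test_null_heritability_boundary(self):
        cfg = SimConfig(n_founders=60, n_generations=2, litter_size=2,
                        n_snps=10, n_qtl=0, qtl_var_fractions=(),
                        var_a=0.0, var_pe=0.3, var_e=1.0,
                        records_per_animal=4, seed=3)
        ped = simulate_pedigree(cfg)
        gm = drop_genotypes(ped, cfg)
        rec, _ = simulate_phenotypes(ped, gm, cfg)
        vc = ai_reml(rec, ModelSpec(), a_inverse(ped), ped.ids)
        assert vc.var_a < 0.05 * (vc.var_pe + vc.var_e)

    def test_scale_equivariance(self):
        ped, rec, _, _ = signal_pedigree_records(seed=9, n_founders=12,
                                                 n_generations=2)
        spec = ModelSpec()
        vc1 = ai_reml(rec, spec, a_inverse(ped), ped.ids)
        rec2 = rec.copy()
        rec2["trait"] = 2.0 * rec2["trait"]
        vc2 = ai_reml(rec2, spec, a_inverse(ped), ped.ids)
        np.testing.assert_allclose(
            [vc2.var_a, vc2.var_pe, vc2.var_e],
            [4 * vc1.var_a, 4 * vc1.var_pe, 4 * vc1.var_e], rtol=1e-3)

    def test_invariant_to_class_relabeling(self):
        """Swapping year-season labels changes which dummy is dropped but
        not the variance components."""
        ped, rec, _, _ = signal_pedigree_records(seed=5, n_founders=10,
                                                 n_generations=2)
        spec = ModelSpec()
        vc1 = ai_reml(rec, spec, a_inverse(ped), ped.ids)
        relabel = {"ys0": "zzz", "zzz": "ys0"}
        rec2 = rec.copy()
        rec2["yearseason"] = rec2["yearseason"].map(
            lambda v: relabel.get(v, v))
        vc2 = ai_reml(rec2, spec, a_inverse(ped), ped.ids)
        np.testing.assert_allclose(
            [vc1.var_a, vc1.var_pe, vc1.var_e],
            [vc2.var_a, vc2.var_pe, vc2.var_e], rtol=1e-6)

    def test_no_repeats_not_identifiable(self, rng):
        ped = random_pedigree(rng, n_founders=5, n_total=10)
        rec = small_records(rng, ped, min_rec=1, max_rec=1)
        with pytest.raises(ValueError, match="identifiable"):
            ai_reml(rec, ModelSpec(), a_inverse(ped), ped.ids)

    def test_reported_standard_errors_finite(self):
        ped, rec, _, _ = signal_pedigree_records(seed=2, n_founders=12,
                                                 n_generations=2)
        vc = ai_reml(rec, ModelSpec(), a_inverse(ped), ped.ids)
        assert np.isfinite([vc.se_a, vc.se_pe, vc.se_e, vc.se_h2]).all()
        assert vc.se_h2 < 0.5


class TestRepeatabilityModelApi:
    def test_fit_returns_summary(self):
        ped, rec, _, _ = signal_pedigree_records(seed=4, n_founders=10,
                                                 n_generations=2)
        res = RepeatabilityModel(rec, ped).fit()
        text = res.summary()
        assert "var_a" in text and "h2" in text
        assert res.params.shape == (3,)
        assert len(res.gebv) == ped.n

    def test_log_transform_requires_positive(self, trio):
        rec = pd.DataFrame({"id": [1, 2, 3], "trait": [1.0, -2.0, 3.0]})
        spec = ModelSpec(yearseason_col=None, age_col=None, intv_col=None,
                        transform="log")
        model = RepeatabilityModel(rec, trio, spec=spec)
        with pytest.raises(ValueError, match="positive"):
            model.solve(VarianceComponents(1.0, 1.0, 1.0))
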