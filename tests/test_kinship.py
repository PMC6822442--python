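"""Pedigree and genomic relationship matrix algebra."""

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from wssgwas.kinship import (GenotypeMatrix, Pedigree, SnpWeightState,
                             UNKNOWN, a22, a_inverse, a_matrix, blend_gw,
                             g_matrix, h_inverse, inbreeding_coefficients,
                             scaling_factor)

from conftest import random_pedigree


def drop_kinship_oracle(pedigree, n_drops, seed):
    """Monte-Carlo additive relationship via gene dropping at one locus.

    Each founder gets two unique allele labels; offspring inherit one
    random allele per parent.  The additive relationship a_ij is twice
    the probability that a random allele from i and one from j are IBD.
    """
    rng = np.random.default_rng(seed)
    n = pedigree.n
    ibd = np.zeros((n, n))
    for _ in range(n_drops):
        alleles = np.zeros((n, 2), dtype=np.int64)
        nxt = 1
        for i in range(n):
            for k, p in enumerate((pedigree.sire[i], pedigree.dam[i])):
                if p == UNKNOWN:
                    alleles[i, k] = nxt
                    nxt += 1
                else:
                    alleles[i, k] = alleles[p, rng.integers(2)]
        for i in range(n):
            for j in range(i, n):
                # P(random allele of i IBD to random allele of j), x2
                match = (alleles[i][:, None] == alleles[j][None, :]).mean()
                ibd[i, j] += 2 * match
                ibd[j, i] = ibd[i, j]
    ibd /= n_drops
    ibd[np.diag_indices(n)] = 1 + (ibd[np.diag_indices(n)] - 1)
    return ibd


class TestAMatrix:
    def test_unrelated_founders_identity(self):
        ped = Pedigree(ids=np.arange(4), sire=np.full(4, UNKNOWN),
                       dam=np.full(4, UNKNOWN))
        assert np.array_equal(a_matrix(ped), np.eye(4))

    def test_textbook_relationships(self, family_pedigree):
        A = a_matrix(family_pedigree)
        assert A[0, 2] == 0.5          # sire-offspring
        assert A[2, 3] == 0.5          # full sibs
        assert A[0, 1] == 0.0          # unrelated founders
        assert A[2, 2] == 1.0          # non-inbred
        # offspring of full-sib mating: F = 0.25
        assert A[4, 4] == pytest.approx(1.25)

    def test_matches_gene_dropping_oracle(self, family_pedigree):
        A = a_matrix(family_pedigree)
        A_mc = drop_kinship_oracle(family_pedigree, n_drops=20000, seed=7)
        # diagonal of the MC oracle is 1 + F via self-IBD of two alleles
        np.testing.assert_allclose(A, A_mc, atol=0.015)

    def test_inbreeding_coefficients_match_diagonal(self, rng):
        ped = random_pedigree(rng, n_founders=10, n_total=60)
        F = inbreeding_coefficients(ped)
        np.testing.assert_allclose(F, np.diag(a_matrix(ped)) - 1,
                                   atol=1e-12)

    def test_cycle_detection(self):
        df = pd.DataFrame({"id": [1, 2], "sire": [2, 1], "dam": [0, 0]})
        with pytest.raises(ValueError, match="cycle"):
            Pedigree.from_dataframe(df)

    def test_from_dataframe_reorders(self):
        df = pd.DataFrame({"id": [3, 1, 2], "sire": [1, 0, 0],
                           "dam": [2, 0, 0]})
        ped = Pedigree.from_dataframe(df)
        A = a_matrix(ped)
        i3 = list(ped.ids).index(3)
        i1 = list(ped.ids).index(1)
        assert A[i1, i3] == 0.5


class TestAInverse:
    def test_trio_pattern(self, trio):
        Ainv = a_inverse(trio).toarray()
        expected = np.array([[1.5, 0.5, -1.0],
                             [0.5, 1.5, -1.0],
                             [-1.0, -1.0, 2.0]])
        np.testing.assert_allclose(Ainv, expected)

    def test_founders_only_identity(self):
        ped = Pedigree(ids=np.arange(5), sire=np.full(5, UNKNOWN),
                       dam=np.full(5, UNKNOWN))
        np.testing.assert_allclose(a_inverse(ped).toarray(), np.eye(5))

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_inverts_a_matrix_random_pedigrees(self, seed):
        rng = np.random.default_rng(seed)
        ped = random_pedigree(rng, n_founders=15,
                              n_total=int(rng.integers(50, 200)))
        prod = a_inverse(ped).toarray() @ a_matrix(ped)
        np.testing.assert_allclose(prod, np.eye(ped.n), atol=1e-8)


class TestA22:
    def test_extraction_matches_direct(self, rng):
        ped = random_pedigree(rng, n_founders=10, n_total=80)
        ped.genotyped = rng.random(80) < 0.4
        idx = ped.genotyped_indices
        np.testing.assert_allclose(
            a22(ped), a_matrix(ped)[np.ix_(idx, idx)])

    def test_no_genotyped_errors(self, trio):
        with pytest.raises(ValueError, match="no genotyped"):
            a22(trio)


def _hw_genotypes(rng, n, freqs, chrom=None, pos=None):
    m = len(freqs)
    dos = (rng.random((n, m)) < freqs).astype(float) \
        + (rng.random((n, m)) < freqs)
    return GenotypeMatrix(
        dosages=dos, ids=np.arange(n),
        chrom=np.ones(m, dtype=int) if chrom is None else chrom,
        pos=np.arange(1, m + 1) * 1000 if pos is None else pos)


class TestGMatrix:
    def test_single_snp_hand_computed(self):
        gm = GenotypeMatrix(dosages=np.array([[0.], [1.], [2.]]),
                            ids=np.arange(3), chrom=[1], pos=[100])
        G = g_matrix(gm, freqs=np.array([0.5]))
        # lambda = 1/(2*0.5*0.5) = 2; z = (-1, 0, 1); G = lambda * z z'
        expected = 2.0 * np.array([[1.0, 0.0, -1.0], [0.0, 0.0, 0.0],
                                   [-1.0, 0.0, 1.0]])
        np.testing.assert_allclose(G, expected)

    def test_mean_diagonal_near_one_under_hw(self, rng):
        freqs = rng.uniform(0.1, 0.5, size=2000)
        gm = _hw_genotypes(rng, 800, freqs)
        G = g_matrix(gm)
        assert abs(np.mean(np.diag(G)) - 1.0) < 0.02

    def test_weight_rescaling_invariance(self, rng):
        freqs = rng.uniform(0.2, 0.5, size=50)
        gm = _hw_genotypes(rng, 40, freqs)
        w = rng.uniform(0.5, 2.0, size=50)
        w_norm = w * 50 / w.sum()
        doubled = 2 * w
        doubled_norm = doubled * 50 / doubled.sum()
        np.testing.assert_allclose(
            g_matrix(gm, w_norm), g_matrix(gm, doubled_norm), atol=1e-12)

    def test_symmetric_and_psd(self, rng):
        freqs = rng.uniform(0.1, 0.5, size=300)
        gm = _hw_genotypes(rng, 100, freqs)
        G = g_matrix(gm)
        np.testing.assert_allclose(G, G.T)
        assert np.linalg.eigvalsh(G).min() >= -1e-8

    def test_monomorphic_snp_rejected(self):
        gm = GenotypeMatrix(dosages=np.zeros((4, 1)), ids=np.arange(4),
                            chrom=[1], pos=[1])
        with pytest.raises(ValueError, match="monomorphic"):
            g_matrix(gm)

    def test_allele_flip_leaves_g_invariant(self, rng):
        freqs = rng.uniform(0.2, 0.4, size=30)
        gm = _hw_genotypes(rng, 50, freqs)
        flipped = GenotypeMatrix(2.0 - gm.dosages, gm.ids, gm.chrom, gm.pos)
        np.testing.assert_allclose(g_matrix(gm), g_matrix(flipped),
                                   atol=1e-12)


class TestBlendAndH:
    def test_blend_full_genomic_share(self, rng):
        G = rng.random((4, 4))
        A = rng.random((4, 4))
        np.testing.assert_allclose(blend_gw(G, A, 1.0), G)

    def test_blend_fixed_point(self, rng):
        A = rng.random((4, 4))
        np.testing.assert_allclose(blend_gw(A, A, 0.9), A)

    def test_blend_is_convex_combination(self, rng):
        G = rng.random((5, 5))
        A = rng.random((5, 5))
        np.testing.assert_allclose(blend_gw(G, A), 0.9 * G + 0.1 * A)

    def test_blend_shape_mismatch(self):
        with pytest.raises(ValueError, match="shape"):
            blend_gw(np.eye(3), np.eye(4))

    def test_h_inverse_no_genotyped_equals_a_inverse(self, rng):
        ped = random_pedigree(rng, n_founders=8, n_total=40)
        Ainv = a_inverse(ped)
        H = h_inverse(Ainv, np.empty((0, 0)), np.empty((0, 0)), ped)
        assert (H != Ainv).nnz == 0

    def test_h_inverse_cancels_when_gw_equals_a22(self, rng):
        ped = random_pedigree(rng, n_founders=8, n_total=40)
        ped.genotyped = np.arange(40) >= 25
        Ainv = a_inverse(ped)
        A22 = a22(ped)
        H = h_inverse(Ainv, A22, A22.copy(), ped)
        np.testing.assert_allclose(H.toarray(), Ainv.toarray(), atol=1e-8)

    def test_h_inverse_matches_dense_oracle(self, rng):
        """Assemble H explicitly by the standard single-step identity and
        invert densely."""
        ped = random_pedigree(rng, n_founders=15, n_total=100)
        ped.genotyped = np.arange(100) >= 60
        idx = ped.genotyped_indices
        other = np.setdiff1d(np.arange(100), idx)
        A = a_matrix(ped)
        A22 = A[np.ix_(idx, idx)]
        freqs = rng.uniform(0.2, 0.5, size=200)
        gm = _hw_genotypes(rng, len(idx), freqs)
        G_w = blend_gw(g_matrix(gm), A22)
        # H: genotyped block replaced by G_w, off blocks propagated
        A22inv = np.linalg.inv(A22)
        H = np.zeros_like(A)
        A11 = A[np.ix_(other, other)]
        A12 = A[np.ix_(other, idx)]
        H[np.ix_(other, other)] = A11 + A12 @ A22inv @ (G_w - A22) \
            @ A22inv @ A12.T
        H[np.ix_(other, idx)] = A12 @ A22inv @ G_w
        H[np.ix_(idx, other)] = H[np.ix_(other, idx)].T
        H[np.ix_(idx, idx)] = G_w
        H_inv = h_inverse(a_inverse(ped), A22, G_w, ped)
        np.testing.assert_allclose(H_inv.toarray(), np.linalg.inv(H),
                                   atol=1e-6)


class TestTripletPersistence:
    def test_sparse_round_trip(self, rng, tmp_path):
        from wssgwas.kinship import load_triplet, save_triplet

        ped = random_pedigree(rng, n_founders=8, n_total=30)
        Ainv = a_inverse(ped)
        path = tmp_path / "ainv.txt.gz"
        save_triplet(Ainv, path)
        back = load_triplet(path)
        assert (back != Ainv).nnz == 0


class TestSnpWeightState:
    def test_identity_trace(self):
        st = SnpWeightState.identity(7)
        assert st.trace == 7

    def test_negative_weights_rejected(self):
        with pytest.raises(ValueError):
            SnpWeightState(np.array([1.0, -0.1]))

    def test_scaling_factor_all_monomorphic(self):
        with pytest.raises(ValueError):
            scaling_factor(np.array([0.0, 1.0]))
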