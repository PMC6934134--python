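"""Genotype QC, G matrices, blending and H-inverse."""

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
from scipy.stats import chi2

from ssblend import pedigree as pedlib
from ssblend.genomic import (
    BlendedG,
    FrequencySpec,
    GenotypeError,
    GenotypeMatrix,
    QCThresholds,
    allele_frequencies,
    blend,
    fit_beta_moments,
    g_matrix,
    g_matrix_scaled,
    h_inverse,
    impute_missing,
    qc_filter,
    read_genotypes,
    scaled_g_denominator,
)


def write_tsv(path, codes, ids=None):
    gm = GenotypeMatrix(codes=np.array(codes, dtype=np.int8),
                        animal_ids=ids or [f"a{i}" for i in range(len(codes))])
    gm.write_tsv(path)
    return gm


class TestReadGenotypes:
    def test_tsv(self, tmp_path):
        path = tmp_path / "g.tsv"
        write_tsv(path, [[0, 1, 2], [2, -1, 0]])
        gm = read_genotypes(path, dialect="tsv")
        assert gm.codes.shape == (2, 3)
        assert gm.codes[1, 1] == -1  # NA normalized

    def test_plink_raw_equivalence(self, tmp_path):
        tsv = tmp_path / "g.tsv"
        write_tsv(tsv, [[0, 1, 2], [2, 0, 1]])
        raw = tmp_path / "g.raw"
        raw.write_text(
            "FID IID PAT MAT SEX PHENOTYPE m0_A m1_A m2_A\n"
            "0 a0 0 0 1 -9 0 1 2\n"
            "0 a1 0 0 1 -9 2 0 1\n"
        )
        a = read_genotypes(tsv, dialect="tsv")
        b = read_genotypes(raw, dialect="plink_raw")
        assert np.array_equal(a.codes, b.codes)
        assert list(a.animal_ids) == list(b.animal_ids)

    def test_invalid_code_rejected(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("animal_id\tm1\na0\t3\n")
        with pytest.raises(GenotypeError, match="3"):
            read_genotypes(path, dialect="tsv")


class TestQC:
    def _gm(self, codes, chrom=None):
        codes = np.array(codes, dtype=np.int8)
        meta = None
        if chrom is not None:
            meta = pd.DataFrame({
                "marker": [f"m{j}" for j in range(codes.shape[1])],
                "chrom": chrom, "pos": range(codes.shape[1]),
            })
        return GenotypeMatrix(codes=codes,
                              animal_ids=[f"a{i}" for i in range(len(codes))],
                              marker_meta=meta)

    def test_low_maf_removed(self):
        rng = np.random.default_rng(0)
        common = rng.integers(0, 3, size=(50, 1))
        rare = np.zeros((50, 1), dtype=int)
        rare[:4] = 1  # allele frequency 0.04
        gm = self._gm(np.hstack([common, rare]))
        filtered, report = qc_filter(gm)
        assert filtered.n_markers == 1
        assert report.set_index("stage").loc["maf", "removed"] == 1

    def test_low_call_rate_removed(self):
        rng = np.random.default_rng(1)
        good = rng.integers(0, 3, size=(40, 1))
        bad = rng.integers(0, 3, size=(40, 1))
        bad[:6] = -1  # 85% call rate
        gm = self._gm(np.hstack([good, bad]))
        filtered, report = qc_filter(gm)
        assert filtered.n_markers == 1
        assert report.set_index("stage").loc["marker_call_rate", "removed"] == 1

    def test_hwe_extreme_het_deficit_removed(self):
        # genotype counts (50, 0, 50): chi-square statistic equals n = 100,
        # p = P(chi2_1 > 100) << 1e-8
        codes = np.array([[0]] * 50 + [[2]] * 50, dtype=np.int8)
        ok = np.tile([0, 1, 1, 2], 25).reshape(100, 1)
        gm = self._gm(np.hstack([ok, codes]))
        assert chi2.sf(100, df=1) < 1e-8
        filtered, report = qc_filter(gm)
        assert report.set_index("stage").loc["hwe", "removed"] == 1

    def test_non_autosomal_removed(self):
        rng = np.random.default_rng(2)
        gm = self._gm(rng.integers(0, 3, size=(60, 3)), chrom=["1", "Z", "2"])
        filtered, report = qc_filter(gm)
        assert filtered.n_markers == 2
        assert report.set_index("stage").loc["non_autosomal", "removed"] == 1

    def test_idempotent(self, small_sim):
        once, _ = qc_filter(small_sim.genotypes)
        twice, rep2 = qc_filter(once)
        assert np.array_equal(once.codes, twice.codes)
        assert rep2["removed"].sum() == 0

    def test_all_markers_removed_raises(self):
        gm = self._gm(np.zeros((30, 2), dtype=int))  # monomorphic
        with pytest.raises(GenotypeError, match="all markers"):
            qc_filter(gm)


class TestAlleleFrequencies:
    def test_observed_simple(self):
        gm = GenotypeMatrix(codes=np.array([[0], [2]], dtype=np.int8),
                            animal_ids=["a", "b"])
        assert allele_frequencies(gm, "observed").p[0] == pytest.approx(0.5)

    def test_observed_derived(self):
        gm = GenotypeMatrix(codes=np.array([[2], [2], [1], [1]], dtype=np.int8),
                            animal_ids=list("abcd"))
        assert allele_frequencies(gm, "observed").p[0] == pytest.approx(0.75)

    def test_half_scheme_constant(self, small_sim):
        f = allele_frequencies(small_sim.genotypes, "half")
        assert np.all(f.p == 0.5)


class TestBetaMoments:
    def test_symmetric_case(self):
        # x = 0.5, v = 0.05: k = 0.25/0.05 - 1 = 4, alpha = beta = 2
        f = FrequencySpec(scheme="observed",
                          p=0.5 + np.sqrt(0.05) * np.array([-1, 1]))
        fit = fit_beta_moments(f)
        assert fit.alpha_hat == pytest.approx(2.0)
        assert fit.beta_hat == pytest.approx(2.0)

    def test_asymmetric_case(self):
        # x = 0.2, v = 0.01: k = 0.16/0.01 - 1 = 15, alpha = 3, beta = 12
        f = FrequencySpec(scheme="observed",
                          p=0.2 + np.sqrt(0.01) * np.array([-1, 1]))
        fit = fit_beta_moments(f)
        assert fit.alpha_hat == pytest.approx(3.0)
        assert fit.beta_hat == pytest.approx(12.0)

    def test_symmetry_gives_equal_parameters(self):
        p = np.array([0.3, 0.7, 0.4, 0.6, 0.5])
        fit = fit_beta_moments(FrequencySpec(scheme="observed", p=p))
        assert fit.alpha_hat == pytest.approx(fit.beta_hat)

    def test_overdispersed_rejected(self):
        p = np.array([0.0, 1.0, 0.0, 1.0])  # v = x(1-x)
        with pytest.raises(ValueError, match="undefined"):
            fit_beta_moments(FrequencySpec(scheme="observed", p=p))


class TestGMatrix:
    def test_hand_example(self):
        gm = GenotypeMatrix(codes=np.array([[0, 2], [2, 0]], dtype=np.int8),
                            animal_ids=["a", "b"])
        f = allele_frequencies(gm, "observed")
        G = g_matrix(gm, f)
        assert G == pytest.approx(np.array([[2.0, -2.0], [-2.0, 2.0]]))

    def test_rows_sum_to_zero_observed(self, small_sim):
        gm, _ = qc_filter(small_sim.genotypes)
        G = g_matrix(gm, allele_frequencies(gm, "observed"))
        assert np.abs(G.sum(axis=1)).max() < 1e-8

    def test_identical_animals_share_diagonal(self):
        gm = GenotypeMatrix(codes=np.array([[0, 1, 2], [0, 1, 2], [2, 1, 0]],
                                           dtype=np.int8),
                            animal_ids=["a", "b", "c"])
        G = g_matrix(gm, allele_frequencies(gm, "observed"))
        assert G[0, 1] == pytest.approx(G[0, 0])
        assert G[0, 1] == pytest.approx(G[1, 1])

    def test_impute_missing(self):
        gm = GenotypeMatrix(codes=np.array([[2], [1], [-1], [0]], dtype=np.int8),
                            animal_ids=list("abcd"))
        f = FrequencySpec(scheme="observed", p=np.array([0.75]))
        M = impute_missing(gm, f)
        assert M[2, 0] == pytest.approx(1.5)
        complete = GenotypeMatrix(codes=np.array([[2], [0]], dtype=np.int8),
                                  animal_ids=["a", "b"])
        out = impute_missing(complete, FrequencySpec("observed", [0.5]))
        assert out == pytest.approx(np.array([[2.0], [0.0]]))


class TestScaledG:
    def test_proportional_to_observed_g(self, small_sim):
        gm, _ = qc_filter(small_sim.genotypes)
        f = allele_frequencies(gm, "observed")
        fit = fit_beta_moments(f)
        G = g_matrix(gm, f)
        Gs = g_matrix_scaled(gm, fit)
        ratio = G[G != 0] / Gs[G != 0]
        assert np.ptp(ratio) < 1e-8  # single scalar ratio

    def test_denominator_hand_oracle(self):
        # alpha = beta = 2 so p0 = q0 = 0.5 and the (p0-q0)^2 term vanishes:
        # denom = m * 2 * (sum p(1-p)/m) * (alpha+beta+2)/(alpha+beta)
        p = 0.5 + np.sqrt(0.05) * np.array([-1.0, 1.0])
        fit = fit_beta_moments(FrequencySpec(scheme="observed", p=p))
        s = np.sum(p * (1 - p)) / 2
        expected = 2 * (2 * s * (2 + 2 + 2) / (2 + 2))
        assert scaled_g_denominator(fit, 2) == pytest.approx(expected)


class TestBlendAndH:
    def setup_method(self):
        rng = np.random.default_rng(5)
        B = rng.normal(size=(6, 6))
        self.G = B @ B.T / 6
        self.A22 = np.eye(6) * 1.02 + 0.1

    def test_endpoints_exact(self):
        assert blend(self.G, self.A22, 1.0).g == pytest.approx(self.G)
        assert blend(self.G, self.A22, 0.0).g == pytest.approx(self.A22)

    def test_scalar_arithmetic(self):
        out = blend(np.array([[2.0]]), np.array([[1.0]]), 0.9)
        assert out.g[0, 0] == pytest.approx(1.9)

    def test_monotone_in_w(self):
        prev = blend(self.G, self.A22, 0.0).g
        for w in (0.25, 0.5, 0.75, 1.0):
            cur = blend(self.G, self.A22, w).g
            step = cur - prev
            direction = np.sign(self.G - self.A22)
            assert np.all(step * direction >= -1e-12)
            prev = cur

    @pytest.mark.parametrize("w", [0.85, 0.90, 0.95])
    def test_blend_cholesky_succeeds(self, small_sim, w):
        gm, _ = qc_filter(small_sim.genotypes)
        G = g_matrix(gm, allele_frequencies(gm, "observed"))
        a22 = pedlib.a_submatrix(small_sim.pedigree, gm.animal_ids)
        np.linalg.cholesky(blend(G, a22, w).g)

    def test_h_inverse_empty_set_equals_a_inverse(self, small_sim):
        Ainv = pedlib.a_inverse(small_sim.pedigree)
        H = h_inverse(Ainv, self.G, self.A22, np.array([], dtype=int))
        assert (H != sp.csr_matrix(Ainv)).nnz == 0

    def test_h_inverse_block_identity(self, small_sim):
        ped = small_sim.pedigree
        gm, _ = qc_filter(small_sim.genotypes)
        G = g_matrix(gm, allele_frequencies(gm, "observed"))
        a22 = pedlib.a_submatrix(ped, gm.animal_ids)
        gw = blend(G, a22, 0.9)
        Ainv = pedlib.a_inverse(ped)
        gidx = ped.index_of(gm.animal_ids)
        H = h_inverse(Ainv, gw, a22, gidx)
        got = (H[np.ix_(gidx, gidx)] - Ainv[np.ix_(gidx, gidx)]).toarray()
        want = np.linalg.inv(gw.g) - np.linalg.inv(a22)
        assert got == pytest.approx(want, abs=1e-8)

    def test_singular_gw_raises(self):
        singular = np.ones((6, 6))
        with pytest.raises(np.linalg.LinAlgError, match="blending weight"):
            h_inverse(sp.eye(6).tocsr(), singular, self.A22, np.arange(6))
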