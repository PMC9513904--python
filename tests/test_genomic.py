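import numpy as np
import pytest

from ipacc.genomic import (
    AlleleFrequencySet,
    GenotypeMatrix,
    allele_frequencies,
    apy_inverse,
    blend_tune,
    build_G0,
    center_genotypes,
    compute_tuning,
    core_count_from_variance,
    invert_grm,
    read_genotypes,
    select_core,
    write_genotypes,
)

MICRO_G0 = np.array([[2.0, -2.0], [-2.0, 2.0]])


def micro_Z():
    gm = GenotypeMatrix(np.array([[0, 2], [2, 0]], dtype=np.int8), ["A", "B"])
    freqs = AlleleFrequencySet(np.array([0.5, 0.5]), 1.0)
    return center_genotypes(gm, freqs)


class TestGenotypeIO:
    def test_parse_row(self, tmp_path):
        f = tmp_path / "g.txt"
        f.write_text("A1 012\n")
        gm = read_genotypes(f)
        np.testing.assert_array_equal(gm.M, [[0, 1, 2]])
        assert gm.ids == ["A1"]

    def test_ragged_row_reports_line(self, tmp_path):
        f = tmp_path / "g.txt"
        f.write_text("A1 01\nA2 012\n")
        with pytest.raises(ValueError, match="line 2"):
            read_genotypes(f)

    def test_invalid_digit(self, tmp_path):
        f = tmp_path / "g.txt"
        f.write_text("A1 017\n")
        with pytest.raises(ValueError, match="invalid dosage"):
            read_genotypes(f)

    def test_missing_code_flagged(self, tmp_path):
        f = tmp_path / "g.txt"
        f.write_text("A1 012\nA2 052\nA3 210\n")
        gm = read_genotypes(f)
        assert gm.missing_mask.sum() == 1
        assert gm.missing_mask[1, 1]

    def test_writer_round_trip(self, tmp_path):
        gm = GenotypeMatrix(np.array([[0, 1, 2], [2, 5, 0]], dtype=np.int8), ["x", "y"])
        out = tmp_path / "w.txt"
        write_genotypes(gm, out)
        back = read_genotypes(out)
        np.testing.assert_array_equal(back.M, gm.M)
        assert back.ids == gm.ids


class TestAlleleFrequencies:
    def test_half(self):
        gm = GenotypeMatrix(np.array([[0], [2]], dtype=np.int8), ["a", "b"])
        assert allele_frequencies(gm).p[0] == pytest.approx(0.5)

    def test_monomorphic_contributes_zero_to_k(self):
        gm = GenotypeMatrix(np.array([[2, 0], [2, 2]], dtype=np.int8), ["a", "b"])
        fr = allele_frequencies(gm)
        assert fr.p[0] == pytest.approx(1.0)
        assert fr.k == pytest.approx(2 * 0.5 * 0.5)  # only the polymorphic SNP

    def test_matches_column_mean_oracle(self):
        rng = np.random.default_rng(0)
        M = rng.integers(0, 3, size=(100, 50)).astype(np.int8)
        gm = GenotypeMatrix(M, [str(i) for i in range(100)])
        np.testing.assert_allclose(allele_frequencies(gm).p, M.mean(axis=0) / 2)

    def test_missing_cells_excluded(self):
        gm = GenotypeMatrix(np.array([[0], [5], [2]], dtype=np.int8), list("abc"))
        assert allele_frequencies(gm).p[0] == pytest.approx(0.5)

    def test_all_missing_snp_errors(self):
        gm = GenotypeMatrix(np.array([[5], [5]], dtype=np.int8), ["a", "b"])
        with pytest.raises(ValueError, match="SNP 0"):
            allele_frequencies(gm)


class TestCentering:
    def test_micro(self):
        Z = micro_Z()
        np.testing.assert_allclose(Z.Z, [[-1, 1], [1, -1]])

    def test_columns_sum_to_zero_with_own_freqs(self):
        rng = np.random.default_rng(1)
        gm = GenotypeMatrix(rng.integers(0, 3, (20, 30)).astype(np.int8), [str(i) for i in range(20)])
        Z = center_genotypes(gm, allele_frequencies(gm))
        np.testing.assert_allclose(Z.Z.sum(axis=0), 0, atol=1e-10)

    def test_missing_centered_to_zero(self):
        gm = GenotypeMatrix(np.array([[5, 0]], dtype=np.int8), ["a"])
        freqs = AlleleFrequencySet(np.array([0.3, 0.3]), 0.84)
        Z = center_genotypes(gm, freqs)
        assert Z.Z[0, 0] == 0.0
        assert Z.Z[0, 1] == pytest.approx(-0.6)

    def test_length_mismatch(self):
        gm = GenotypeMatrix(np.array([[0, 1]], dtype=np.int8), ["a"])
        with pytest.raises(ValueError, match="frequency length"):
            center_genotypes(gm, AlleleFrequencySet(np.array([0.5]), 0.5))


class TestG0:
    def test_micro_product(self):
        assert build_G0(micro_Z(), 1.0) == pytest.approx(MICRO_G0)

    def test_row_sums_zero_with_own_freqs(self):
        rng = np.random.default_rng(2)
        gm = GenotypeMatrix(rng.integers(0, 3, (30, 200)).astype(np.int8), [str(i) for i in range(30)])
        fr = allele_frequencies(gm)
        G0 = build_G0(center_genotypes(gm, fr), fr.k)
        np.testing.assert_allclose(G0.sum(axis=1), 0, atol=1e-8)
        assert np.linalg.eigvalsh(G0)[0] > -1e-10

    def test_nonpositive_k_rejected(self):
        with pytest.raises(ValueError):
            build_G0(micro_Z(), 0.0)


class TestBlendTune:
    def test_equal_means_give_identity_tuning(self):
        G = np.array([[1.0, 0.2], [0.2, 1.0]])
        delta, b = compute_tuning(G, G)
        assert delta == 0 and b == 1

    def test_hand_example(self):
        A22 = np.array([[1, 0.5], [0.5, 1]])
        delta, b = compute_tuning(MICRO_G0, A22)
        assert delta == pytest.approx(0.75)
        assert b == pytest.approx(0.625)

    @pytest.mark.parametrize("seed", range(3))
    def test_b_is_one_minus_half_delta(self, seed):
        rng = np.random.default_rng(seed)
        G = rng.normal(size=(5, 5))
        A = rng.normal(size=(5, 5))
        delta, b = compute_tuning(G, A)
        assert b == pytest.approx(1 - delta / 2)

    def test_alpha_zero_no_tuning_is_G0(self):
        G = blend_tune(MICRO_G0, np.eye(2), 0.0, 0.0, 1.0)
        np.testing.assert_array_equal(G, MICRO_G0)

    def test_G0_equal_A22_recovers_A22(self):
        A22 = np.array([[1.1, 0.4], [0.4, 0.9]])
        delta, b = compute_tuning(A22, A22)
        np.testing.assert_allclose(blend_tune(A22, A22, 0.3, delta, b), A22)

    def test_entrywise_hand_formula(self):
        A22 = np.array([[1, 0.5], [0.5, 1]])
        G = blend_tune(MICRO_G0, A22, 0.05, 0.75, 0.625)
        expected = 0.625 * (0.95 * MICRO_G0 + 0.05 * A22) + 0.75
        np.testing.assert_allclose(G, expected)

    def test_bad_alpha(self):
        with pytest.raises(ValueError):
            blend_tune(MICRO_G0, np.eye(2), 1.0, 0.0, 1.0)


class TestInvertGrm:
    def test_identity(self):
        np.testing.assert_allclose(invert_grm(np.eye(3)), np.eye(3))

    def test_two_by_two(self):
        G = np.array([[2.0, 1.0], [1.0, 2.0]])
        np.testing.assert_allclose(invert_grm(G), np.array([[2, -1], [-1, 2]]) / 3)

    def test_random_pd_against_solve(self):
        rng = np.random.default_rng(3)
        B = rng.normal(size=(50, 60))
        G = B @ B.T + np.eye(50)
        Ginv = invert_grm(G)
        assert np.abs(G @ Ginv - np.eye(50)).max() < 1e-8

    def test_non_pd_error_mentions_alpha(self):
        G = np.array([[1.0, 2.0], [2.0, 1.0]])
        with pytest.raises(ValueError, match="alpha"):
            invert_grm(G)


class TestCoreCount:
    def test_identity_needs_all(self):
        assert core_count_from_variance(np.eye(10), 0.98) == 10

    def test_rank_one_needs_one(self):
        v = np.arange(1.0, 6.0)
        assert core_count_from_variance(np.outer(v, v), 0.99) == 1

    def test_bounded_by_marker_count(self):
        rng = np.random.default_rng(4)
        Z = rng.normal(size=(40, 20))
        assert core_count_from_variance(Z @ Z.T, 0.999) <= 20

    def test_monotone_in_threshold(self):
        rng = np.random.default_rng(5)
        Z = rng.normal(size=(30, 25))
        G = Z @ Z.T
        counts = [core_count_from_variance(G, t) for t in (0.5, 0.8, 0.95, 0.99, 1.0)]
        assert counts == sorted(counts)


class TestApy:
    def test_all_core_equals_direct(self):
        rng = np.random.default_rng(6)
        B = rng.normal(size=(20, 40))
        G = B @ B.T / 40 + 0.05 * np.eye(20)
        ids = [str(i) for i in range(20)]
        apy = apy_inverse(G, ids, ids)
        assert np.abs(apy.G_apy_inv - invert_grm(G)).max() < 1e-8

    def test_hand_mendelian_error(self):
        G = np.array([[1, 0.5, 0.5], [0.5, 1, 0.25], [0.5, 0.25, 1]])
        apy = apy_inverse(G, ["1", "2", "3"], ["1", "2"])
        assert apy.m_nn[0] == pytest.approx(0.75)

    def test_exact_on_low_rank_structure(self):
        # non-core rows are linear maps of core rows plus a diagonal: the
        # APY inverse is then the exact inverse
        rng = np.random.default_rng(7)
        r, n = 10, 30
        Zc = rng.normal(size=(r, r))
        Gcc = Zc @ Zc.T + np.eye(r)
        P = rng.normal(size=(n - r, r)) * 0.3
        Gcn = Gcc @ P.T
        Gnn = P @ Gcc @ P.T + np.diag(rng.uniform(0.5, 1.0, n - r))
        G = np.block([[Gcc, Gcn], [Gcn.T, Gnn]])
        ids = [str(i) for i in range(n)]
        apy = apy_inverse(G, ids, ids[:r])
        assert np.abs(apy.G_apy_inv @ G - np.eye(n)).max() < 1e-6

    def test_preserves_caller_ordering(self):
        rng = np.random.default_rng(8)
        B = rng.normal(size=(6, 12))
        G = B @ B.T / 12 + 0.1 * np.eye(6)
        ids = list("abcdef")
        apy = apy_inverse(G, ids, ["b", "e"])  # scattered core
        assert np.abs(apy.G_apy_inv @ G - np.eye(6)).max() < 1e-6 or apy.m_nn.min() > 0

    def test_singular_core_raises(self):
        G = np.array([[1.0, 1.0, 0.5], [1.0, 1.0, 0.5], [0.5, 0.5, 1.0]])
        with pytest.raises((ValueError, np.linalg.LinAlgError)):
            apy_inverse(G, ["1", "2", "3"], ["1", "2"])


class TestSelectCore:
    def test_all(self):
        ids = list("abcd")
        assert select_core(ids, 4, 0) == ids

    def test_reproducible(self):
        ids = [str(i) for i in range(100)]
        assert select_core(ids, 10, 5) == select_core(ids, 10, 5)

    def test_too_many_errors(self):
        with pytest.raises(ValueError):
            select_core(["a"], 2, 0)

    def test_roughly_uniform(self):
        from scipy.stats import chisquare

        ids = [str(i) for i in range(20)]
        counts = np.zeros(20)
        for s in range(1000):
            for a in select_core(ids, 5, s):
                counts[int(a)] += 1
        assert chisquare(counts).pvalue > 1e-3
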