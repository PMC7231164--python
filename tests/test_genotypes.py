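"""Genotype loading, QC filters, allele frequencies, F_ST and PCA."""
import textwrap
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest

import sgskit as sk
from sgskit.genotypes import MISSING


# ---------------------------------------------------------------------------
# loading
# ---------------------------------------------------------------------------

class TestLoading:
    def test_vcf_gt_decoding(self, tmp_path):
        vcf = textwrap.dedent("""\
            ##fileformat=VCFv4.2
            ##contig=<ID=1>
            ##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
            #CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ta\tb\tc
            1\t1\tL1\tA\tG\t.\tPASS\t.\tGT\t0/0\t0/1\t1/1
            1\t2\tL2\tA\tG\t.\tPASS\t.\tGT\t./.\t0/0\t0/1
        """)
        path = tmp_path / "t.vcf"
        path.write_text(vcf)
        G = sk.load_genotypes(path, "vcf", {"a": "x", "b": "x", "c": "y"})
        assert list(G.loci) == ["L1", "L2"]
        np.testing.assert_array_equal(G.calls[:, 0], [2, 1, 0])
        np.testing.assert_array_equal(G.calls[:, 1], [MISSING, 2, 1])

    def test_multiallelic_records_skipped(self, tmp_path):
        vcf = textwrap.dedent("""\
            ##fileformat=VCFv4.2
            ##contig=<ID=1>
            ##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
            #CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ta\tb
            1\t1\tL1\tA\tG,T\t.\tPASS\t.\tGT\t0/1\t1/2
            1\t2\tL2\tA\tG\t.\tPASS\t.\tGT\t0/0\t1/1
        """)
        path = tmp_path / "t.vcf"
        path.write_text(vcf)
        G = sk.load_genotypes(path, "vcf", {"a": "x", "b": "x"})
        assert list(G.loci) == ["L2"]

    def test_matrix_na_reduces_called_alleles(self, tmp_path):
        path = tmp_path / "m.tsv"
        path.write_text("id\tL1\tL2\ni1\t2\tNA\ni2\t1\t0\ni3\t1\t1\n")
        G = sk.load_genotypes(path, "matrix", {"i1": "g", "i2": "g", "i3": "g"})
        st = sk.allele_frequencies(G)
        assert st.n["g"][0] == 6 and st.n["g"][1] == 4
        assert st.x["g"][1] == 1

    def test_group_map_errors(self, tmp_path):
        path = tmp_path / "m.tsv"
        path.write_text("id\tL1\ni1\t2\ni2\t1\n")
        with pytest.raises(ValueError, match="absent from data"):
            sk.load_genotypes(path, "matrix", {"i1": "g", "i2": "g", "ghost": "g"})
        with pytest.raises(ValueError, match="without a group"):
            sk.load_genotypes(path, "matrix", {"i1": "g"})

    def test_vcf_round_trip(self, tmp_path, small_cohort):
        G = sk.generate_read_depths(small_cohort.genotypes, 15, seed=3)
        sk.write_vcf(G, tmp_path / "c.vcf")
        sk.write_group_map(G, tmp_path / "g.tsv")
        G2 = sk.load_genotypes(tmp_path / "c.vcf", "vcf", tmp_path / "g.tsv")
        np.testing.assert_array_equal(G.calls, G2.calls)
        np.testing.assert_array_equal(G.groups, G2.groups)
        np.testing.assert_array_equal(G.tags, G2.tags)
        np.testing.assert_array_equal(G.allele_depths, G2.allele_depths)


# ---------------------------------------------------------------------------
# HWE exact test
# ---------------------------------------------------------------------------

def hwe_oracle(n_aa, n_ab, n_bb):
    """Exact-rational enumeration of the conditional HWE distribution.

    Unnormalized weight of h heterozygotes: n! 2^h / (aa! h! bb!).
    """
    from math import factorial
    n = n_aa + n_ab + n_bb
    na = 2 * n_aa + n_ab
    weights = {}
    for h in range(na % 2, min(na, 2 * n - na) + 1, 2):
        aa = (na - h) // 2
        bb = n - aa - h
        if bb < 0:
            continue
        weights[h] = Fraction(factorial(n) * 2 ** h,
                              factorial(aa) * factorial(h) * factorial(bb))
    total = sum(weights.values())
    p_obs = weights[n_ab] / total
    return float(sum(w for w in weights.values() if Fraction(w, total) <= p_obs) / total)


class TestHWE:
    @pytest.mark.parametrize("counts", [
        (25, 50, 25), (10, 5, 10), (0, 50, 0), (3, 1, 7), (0, 2, 18), (5, 0, 5),
    ])
    def test_matches_exact_rational_enumeration(self, counts):
        assert sk.hwe_exact_pvalue(*counts) == pytest.approx(hwe_oracle(*counts), rel=1e-9)

    def test_perfect_proportions_not_rejected(self):
        assert sk.hwe_exact_pvalue(25, 50, 25) > 0.999

    def test_all_heterozygous_rejected(self):
        assert sk.hwe_exact_pvalue(0, 50, 0) < 1e-3

    def test_monomorphic_is_one(self):
        assert sk.hwe_exact_pvalue(30, 0, 0) == 1.0


# ---------------------------------------------------------------------------
# filters
# ---------------------------------------------------------------------------

def _matrix_from_calls(calls, groups):
    calls = np.asarray(calls, dtype=np.int8)
    return sk.GenotypeMatrix(
        calls=calls,
        individuals=np.array([f"i{k}" for k in range(calls.shape[0])], dtype=object),
        loci=np.array([f"L{j}" for j in range(calls.shape[1])], dtype=object),
        groups=np.array(groups, dtype=object),
    )


class TestFilterLoci:
    def test_per_group_missingness_rule(self):
        # locus 0: 20% missing in group a only -> removed under per-group rule
        rng = np.random.default_rng(1)
        calls = rng.binomial(2, 0.5, size=(40, 2)).astype(np.int8)
        calls[:4, 0] = MISSING        # 4/20 missing within group a
        groups = ["a"] * 20 + ["b"] * 20
        G = _matrix_from_calls(calls, groups)
        filtered, rep = sk.filter_loci(G, max_missing_frac=0.10, maf_min=0.0,
                                       hwe_alpha=0.0)
        assert "L0" in set(rep.removed)
        assert "L1" in set(filtered.loci)

    def test_hwe_removes_all_het_locus(self):
        calls = np.ones((50, 1), dtype=np.int8)   # every individual heterozygous
        G = _matrix_from_calls(calls, ["a"] * 25 + ["b"] * 25)
        _, rep = sk.filter_loci(G, max_missing_frac=1.0, maf_min=0.0, hwe_alpha=1e-3)
        assert "L0" in set(rep.removed)

    def test_maf_threshold(self):
        calls = np.zeros((100, 1), dtype=np.int8)
        calls[0, 0] = 1               # pooled MAF = 1/200 = 0.005 < 0.01
        G = _matrix_from_calls(calls, ["a"] * 50 + ["b"] * 50)
        _, rep = sk.filter_loci(G, max_missing_frac=1.0, maf_min=0.01, hwe_alpha=0.0)
        assert "L0" in set(rep.removed)

    def test_idempotent(self, small_cohort):
        G = small_cohort.genotypes
        once, _ = sk.filter_loci(G)
        twice, rep2 = sk.filter_loci(once)
        assert rep2.n_removed == 0
        np.testing.assert_array_equal(once.calls, twice.calls)


class TestAlleleBalance:
    def _with_depths(self, het_depths, n_loci=1):
        n = len(het_depths)
        calls = np.ones((n, n_loci), dtype=np.int8)
        G = _matrix_from_calls(calls, ["a"] * n)
        depths = np.zeros((n, n_loci, 2), dtype=np.int64)
        for i, (r, alt) in enumerate(het_depths):
            depths[i, :, 0] = r
            depths[i, :, 1] = alt
        return sk.GenotypeMatrix(calls=G.calls, individuals=G.individuals,
                                 loci=G.loci, groups=G.groups, allele_depths=depths)

    def test_balanced_depths_retained(self):
        G = self._with_depths([(10, 10)] * 20)
        filtered, rep = sk.allele_balance_filter(G)
        assert rep.n_removed == 0

    def test_strong_bias_removed(self):
        G = self._with_depths([(17, 3)] * 20)
        _, rep = sk.allele_balance_filter(G)
        assert rep.n_removed == 1
        # oracle: t-test on slightly jittered constant ratios is overwhelming
        from scipy import stats
        ratios = np.full(20, 3 / 20) + np.linspace(-1e-6, 1e-6, 20)
        assert stats.ttest_1samp(ratios, 0.5, alternative="less").pvalue < 1e-6

    def test_single_heterozygote_passes_with_warning(self, caplog):
        G = self._with_depths([(2, 18)])
        with caplog.at_level("WARNING"):
            _, rep = sk.allele_balance_filter(G)
        assert rep.n_removed == 0
        assert any("untested" in w for w in rep.warnings)

    def test_requires_depths(self, tiny_matrix):
        with pytest.raises(ValueError, match="allele_depths"):
            sk.allele_balance_filter(tiny_matrix)


# ---------------------------------------------------------------------------
# allele frequencies
# ---------------------------------------------------------------------------

class TestAlleleFrequencies:
    def test_simple_counts(self):
        G = _matrix_from_calls([[2], [1], [1], [0]], ["g"] * 4)
        st = sk.allele_frequencies(G)
        assert st.x["g"][0] == 4 and st.n["g"][0] == 8
        assert st.p("g")[0] == 0.5

    def test_missing_reduces_n(self):
        G = _matrix_from_calls([[2], [1], [MISSING], [0]], ["g"] * 4)
        st = sk.allele_frequencies(G)
        assert st.n["g"][0] == 6

    def test_matches_bruteforce_and_conserves(self, small_cohort):
        G = small_cohort.genotypes
        st = sk.allele_frequencies(G)
        # brute-force per-cell summation oracle
        for g in G.group_names:
            sub = G.calls[G.groups == g]
            x = np.zeros(G.n_loci, dtype=int)
            n = np.zeros(G.n_loci, dtype=int)
            for i in range(sub.shape[0]):
                for j in range(sub.shape[1]):
                    if sub[i, j] != MISSING:
                        x[j] += sub[i, j]
                        n[j] += 2
            np.testing.assert_array_equal(st.x[g], x)
            np.testing.assert_array_equal(st.n[g], n)
        pooled = sum(st.x[g] for g in G.group_names)
        np.testing.assert_array_equal(st.x["pooled"], pooled)


# ---------------------------------------------------------------------------
# F_ST
# ---------------------------------------------------------------------------

def _wc_oracle(counts1, counts2):
    """Hand-coded Weir–Cockerham variance components for 2 populations.

    counts: per locus (n_aa, n_ab, n_bb) genotype counts.
    """
    a_s = b_s = c_s = 0.0
    for (c1, c2) in zip(counts1, counts2):
        n1 = sum(c1); n2 = sum(c2)
        p1 = (2 * c1[0] + c1[1]) / (2 * n1)
        p2 = (2 * c2[0] + c2[1]) / (2 * n2)
        h1 = c1[1] / n1; h2 = c2[1] / n2
        r = 2
        nbar = (n1 + n2) / 2
        nc = (r * nbar - (n1 ** 2 + n2 ** 2) / (r * nbar)) / (r - 1)
        pbar = (n1 * p1 + n2 * p2) / (r * nbar)
        if pbar in (0, 1):
            continue
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
        hbar = (n1 * h1 + n2 * h2) / (r * nbar)
        a = nbar / nc * (s2 - 1 / (nbar - 1) * (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4))
        b = nbar / (nbar - 1) * (pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar)
        c = hbar / 2
        a_s += a; b_s += b; c_s += c
    return a_s / (a_s + b_s + c_s)


class TestFst:
    def test_two_locus_toy_matches_hand_computation(self):
        counts1 = [(10, 5, 5), (2, 10, 8)]
        counts2 = [(4, 6, 10), (9, 8, 3)]
        rows = []
        groups = []
        for grp, counts in (("a", counts1), ("b", counts2)):
            cols = []
            for (aa, ab, bb) in counts:
                cols.append([2] * aa + [1] * ab + [0] * bb)
            block = np.array(cols).T
            rows.append(block)
            groups += [grp] * block.shape[0]
        G = _matrix_from_calls(np.vstack(rows), groups)
        est = sk.pairwise_fst(G, ("a", "b"))
        assert est == pytest.approx(_wc_oracle(counts1, counts2), abs=1e-12)

    def test_group_with_itself_is_zero(self, small_cohort):
        G = small_cohort.genotypes
        assert sk.pairwise_fst(G, ("larvae", "larvae")) == pytest.approx(0.0, abs=1e-12)

    def test_fixed_differences_give_one(self):
        calls = np.vstack([np.full((10, 5), 2), np.full((10, 5), 0)]).astype(np.int8)
        G = _matrix_from_calls(calls, ["a"] * 10 + ["b"] * 10)
        assert sk.pairwise_fst(G, ("a", "b")) == pytest.approx(1.0, abs=1e-12)

    def test_panmictic_near_zero(self):
        rng = np.random.default_rng(7)
        p = rng.uniform(0.1, 0.9, 400)
        calls = rng.binomial(2, p, size=(200, 400)).astype(np.int8)
        G = _matrix_from_calls(calls, ["a"] * 100 + ["b"] * 100)
        assert abs(sk.pairwise_fst(G, ("a", "b"))) < 0.005

    def test_monomorphic_everywhere_nan(self):
        calls = np.full((10, 3), 2, dtype=np.int8)
        G = _matrix_from_calls(calls, ["a"] * 5 + ["b"] * 5)
        assert np.isnan(sk.pairwise_fst(G, ("a", "b")))


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

class TestPCA:
    def test_two_clusters_separate_on_pc1(self):
        calls = np.vstack([np.tile([2, 2, 0, 0, 2], (8, 1)),
                           np.tile([0, 0, 2, 2, 0], (8, 1))]).astype(np.int8)
        G = _matrix_from_calls(calls, ["a"] * 8 + ["b"] * 8)
        res = sk.pca_coordinates(G)
        pc1 = res.coords["PC1"].to_numpy()
        assert np.ptp(pc1[:8]) < 1e-10 and np.ptp(pc1[8:]) < 1e-10
        assert abs(pc1[0] - pc1[8]) > 1.0

    def test_matches_eigendecomposition(self, small_cohort):
        G = small_cohort.genotypes
        res = sk.pca_coordinates(G, scale=False, n_components=3)
        X = G.calls.astype(float)
        X[X == MISSING] = np.nan
        mu = np.nanmean(X, axis=0)
        idx = np.where(np.isnan(X))
        X[idx] = mu[idx[1]]
        X -= mu
        cov = X.T @ X
        w, v = np.linalg.eigh(cov)
        order = np.argsort(w)[::-1]
        for k in range(3):
            proj = X @ v[:, order[k]]
            got = res.coords.iloc[:, k].to_numpy()
            assert (np.allclose(proj, got, atol=1e-8)
                    or np.allclose(proj, -got, atol=1e-8))

    def test_reordering_individuals_permutes_rows(self, small_cohort):
        G = small_cohort.genotypes
        perm = np.random.default_rng(5).permutation(G.n_individuals)
        G2 = sk.GenotypeMatrix(calls=G.calls[perm], individuals=G.individuals[perm],
                               loci=G.loci, groups=G.groups[perm])
        r1 = sk.pca_coordinates(G, n_components=2).coords
        r2 = sk.pca_coordinates(G2, n_components=2).coords
        np.testing.assert_allclose(r1.loc[r2.index].to_numpy(), r2.to_numpy(),
                                   atol=1e-8)

    def test_sign_convention_loading_sums_nonnegative(self, small_cohort):
        res = sk.pca_coordinates(small_cohort.genotypes, n_components=4)
        assert (res.loadings.sum(axis=1) >= -1e-10).all()

    def test_monomorphic_subset_errors(self):
        calls = np.full((6, 2), 1, dtype=np.int8)
        G = _matrix_from_calls(calls, ["a"] * 3 + ["b"] * 3)
        with pytest.raises(ValueError, match="monomorphic"):
            sk.pca_coordinates(G)
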