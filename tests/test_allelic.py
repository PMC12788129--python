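"""PSNPs, allele counting, TMM, dispersion, NB bias test, regression."""

import numpy as np
import pandas as pd
import pytest

from hybmeth import allelic
from hybmeth import formats_io as fio
from hybmeth._stats import nb_exact_test_vec


def trio_variants(rows):
    """rows: (pos, gt_mother, gt_father, gt_f1)."""
    return pd.DataFrame({
        "chrom": "chr1", "pos": [r[0] for r in rows],
        "ref": "A", "alt": "G",
        "gt_mother": [r[1] for r in rows],
        "gt_father": [r[2] for r in rows],
        "gt_f1": [r[3] for r in rows],
        "dp_mother": 10, "dp_father": 10, "dp_f1": 10})


GENES = pd.DataFrame({"gene_id": ["g1"], "chrom": ["chr1"],
                      "start": [100], "end": [500], "strand": ["+"]})


class TestPSNPs:
    def test_canonical_psnp_kept(self):
        v = trio_variants([(150, fio.HOM_REF, fio.HOM_ALT, fio.HET)])
        out = allelic.identify_psnps(v, GENES)
        assert len(out) == 1
        assert out.loc[0, "maternal_base"] == "A"
        assert out.loc[0, "paternal_base"] == "G"
        assert out.loc[0, "gene_id"] == "g1"

    @pytest.mark.parametrize("gm, gf, g1", [
        (fio.HOM_REF, fio.HOM_REF, fio.HOM_REF),   # parents identical
        (fio.HOM_REF, fio.HOM_ALT, fio.HOM_ALT),   # F1 not het
        (fio.HET, fio.HOM_ALT, fio.HET),           # mother not homozygous
        (fio.HOM_REF, fio.MISSING, fio.HET),       # father missing
    ])
    def test_non_psnp_rejected(self, gm, gf, g1):
        v = trio_variants([(150, gm, gf, g1)])
        assert len(allelic.identify_psnps(v, GENES)) == 0

    def test_intergenic_psnp_has_no_gene(self):
        v = trio_variants([(900, fio.HOM_REF, fio.HOM_ALT, fio.HET)])
        out = allelic.identify_psnps(v, GENES)
        assert out["gene_id"].isna().all()


class TestAggregate:
    def depths(self, rows):
        return pd.DataFrame({"chrom": "chr1", "pos": [r[0] for r in rows],
                             "maternal_reads": [r[1] for r in rows],
                             "paternal_reads": [r[2] for r in rows],
                             "sample": "f1"})

    def psnps(self, positions):
        return pd.DataFrame({"chrom": "chr1", "pos": positions,
                             "gene_id": "g1"})

    def test_single_psnp_passthrough(self):
        out = allelic.aggregate_allele_counts(self.depths([(150, 30, 10)]),
                                              self.psnps([150]))
        assert out.loc[0, "count_maternal"] == 30
        assert out.loc[0, "count_paternal"] == 10

    def test_two_psnp_mean(self):
        out = allelic.aggregate_allele_counts(
            self.depths([(150, 30, 10), (200, 10, 30)]),
            self.psnps([150, 200]))
        assert out.loc[0, "count_maternal"] == 20
        assert out.loc[0, "count_paternal"] == 20

    def test_zero_coverage_psnp_ignored(self):
        out = allelic.aggregate_allele_counts(
            self.depths([(150, 30, 10), (200, 0, 0)]),
            self.psnps([150, 200]))
        assert out.loc[0, "count_maternal"] == 30
        assert out.loc[0, "n_psnps"] == 1


class TestTMM:
    def test_identical_libraries_unit_factors(self):
        x = np.tile(np.arange(1, 101), (2, 1)).T
        np.testing.assert_allclose(allelic.tmm_factors(x), [1.0, 1.0])

    def test_doubled_library(self):
        rng = np.random.default_rng(0)
        a = rng.integers(10, 1000, 200).astype(float)
        x = np.column_stack([a, 2 * a])
        np.testing.assert_allclose(allelic.tmm_factors(x),
                                   [2 ** -0.5, 2 ** 0.5], rtol=1e-9)

    def test_gene_permutation_invariance(self):
        rng = np.random.default_rng(1)
        x = rng.integers(0, 500, size=(300, 2)).astype(float)
        f1 = allelic.tmm_factors(x)
        f2 = allelic.tmm_factors(x[rng.permutation(300)])
        np.testing.assert_allclose(f1, f2, rtol=1e-12)

    def test_geometric_mean_one(self):
        rng = np.random.default_rng(2)
        x = rng.integers(0, 500, size=(300, 3)).astype(float)
        f = allelic.tmm_factors(x)
        assert np.exp(np.mean(np.log(f))) == pytest.approx(1.0)

    def test_all_zero_library_rejected(self):
        with pytest.raises(ValueError):
            allelic.tmm_factors(np.column_stack([np.ones(30), np.zeros(30)]))


class TestDispersion:
    def test_poisson_pairs_give_near_zero(self):
        rng = np.random.default_rng(3)
        x = rng.poisson(300, size=(2000, 2)).astype(float)
        assert allelic.estimate_dispersion(x) < 0.01

    def test_nb_dispersion_recovered(self):
        rng = np.random.default_rng(4)
        phi, mu = 0.2, 300
        r = 1 / phi
        x = rng.negative_binomial(r, r / (r + mu), size=(2000, 2)).astype(float)
        est = allelic.estimate_dispersion(x)
        assert abs(est - phi) < 0.05

    def test_identical_pairs_floored_at_zero(self):
        x = np.tile([[100.0, 100.0]], (30, 1))
        assert allelic.estimate_dispersion(x) == 0.0

    def test_too_few_genes_errors(self):
        with pytest.raises(ValueError, match="fixed dispersion"):
            allelic.estimate_dispersion(np.ones((10, 2)))


class TestBiasTest:
    def test_balanced_counts_none(self):
        out = allelic.allelic_bias_test(np.array([100]), np.array([100]))
        assert out.loc[0, "klass"] == allelic.NO_BIAS

    def test_three_fold_maternal_bias(self):
        out = allelic.allelic_bias_test(np.array([300]), np.array([100]),
                                        dispersion=0.05)
        assert out.loc[0, "klass"] == allelic.MATERNAL_BIAS

    def test_fold_below_threshold_never_called(self):
        out = allelic.allelic_bias_test(np.array([130]), np.array([100]),
                                        dispersion=0.0)
        assert out.loc[0, "klass"] == allelic.NO_BIAS

    def test_both_zero_is_null(self):
        out = allelic.allelic_bias_test(np.array([0]), np.array([0]))
        assert out.loc[0, "p_value"] == 1.0
        assert out.loc[0, "klass"] == allelic.NO_BIAS

    def test_poisson_case_matches_binomial_oracle(self):
        # dispersion 0: conditional law is Binomial(n, 1/2); compare to an
        # exact enumeration of the two-sided min-likelihood sum
        from math import comb
        for x1, x2 in [(10, 3), (30, 20), (5, 5), (0, 7)]:
            n = x1 + x2
            probs = [comb(n, k) * 0.5 ** n for k in range(n + 1)]
            p_expected = sum(p for p in probs if p <= probs[x1] * (1 + 1e-7))
            got = nb_exact_test_vec(np.array([x1]), np.array([x2]), 0.0)[0]
            assert got == pytest.approx(min(1.0, p_expected), rel=1e-9)

    def test_nb_case_matches_direct_enumeration(self):
        from scipy.stats import nbinom
        phi = 0.1
        x1, x2 = 90, 40
        n = x1 + x2
        mu = n / 2
        r = 1 / phi
        pmf = nbinom.pmf(np.arange(n + 1), r, r / (r + mu))
        joint = pmf * pmf[::-1]
        joint = joint / joint.sum()
        expected = joint[joint <= joint[x1] * (1 + 1e-7)].sum()
        got = nb_exact_test_vec(np.array([x1]), np.array([x2]), phi)[0]
        assert got == pytest.approx(expected, rel=1e-9)

    def test_label_swap_symmetry(self):
        rng = np.random.default_rng(6)
        cm = rng.integers(0, 600, 200)
        cp = rng.integers(0, 600, 200)
        a = allelic.allelic_bias_test(cm, cp, dispersion=0.1)
        b = allelic.allelic_bias_test(cp, cm, dispersion=0.1)
        np.testing.assert_allclose(a["p_value"], b["p_value"], rtol=1e-9)
        swap = {allelic.MATERNAL_BIAS: allelic.PATERNAL_BIAS,
                allelic.PATERNAL_BIAS: allelic.MATERNAL_BIAS,
                allelic.NO_BIAS: allelic.NO_BIAS}
        assert list(b["klass"]) == [swap[k] for k in a["klass"]]


class TestRegression:
    def test_perfect_line(self):
        x = np.array([10, 100, 1000, 5000])
        fit = allelic.allelic_total_regression(x, x)
        assert fit["slope"] == pytest.approx(1.0)
        assert fit["intercept"] == pytest.approx(0.0, abs=1e-12)
        assert fit["r_squared"] == pytest.approx(1.0)

    def test_fair_split_gives_slope_one_intercept_minus_one(self):
        # each allele ~ half the total: log2(allele) ~ log2(total) - 1
        rng = np.random.default_rng(7)
        total = rng.integers(100, 5000, 500)
        allele = rng.binomial(total, 0.5)
        fit = allelic.allelic_total_regression(allele, total)
        assert fit["slope"] == pytest.approx(1.0, abs=0.03)
        assert fit["intercept"] == pytest.approx(-1.0, abs=0.25)
        assert fit["r_squared"] > 0.97

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            allelic.allelic_total_regression([1, 2], [1, 2])


class TestSummary:
    def test_empty_zeroes(self):
        out = allelic.bias_summary(pd.DataFrame(columns=["klass", "log2_fold",
                                                         "p_value"]))
        assert out["counts"]["biased_total"] == 0

    def test_counts_conserved(self):
        calls = pd.DataFrame({
            "klass": [allelic.MATERNAL_BIAS, allelic.PATERNAL_BIAS,
                      allelic.NO_BIAS, allelic.MATERNAL_BIAS],
            "log2_fold": [1.0, -1.2, 0.1, 2.0],
            "p_value": [1e-4, 1e-3, 0.5, 1e-6]})
        out = allelic.bias_summary(calls)
        c = out["counts"]
        assert c["biased_total"] == c[allelic.MATERNAL_BIAS] + c[allelic.PATERNAL_BIAS]
        assert len(out["volcano"]) == 4
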