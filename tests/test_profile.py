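"""Global profile operations: levels, caller, proportions, metaplots, conversion."""

import numpy as np
import pandas as pd
import pytest

from hybmeth import profile
from hybmeth.formats_io import MethCallRecord

from conftest import make_meth_frame


class TestLevelAndMPV:
    @pytest.mark.parametrize("mc, total, expected", [
        (3, 10, 0.3), (0, 5, 0.0), (7, 7, 1.0)])
    def test_methylation_level(self, mc, total, expected):
        rec = MethCallRecord("chr1", 1, "+", "CG", mc, total)
        assert profile.methylation_level(rec) == pytest.approx(expected)

    def test_zero_coverage_undefined(self):
        rec = MethCallRecord("chr1", 1, "+", "CG", 0, 0)
        with pytest.raises(ValueError):
            profile.methylation_level(rec)

    @pytest.mark.parametrize("a, b, expected", [
        (0.2, 0.4, 0.3), (0.7, 0.7, 0.7), (0.0, 1.0, 0.5)])
    def test_mid_parent_value(self, a, b, expected):
        assert profile.mid_parent_value(a, b) == pytest.approx(expected)


class TestMethylatedSiteCaller:
    def make(self, mc, total):
        return make_meth_frame([("chr1", 1, "+", "CG", mc, total)])

    def test_zero_mc_never_methylated(self):
        assert len(profile.call_methylated_sites(self.make(0, 10), 0.006)) == 0

    def test_fully_methylated_called(self):
        # p = P(X >= 10 | n=10, 0.006) = 0.006^10, far below alpha
        out = profile.call_methylated_sites(self.make(10, 10), 0.006, 0.05)
        assert len(out) == 1

    def test_single_read_not_significant(self):
        # p = 1 - 0.994^10 ~ 0.0584 > 0.05
        p_exact = 1 - 0.994 ** 10
        assert p_exact > 0.05
        out = profile.call_methylated_sites(self.make(1, 10), 0.006, 0.05)
        assert len(out) == 0

    def test_caller_matches_closed_form_tail(self):
        # oracle: sum of binomial pmf terms for a handful of configurations
        from math import comb
        for mc, total in [(2, 15), (3, 20), (5, 12)]:
            f = 0.006
            tail = sum(comb(total, k) * f**k * (1 - f)**(total - k)
                       for k in range(mc, total + 1))
            called = len(profile.call_methylated_sites(
                self.make(mc, total), f, alpha=0.05)) == 1
            assert called == (tail <= 0.05)


class TestContextProportions:
    def test_equal_counts_give_thirds(self):
        df = make_meth_frame([("chr1", i + 1, "+", ctx, 1, 1)
                              for i, ctx in enumerate(["CG", "CHG", "CHH"])])
        out = profile.context_proportions(df)
        assert np.allclose(out["proportion"], 1 / 3)

    def test_proportions_sum_to_one_and_counts_conserved(self, small_dataset):
        called = profile.call_methylated_sites(small_dataset["f1"])
        out = profile.context_proportions(called)
        assert out["proportion"].sum() == pytest.approx(1.0, abs=1e-12)
        assert out["mc_sites"].sum() == len(called)

    def test_empty_input_errors(self):
        with pytest.raises(ValueError):
            profile.context_proportions(make_meth_frame([]))


class TestChromosomeLevels:
    def test_two_site_mean(self):
        df = make_meth_frame([("chr1", 1, "+", "CG", 2, 10),
                              ("chr1", 5, "+", "CG", 4, 10)])
        out = profile.chromosome_mean_levels(df, "CG", min_cov=1)
        assert out["chr1"] == pytest.approx(0.3)

    def test_all_ones(self):
        df = make_meth_frame([("chr1", i, "+", "CG", 5, 5) for i in (1, 2, 3)])
        assert profile.chromosome_mean_levels(df, "CG")["chr1"] == 1.0

    def test_uncovered_chromosome_missing(self):
        df = make_meth_frame([("chr1", 1, "+", "CG", 2, 10),
                              ("chr2", 1, "+", "CG", 0, 1)])
        out = profile.chromosome_mean_levels(df, "CG", min_cov=4)
        assert "chr2" not in out.index

    def test_simulated_mean_near_truth(self, small_dataset):
        # compare to the mean of true F1 propensities (sampling error ~1e-3)
        truth = small_dataset["truth"].sites
        cg = truth[truth["context"] == "CG"]
        expected = np.nanmean((cg["p_f1_maternal"] + cg["p_f1_paternal"]) / 2)
        got = profile.chromosome_mean_levels(small_dataset["f1"], "CG")["chr1"]
        assert abs(got - expected) < 0.02

    def test_f1_between_parents_when_fully_additive(self):
        from hybmeth.simulate import (SimulationConfig, simulate_methylomes,
                                      simulate_parental_genomes)
        cfg = SimulationConfig(seed=21, n_chromosomes=1, chrom_length=40_000,
                               n_genes=5, mode_weights={"additive": 1.0})
        rng = np.random.default_rng(cfg.seed)
        genomes, variants, _ = simulate_parental_genomes(cfg, rng)
        meth = simulate_methylomes(cfg, genomes, variants, rng)
        for ctx in ("CG", "CHH"):
            m = profile.chromosome_mean_levels(meth["mother"], ctx)["chr1"]
            f = profile.chromosome_mean_levels(meth["father"], ctx)["chr1"]
            f1 = profile.chromosome_mean_levels(meth["f1"], ctx)["chr1"]
            lo, hi = sorted([m, f])
            assert lo - 0.01 <= f1 <= hi + 0.01


class TestConversionRate:
    def test_direct_formula(self):
        df = make_meth_frame([("lambda", 1, "+", "CHH", 6, 1000)])
        assert profile.conversion_rate(df) == pytest.approx(0.994)

    def test_no_mc_gives_one(self):
        df = make_meth_frame([("lambda", 1, "+", "CHH", 0, 500)])
        assert profile.conversion_rate(df) == 1.0

    def test_zero_coverage_errors(self):
        df = make_meth_frame([("lambda", 1, "+", "CHH", 0, 0)])
        with pytest.raises(ValueError):
            profile.conversion_rate(df)


class TestMetaplot:
    def _uniform(self, level=0.5, n=2000, mc=5, total=10):
        rows = [("chr1", p, "+", "CG", mc, total) for p in range(1, n + 1, 3)]
        return make_meth_frame(rows)

    def _genes(self, strand="+"):
        return pd.DataFrame({"gene_id": ["g1"], "chrom": ["chr1"],
                             "start": [800], "end": [1400], "strand": [strand]})

    def test_uniform_levels_give_flat_profile(self):
        out = profile.metaplot_profile(self._uniform(), self._genes(),
                                       "CG", flank_bp=500, n_bins=5)
        covered = out[out["n_sites"] > 0]
        assert np.allclose(covered["mean_level"], 0.5)

    def test_minus_strand_is_reverse_of_plus(self):
        # gradient of levels: minus-strand profile mirrors the plus profile
        rows = [("chr1", p, "+", "CG", min(10, p // 200), 10)
                for p in range(1, 2001, 7)]
        meth = make_meth_frame(rows)
        plus = profile.metaplot_profile(meth, self._genes("+"), "CG", 500, 5)
        minus = profile.metaplot_profile(meth, self._genes("-"), "CG", 500, 5)
        np.testing.assert_allclose(plus["mean_level"].to_numpy(),
                                   minus["mean_level"].to_numpy()[::-1],
                                   rtol=1e-9)

    def test_elevated_flanks_exceed_body(self):
        rows = []
        for p in range(1, 2001, 3):
            inside = 800 <= p <= 1400
            rows.append(("chr1", p, "+", "CG", 2 if inside else 9, 10))
        meth = make_meth_frame(rows)
        out = profile.metaplot_profile(meth, self._genes(), "CG", 500, 5)
        body = out[out["region"] == "body"]["mean_level"].mean()
        up = out[out["region"] == "upstream"]["mean_level"].mean()
        down = out[out["region"] == "downstream"]["mean_level"].mean()
        assert up > body and down > body


class TestElementLevels:
    def test_single_element_mean(self):
        meth = make_meth_frame([("chr1", 10, "+", "CG", 9, 10),
                                ("chr1", 20, "+", "CG", 7, 10)])
        beds = {"island": pd.DataFrame({"chrom": ["chr1"], "start": [1],
                                        "end": [100]})}
        out = profile.element_levels(meth, beds, "CG", min_cov=1)
        assert out["island"] == pytest.approx(0.8)

    def test_partition_conserves_genome_mean(self):
        rows = [("chr1", p, "+", "CG", p % 11, 10) for p in range(1, 101)]
        meth = make_meth_frame(rows)
        beds = {"left": pd.DataFrame({"chrom": ["chr1"], "start": [1], "end": [50]}),
                "right": pd.DataFrame({"chrom": ["chr1"], "start": [51],
                                       "end": [100]})}
        out = profile.element_levels(meth, beds, "CG", min_cov=1)
        genome_mean = (meth["mc_count"] / meth["total_count"]).mean()
        weighted = (out["left"] * 50 + out["right"] * 50) / 100
        assert weighted == pytest.approx(genome_mean)

    def test_site_in_two_classes_counted_in_both(self):
        meth = make_meth_frame([("chr1", 10, "+", "CG", 5, 10)])
        beds = {"a": pd.DataFrame({"chrom": ["chr1"], "start": [1], "end": [20]}),
                "b": pd.DataFrame({"chrom": ["chr1"], "start": [5], "end": [15]})}
        out = profile.element_levels(meth, beds, "CG", min_cov=1)
        assert out["a"] == out["b"] == pytest.approx(0.5)

    def test_empty_class_missing(self):
        meth = make_meth_frame([("chr1", 10, "+", "CG", 5, 10)])
        beds = {"far": pd.DataFrame({"chrom": ["chr2"], "start": [1], "end": [9]})}
        out = profile.element_levels(meth, beds, "CG", min_cov=1)
        assert np.isnan(out["far"])
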