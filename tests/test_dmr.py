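"""Window construction, Fisher window tests, DMR merging, inheritance logic."""

from math import comb

import numpy as np
import pandas as pd
import pytest

from hybmeth import dmr

from conftest import make_meth_frame


def hypergeom_two_sided(mc_a, tot_a, mc_b, tot_b):
    """Enumeration oracle: min-likelihood two-sided Fisher p."""
    N, K, n = tot_a + tot_b, mc_a + mc_b, tot_a
    denom = comb(N, n)
    probs = {k: comb(K, k) * comb(N - K, n - k) / denom
             for k in range(max(0, K - (N - n)), min(K, n) + 1)}
    p_obs = probs[mc_a]
    return min(1.0, sum(p for p in probs.values() if p <= p_obs * (1 + 1e-7)))


def meth_pair(site_specs):
    """site_specs: (pos, mc_a, tot_a, mc_b, tot_b) all CG plus-strand chr1."""
    a = make_meth_frame([("chr1", p, "+", "CG", ma, ta)
                         for p, ma, ta, mb, tb in site_specs])
    b = make_meth_frame([("chr1", p, "+", "CG", mb, tb)
                         for p, ma, ta, mb, tb in site_specs])
    return a, b


class TestWindows:
    def test_no_covered_sites_no_windows(self):
        a, b = meth_pair([(100, 1, 2, 1, 2)])  # below min_cov 4
        assert len(dmr.make_windows(a, b, "CG")) == 0

    def test_five_sites_in_span_yield_window(self):
        a, b = meth_pair([(100 + i * 50, 5, 10, 5, 10) for i in range(5)])
        w = dmr.make_windows(a, b, "CG", 1000, 100, min_sites=5)
        assert len(w) >= 1
        assert (w["site_count"] >= 5).all()

    def test_step_equal_window_disjoint(self):
        a, b = meth_pair([(i, 5, 10, 5, 10) for i in range(1, 3000, 10)])
        w = dmr.make_windows(a, b, "CG", 1000, 1000, min_sites=5)
        assert (w["start"].to_numpy()[1:] > w["end"].to_numpy()[:-1]).all()

    def test_coverage_required_in_both_samples(self):
        a = make_meth_frame([("chr1", 100, "+", "CG", 5, 10)])
        b = make_meth_frame([("chr1", 100, "+", "CG", 0, 2)])
        assert len(dmr.make_windows(a, b, "CG", min_sites=1)) == 0


class TestWindowTest:
    def test_extreme_table_matches_enumeration(self):
        # pooled (10 mC, 0 uC) vs (0 mC, 10 uC): p = 2 / C(20, 10)
        w = pd.Series({"mc_a": 10, "total_a": 10, "mc_b": 0, "total_b": 10})
        p, fold, (la, lb) = dmr.test_window(w)
        assert p == pytest.approx(2 / comb(20, 10))
        assert (la, lb) == (1.0, 0.0)

    def test_identical_counts_null(self):
        w = pd.Series({"mc_a": 5, "total_a": 10, "mc_b": 5, "total_b": 10})
        p, fold, _ = dmr.test_window(w)
        assert p == 1.0
        assert fold == pytest.approx(1.0)

    def test_fold_two_case(self):
        w = pd.Series({"mc_a": 50, "total_a": 100, "mc_b": 25, "total_b": 100})
        p, fold, (la, lb) = dmr.test_window(w)
        assert fold == pytest.approx((0.5 + dmr.EPS) / (0.25 + dmr.EPS))
        assert p == pytest.approx(hypergeom_two_sided(50, 100, 25, 100))

    def test_zero_total_rejected(self):
        w = pd.Series({"mc_a": 0, "total_a": 0, "mc_b": 5, "total_b": 10})
        with pytest.raises(ValueError):
            dmr.test_window(w)


class TestCallDmrs:
    def differential(self, n=40, spacing=30, mc_a=9, mc_b=0, total=10):
        return meth_pair([(1000 + i * spacing, mc_a, total, mc_b, total)
                          for i in range(n)])

    def test_overlapping_significant_windows_merge(self):
        a, b = self.differential()
        out = dmr.call_dmrs(a, b, "CG")
        assert len(out) == 1
        assert out.loc[0, "direction"] == "a>b"
        assert (out["fold_change"] >= 2).all()
        assert (out["p_value"] <= 0.05).all()
        assert (out["site_count"] >= 5).all()

    def test_opposite_directions_not_merged(self):
        specs = [(1000 + i * 30, 9, 10, 0, 10) for i in range(20)]
        specs += [(3000 + i * 30, 0, 10, 9, 10) for i in range(20)]
        a, b = meth_pair(specs)
        out = dmr.call_dmrs(a, b, "CG")
        assert len(out) == 2
        assert set(out["direction"]) == {"a>b", "a<b"}

    def test_merging_idempotent_and_order_free(self):
        a, b = self.differential()
        out1 = dmr.call_dmrs(a, b, "CG")
        # shuffling input site order must not change the DMR set
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(a))
        out2 = dmr.call_dmrs(a.iloc[perm].reset_index(drop=True),
                             b.iloc[perm].reset_index(drop=True), "CG")
        pd.testing.assert_frame_equal(out1, out2)

    def test_null_data_yields_no_dmrs(self):
        a, b = meth_pair([(1000 + i * 30, 5, 10, 5, 10) for i in range(50)])
        assert len(dmr.call_dmrs(a, b, "CG")) == 0

    def test_power_on_engineered_region(self):
        # one strongly differential region at 15x coverage is detected
        from hybmeth.simulate import (SimulationConfig, simulate_methylomes,
                                      simulate_parental_genomes)
        hits = 0
        for seed in range(5):
            cfg = SimulationConfig(seed=seed, n_chromosomes=1,
                                   chrom_length=30_000, n_genes=3,
                                   parent_region_diff_prob=0.0,
                                   parent_site_diff_prob=0.0,
                                   mode_weights={"additive": 1.0})
            rng = np.random.default_rng(cfg.seed)
            genomes, variants, _ = simulate_parental_genomes(cfg, rng)
            meth = simulate_methylomes(cfg, genomes, variants, rng)
            mother, father = meth["mother"], meth["father"].copy()
            # engineer a Delta-level ~0.6 region: father unmethylated in 10-15kb
            mask = (father["pos"] >= 10_000) & (father["pos"] <= 15_000) \
                & (father["context"] == "CG")
            father.loc[mask, "mc_count"] = np.minimum(father.loc[mask, "mc_count"], 0)
            out = dmr.call_dmrs(mother, father, "CG")
            hit = ((out["start"] <= 15_000) & (out["end"] >= 10_000)).any()
            hits += int(hit)
        assert hits == 5


class TestInheritance:
    @staticmethod
    def df(rows):
        return pd.DataFrame(rows, columns=["chrom", "start", "end", "direction"])

    def test_like_father_rule(self):
        # mother > father; F1 differs from mother in father's direction
        parental = self.df([("chr1", 100, 200, "a>b")])
        f1_vs_mother = self.df([("chr1", 150, 250, "a<b")])  # F1 below mother
        f1_vs_father = self.df([])
        calls, _ = dmr.classify_dmr_inheritance(parental, f1_vs_father,
                                                f1_vs_mother)
        assert calls.loc[0, "category"] == dmr.LIKE_FATHER

    def test_both_comparisons_unresolved(self):
        parental = self.df([("chr1", 100, 200, "a>b")])
        f1_vs_mother = self.df([("chr1", 150, 250, "a<b")])
        f1_vs_father = self.df([("chr1", 120, 180, "a>b")])
        calls, _ = dmr.classify_dmr_inheritance(parental, f1_vs_father,
                                                f1_vs_mother)
        assert calls.loc[0, "category"] == dmr.UNRESOLVED

    def test_parent_label_swap_swaps_categories(self):
        parental = self.df([("chr1", 100, 200, "a>b"),
                            ("chr1", 500, 600, "a<b")])
        f1_vs_mother = self.df([("chr1", 150, 250, "a<b")])
        f1_vs_father = self.df([("chr1", 520, 580, "a<b")])
        calls, _ = dmr.classify_dmr_inheritance(parental, f1_vs_father,
                                                f1_vs_mother)
        # swap: parental directions flip, comparison roles exchange
        swapped_parental = parental.assign(
            direction=parental["direction"].map({"a>b": "a<b", "a<b": "a>b"}))
        calls_sw, _ = dmr.classify_dmr_inheritance(swapped_parental,
                                                   f1_vs_mother, f1_vs_father)
        swap = {dmr.LIKE_FATHER: dmr.LIKE_MOTHER,
                dmr.LIKE_MOTHER: dmr.LIKE_FATHER,
                dmr.UNRESOLVED: dmr.UNRESOLVED}
        assert list(calls_sw["category"]) == [swap[c] for c in calls["category"]]

    def test_venn_counts_partition_clusters(self):
        parental = self.df([("chr1", 100, 200, "a>b"),
                            ("chr1", 1000, 1100, "a>b")])
        f1_vs_mother = self.df([("chr1", 150, 250, "a<b")])
        f1_vs_father = self.df([("chr1", 5000, 5100, "a>b")])
        _, venn = dmr.classify_dmr_inheritance(parental, f1_vs_father,
                                               f1_vs_mother)
        total_clusters = venn["count"].sum()
        assert total_clusters == 3  # {100-250 shared}, {1000-1100}, {5000-5100}
        shared = venn[(venn["parental"]) & (venn["f1_vs_mother"])
                      & (~venn["f1_vs_father"])]
        assert shared["count"].iloc[0] == 1


class TestTransmittedFraction:
    def test_zero_of_n(self):
        calls = pd.DataFrame({"category": [dmr.UNRESOLVED] * 10})
        assert dmr.transmitted_fraction(calls, dmr.LIKE_FATHER) == 0.0

    def test_simple_fraction(self):
        calls = pd.DataFrame({"category": [dmr.LIKE_FATHER] * 3
                              + [dmr.UNRESOLVED] * 7})
        assert dmr.transmitted_fraction(calls, dmr.LIKE_FATHER) == 30.0

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            dmr.transmitted_fraction(pd.DataFrame({"category": []}), dmr.LIKE_FATHER)
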