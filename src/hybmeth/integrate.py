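"""Joining PSMS gene sets with allelic-expression bias calls.

Per gene the PSMSs are split by origin parent; genes with PSMSs of both
origins are BIPARENTAL, otherwise MATERNAL_ONLY / PATERNAL_ONLY.  The
methylation level of each parental allele is the per-PSMS mC/C of the F1
reads carrying the cytosine allele; the two alleles' level lists (different
positions, hence unpaired) are compared with a two-sided rank-sum test on
all eligible genes and with Welch's t-test on the subset where both lists
pass a Shapiro normality screen (p > 0.05).  Summary tables reproduce the
cross-tabulations of bias class by PSMS origin, the co-regulation Venn
split by bias stratum, and the monoallelic-methylation-vs-expression 2x2.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .allelic import MATERNAL_BIAS, NO_BIAS, PATERNAL_BIAS

BIPARENTAL = "BIPARENTAL"
MATERNAL_ONLY = "MATERNAL_ONLY"
PATERNAL_ONLY = "PATERNAL_ONLY"


def _pct(count: int, total: int) -> float:
    return round(100.0 * count / total, 2)


def allelic_methylation_test(levels_a, levels_b, method: str = "wilcoxon",
                             min_sites: int = 3) -> float:
    """Compare two alleles' per-PSMS methylation level lists.

    ``wilcoxon``: two-sided rank-sum (mid-ranks for ties); ``ttest``:
    Welch's two-sided t.  Returns NaN when either list has fewer than
    ``min_sites`` observations.
    """
    a = np.asarray(levels_a, dtype=float)
    b = np.asarray(levels_b, dtype=float)
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    if len(a) < min_sites or len(b) < min_sites:
        return float("nan")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return 1.0  # identical constant lists: no evidence of difference
    if method == "wilcoxon":
        # small samples: exact permutation enumeration (valid under ties);
        # larger ones: scipy's default (exact when tie-free, else normal
        # approximation with tie correction)
        kwargs = {}
        if len(a) + len(b) <= 12:
            kwargs["method"] = stats.PermutationMethod()
        return float(stats.mannwhitneyu(a, b, alternative="two-sided",
                                        **kwargs).pvalue)
    if method == "ttest":
        if np.all(a == a[0]) and np.all(b == b[0]):
            return 0.0 if a[0] != b[0] else 1.0
        return float(stats.ttest_ind(a, b, equal_var=False).pvalue)
    raise ValueError(f"unknown method {method!r}")


def _allele_levels(gene_psms: pd.DataFrame, f1_allele_meth: pd.DataFrame,
                   origin: str) -> np.ndarray:
    """Per-PSMS F1 methylation levels on the cytosine-carrying allele."""
    allele = "maternal" if origin == "mother" else "paternal"
    sub = gene_psms[gene_psms["origin"] == origin]
    if len(sub) == 0:
        return np.array([])
    j = sub.merge(f1_allele_meth[f1_allele_meth["allele"] == allele],
                  on=["chrom", "pos", "strand"], how="left")
    j = j[j["total_count"] > 0]
    return (j["mc_count"] / j["total_count"]).to_numpy()


def build_gene_table(psms_assigned: pd.DataFrame, f1_allele_meth: pd.DataFrame,
                     bias_calls: pd.DataFrame, min_sites: int = 3,
                     shapiro_alpha: float = 0.05) -> pd.DataFrame:
    """One integration record per gene with >= 1 assigned PSMS.

    Combines PSMS origin counts, mean allelic methylation at PSMSs,
    rank-sum and (normality-screened) Welch p-values, and the gene's
    expression bias class (genes absent from ``bias_calls`` get NaN class
    and are excluded from bias-stratified summaries).
    """
    bias = bias_calls.set_index("gene_id") if len(bias_calls) else None
    rows = []
    for gene_id, sub in psms_assigned.groupby("gene_id", sort=True):
        n_mat = int((sub["origin"] == "mother").sum())
        n_pat = int((sub["origin"] == "father").sum())
        if n_mat and n_pat:
            category = BIPARENTAL
        elif n_mat:
            category = MATERNAL_ONLY
        else:
            category = PATERNAL_ONLY
        lev_m = _allele_levels(sub, f1_allele_meth, "mother")
        lev_p = _allele_levels(sub, f1_allele_meth, "father")
        mean_m = float(np.mean(lev_m)) if len(lev_m) else float("nan")
        mean_p = float(np.mean(lev_p)) if len(lev_p) else float("nan")
        wilcoxon_p = allelic_methylation_test(lev_m, lev_p, "wilcoxon", min_sites)
        ttest_p = float("nan")
        if len(lev_m) >= min_sites and len(lev_p) >= min_sites:
            if _normalish(lev_m, shapiro_alpha) and _normalish(lev_p, shapiro_alpha):
                ttest_p = allelic_methylation_test(lev_m, lev_p, "ttest", min_sites)
        klass = np.nan
        if bias is not None and gene_id in bias.index:
            klass = bias.loc[gene_id, "klass"]
        rows.append((gene_id, n_mat, n_pat, mean_m, mean_p, wilcoxon_p,
                     ttest_p, klass, category))
    return pd.DataFrame(rows, columns=[
        "gene_id", "n_psms_maternal", "n_psms_paternal",
        "mean_meth_maternal", "mean_meth_paternal",
        "wilcoxon_p", "ttest_p", "bias_klass", "category"])


def _normalish(x: np.ndarray, alpha: float) -> bool:
    if len(x) < 3 or np.all(x == x[0]):
        return False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            return stats.shapiro(x).pvalue > alpha
        except ValueError:
            return False


def cross_tabulate(gene_table: pd.DataFrame, origin: str) -> pd.DataFrame:
    """Bias-class counts among genes with >= 1 PSMS of the given origin.

    Returns rows (no-bias, maternal-bias, paternal-bias) with counts and
    percentages rounded to 2 dp.
    """
    col = "n_psms_maternal" if origin == "mother" else "n_psms_paternal"
    sub = gene_table[(gene_table[col] > 0) & gene_table["bias_klass"].notna()]
    if len(sub) == 0:
        raise ValueError("no genes join the bias calls for this origin")
    total = len(sub)
    rows = []
    for label, klass in (("no_bias", NO_BIAS), ("maternal_bias", MATERNAL_BIAS),
                         ("paternal_bias", PATERNAL_BIAS)):
        n = int((sub["bias_klass"] == klass).sum())
        rows.append((label, n, _pct(n, total)))
    return pd.DataFrame(rows, columns=["bias", "count", "percent"])


def coregulation_sets(gene_table: pd.DataFrame) -> pd.DataFrame:
    """Regulation-category counts within each expression-bias stratum."""
    sub = gene_table[gene_table["bias_klass"].notna()]
    strata = [("unbiased", sub[sub["bias_klass"] == NO_BIAS]),
              ("biased", sub[sub["bias_klass"].isin([MATERNAL_BIAS,
                                                     PATERNAL_BIAS])])]
    rows = []
    for name, s in strata:
        total = len(s)
        for cat in (BIPARENTAL, MATERNAL_ONLY, PATERNAL_ONLY):
            n = int((s["category"] == cat).sum())
            rows.append((name, cat, n, _pct(n, total) if total else 0.0))
    return pd.DataFrame(rows, columns=["stratum", "category", "count", "percent"])


def significant_fraction(gene_table: pd.DataFrame, method: str = "ttest",
                         alpha: float = 0.05) -> tuple[float, int, int]:
    """Percentage (2 dp) of tested genes with allelic-methylation p < alpha.

    Returns ``(percent, n_significant, n_tested)`` for the chosen test.
    """
    col = {"wilcoxon": "wilcoxon_p", "ttest": "ttest_p"}.get(method)
    if col is None:
        raise ValueError(f"unknown method {method!r}")
    tested = gene_table[gene_table[col].notna()]
    n = len(tested)
    if n == 0:
        return 0.0, 0, 0
    sig = int((tested[col] < alpha).sum())
    return _pct(sig, n), sig, n


def monoallelic_summary(gene_table: pd.DataFrame,
                        bias_calls: pd.DataFrame | None = None) -> pd.DataFrame:
    """2x2 of monoallelic-methylation origin vs expression dominance.

    Restricted to biased genes whose PSMSs come from a single parent.
    Returns one row per (methylation origin, expression bias) cell with
    counts and within-origin percentages.
    """
    sub = gene_table[gene_table["bias_klass"].isin([MATERNAL_BIAS, PATERNAL_BIAS])]
    rows = []
    for cat, meth_origin in ((MATERNAL_ONLY, "maternal"),
                             (PATERNAL_ONLY, "paternal")):
        s = sub[sub["category"] == cat]
        total = len(s)
        for klass, label in ((MATERNAL_BIAS, "maternal_dominant"),
                             (PATERNAL_BIAS, "paternal_dominant")):
            n = int((s["bias_klass"] == klass).sum())
            rows.append((meth_origin, label, n,
                         _pct(n, total) if total else 0.0))
    return pd.DataFrame(rows, columns=["methylation_origin",
                                       "expression_dominance", "count", "percent"])


def expression_matrix(gene_table: pd.DataFrame,
                      bias_calls: pd.DataFrame) -> pd.DataFrame:
    """Normalized allele-expression matrix for monoallelically methylated, biased genes."""
    sub = gene_table[
        gene_table["bias_klass"].isin([MATERNAL_BIAS, PATERNAL_BIAS])
        & gene_table["category"].isin([MATERNAL_ONLY, PATERNAL_ONLY])]
    cols = ["gene_id", "norm_maternal", "norm_paternal"]
    mat = bias_calls[cols].merge(sub[["gene_id", "category"]], on="gene_id")
    return mat.sort_values(["category", "gene_id"]).reset_index(drop=True)
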