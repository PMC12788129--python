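"""PSNP identification, allele counting, TMM normalization and AEI calling.

Parent-specific SNPs (PSNPs) are biallelic sites where the parents are
homozygous for different alleles and the F1 is heterozygous for exactly
those two; they let RNA reads be assigned to a parental allele.  Per-gene
allele counts are the per-PSNP mean (not sum) of allele-resolved read
counts, so PSNP density does not inflate expression.  Libraries are scaled
by trimmed-mean-of-M-values (TMM) factors computed on raw count log-ratios
(the factor therefore absorbs sequencing depth as well as composition;
factors are rescaled to geometric mean 1).  Allelic bias is called with an
exact conditional negative-binomial test (common dispersion, estimated by
method of moments across genes) plus a 1.5-fold threshold on normalized
counts.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from . import formats_io as fio
from ._stats import nb_exact_test_vec

logger = logging.getLogger(__name__)

MATERNAL_BIAS = "MATERNAL_BIAS"
PATERNAL_BIAS = "PATERNAL_BIAS"
NO_BIAS = "NONE"


def identify_psnps(variants: pd.DataFrame, annotation: pd.DataFrame,
                   mother: str = "mother", father: str = "father",
                   f1: str = "f1") -> pd.DataFrame:
    """Select PSNPs from a trio genotype frame and annotate their gene.

    ``variants`` is the frame from :func:`hybmeth.formats_io.read_vcf_minimal`.
    Keeps biallelic SNPs with both parents homozygous for different alleles
    and the F1 heterozygous; adds ``maternal_base``, ``paternal_base`` and
    ``gene_id`` (NaN outside genes; a PSNP inside two overlapping genes is
    duplicated, one row per gene).
    """
    gm = variants[f"gt_{mother}"]
    gf = variants[f"gt_{father}"]
    g1 = variants[f"gt_{f1}"]
    hom = gm.isin([fio.HOM_REF, fio.HOM_ALT]) & gf.isin([fio.HOM_REF, fio.HOM_ALT])
    keep = hom & (gm != gf) & (g1 == fio.HET)
    psnps = variants.loc[keep].copy()
    psnps["maternal_base"] = np.where(psnps[f"gt_{mother}"] == fio.HOM_REF,
                                      psnps["ref"], psnps["alt"])
    psnps["paternal_base"] = np.where(psnps[f"gt_{father}"] == fio.HOM_REF,
                                      psnps["ref"], psnps["alt"])
    out = []
    for chrom, sub in psnps.groupby("chrom", sort=False):
        genes = annotation[annotation["chrom"] == chrom]
        assigned = np.zeros(len(sub), dtype=bool)
        for g in genes.itertuples(index=False):
            inside = (sub["pos"] >= g.start) & (sub["pos"] <= g.end)
            if inside.any():
                out.append(sub.loc[inside].assign(gene_id=g.gene_id))
                assigned |= inside.to_numpy()
        if (~assigned).any():
            out.append(sub.loc[~assigned].assign(gene_id=np.nan))
    if not out:
        return psnps.assign(gene_id=np.nan).iloc[0:0]
    res = pd.concat(out, ignore_index=True)
    return res.sort_values(["chrom", "pos"]).reset_index(drop=True)


def aggregate_allele_counts(allele_depths: pd.DataFrame,
                            psnps: pd.DataFrame, use_sum: bool = False) -> pd.DataFrame:
    """Per-gene (maternal, paternal) counts from per-PSNP allele depths.

    The per-gene count is the mean over its covered PSNPs (total reads > 0)
    of per-allele reads, rounded to the nearest integer (``use_sum=True``
    sums instead).  Genes with no covered PSNP are excluded and logged.
    """
    genic = psnps[psnps["gene_id"].notna()][["chrom", "pos", "gene_id"]]
    j = genic.merge(allele_depths, on=["chrom", "pos"])
    j = j[(j["maternal_reads"] + j["paternal_reads"]) > 0]
    n_genes = genic["gene_id"].nunique()
    agg = "sum" if use_sum else "mean"
    g = j.groupby("gene_id")[["maternal_reads", "paternal_reads"]].agg(agg)
    if len(g) < n_genes:
        logger.info("aggregate_allele_counts: %d genes with no covered PSNP excluded",
                    n_genes - len(g))
    out = g.round().astype(np.int64).reset_index()
    out = out.rename(columns={"maternal_reads": "count_maternal",
                              "paternal_reads": "count_paternal"})
    out["n_psnps"] = j.groupby("gene_id")["pos"].size().to_numpy()
    return out


def tmm_factors(count_matrix: np.ndarray | pd.DataFrame,
                trim_m: float = 0.30, trim_a: float = 0.05) -> np.ndarray:
    """TMM scaling factor per library (column), geometric mean 1.

    M-values are log2 ratios of raw counts against a reference library (the
    one whose 75th percentile count is closest to the mean of the 75th
    percentiles); genes with a zero count in either library are excluded.
    The doubly-trimmed (30% on M, 5% on A), precision-weighted mean M gives
    the factor.  Because ratios are taken on raw counts, the factor absorbs
    library depth: dividing each library by its factor puts all libraries
    on a common scale.
    """
    x = np.asarray(count_matrix, dtype=float)
    if x.ndim != 2 or x.shape[1] < 2:
        raise ValueError("need a genes x libraries matrix with >= 2 libraries")
    lib_sizes = x.sum(axis=0)
    if (lib_sizes == 0).any():
        raise ValueError("a library has all-zero counts")
    q75 = np.quantile(x, 0.75, axis=0)
    ref = int(np.argmin(np.abs(q75 - q75.mean())))
    factors = np.ones(x.shape[1])
    for k in range(x.shape[1]):
        if k == ref:
            continue
        ok = (x[:, k] > 0) & (x[:, ref] > 0)
        xk, xr = x[ok, k], x[ok, ref]
        m = np.log2(xk) - np.log2(xr)
        a = 0.5 * (np.log2(xk) + np.log2(xr))
        w = (lib_sizes[k] - xk) / (lib_sizes[k] * xk) \
            + (lib_sizes[ref] - xr) / (lib_sizes[ref] * xr)
        lo_m, hi_m = np.quantile(m, [trim_m, 1 - trim_m])
        lo_a, hi_a = np.quantile(a, [trim_a, 1 - trim_a])
        keep = (m >= lo_m) & (m <= hi_m) & (a >= lo_a) & (a <= hi_a)
        if keep.sum() == 0 or w[keep].sum() == 0:
            keep = np.ones(len(m), dtype=bool)
        factors[k] = 2.0 ** (np.sum(w[keep] * m[keep]) / np.sum(w[keep]))
    factors = factors / np.exp(np.mean(np.log(factors)))
    return factors


def estimate_dispersion(count_pairs: np.ndarray | pd.DataFrame) -> float:
    """Method-of-moments common NB dispersion across gene (x1, x2) pairs.

    Models both counts of a pair as replicates of one NB(mu_g, phi) with
    var = mu + phi mu^2; phi is estimated as
    sum(s2_g - m_g) / sum(m_g^2 - s2_g/2) (the denominator is the unbiased
    estimate of sum mu_g^2), floored at 0.  Requires >= 20 genes.
    """
    x = np.asarray(count_pairs, dtype=float)
    if x.ndim != 2 or x.shape[1] != 2:
        raise ValueError("need a genes x 2 matrix")
    if x.shape[0] < 20:
        raise ValueError("need >= 20 genes; pass a fixed dispersion instead")
    m = x.mean(axis=1)
    s2 = (x[:, 0] - x[:, 1]) ** 2 / 2.0
    denom = np.sum(m ** 2 - s2 / 2.0)
    if denom <= 0:
        return 0.0
    return float(max(0.0, np.sum(s2 - m) / denom))


def allelic_bias_test(count_maternal: np.ndarray, count_paternal: np.ndarray,
                      factors: tuple[float, float] = (1.0, 1.0),
                      dispersion: float = 0.0, fold_threshold: float = 1.5,
                      alpha: float = 0.05) -> pd.DataFrame:
    """Exact NB test of maternal vs paternal counts with a fold threshold.

    Counts are divided by their library's TMM factor and rounded; the
    two-sided exact conditional NB test (common ``dispersion``) gives the
    p-value, and a gene is called biased only when p < alpha AND the
    normalized fold change >= ``fold_threshold``, directed by the larger
    normalized count.  Returns norm counts, log2 fold, p and ``klass``.
    """
    cm = np.asarray(count_maternal, dtype=float)
    cp = np.asarray(count_paternal, dtype=float)
    nm = np.round(cm / factors[0]).astype(np.int64)
    npp = np.round(cp / factors[1]).astype(np.int64)
    p = nb_exact_test_vec(nm, npp, dispersion)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(npp > 0, nm / np.maximum(npp, 1), np.inf)
        ratio = np.where((nm == 0) & (npp == 0), 1.0, ratio)
        fold = np.maximum(ratio, np.where(ratio > 0, 1.0 / ratio, np.inf))
        log2_fold = np.log2((nm + 0.5) / (npp + 0.5))
    klass = np.full(len(nm), NO_BIAS, dtype=object)
    biased = (p < alpha) & (fold >= fold_threshold)
    klass[biased & (nm > npp)] = MATERNAL_BIAS
    klass[biased & (npp > nm)] = PATERNAL_BIAS
    return pd.DataFrame({"norm_maternal": nm, "norm_paternal": npp,
                         "log2_fold": log2_fold, "p_value": p, "klass": klass})


def call_allelic_bias(gene_counts: pd.DataFrame, dispersion: float | None = None,
                      fold_threshold: float = 1.5, alpha: float = 0.05,
                      fallback_dispersion: float = 0.1) -> pd.DataFrame:
    """TMM-normalize per-gene allele counts, estimate dispersion, test bias."""
    mat = gene_counts[["count_maternal", "count_paternal"]].to_numpy()
    factors = tmm_factors(mat)
    if dispersion is None:
        norm = mat / factors
        try:
            dispersion = estimate_dispersion(norm)
        except ValueError:
            logger.warning("too few genes for dispersion estimation; "
                           "using fixed dispersion %.3f", fallback_dispersion)
            dispersion = fallback_dispersion
    res = allelic_bias_test(mat[:, 0], mat[:, 1], factors=(factors[0], factors[1]),
                            dispersion=dispersion, fold_threshold=fold_threshold,
                            alpha=alpha)
    out = pd.concat([gene_counts.reset_index(drop=True), res], axis=1)
    out.attrs["tmm_factors"] = factors
    out.attrs["dispersion"] = dispersion
    return out


def allelic_total_regression(allelic_counts: np.ndarray,
                             total_counts: np.ndarray) -> dict:
    """OLS of log2(allelic + 1) on log2(total + 1).

    Returns slope, intercept and R^2; needs >= 3 finite points.
    """
    y = np.log2(np.asarray(allelic_counts, dtype=float) + 1.0)
    x = np.log2(np.asarray(total_counts, dtype=float) + 1.0)
    ok = np.isfinite(x) & np.isfinite(y)
    if ok.sum() < 3:
        raise ValueError("need >= 3 finite points")
    fit = stats.linregress(x[ok], y[ok])
    return {"slope": float(fit.slope), "intercept": float(fit.intercept),
            "r_squared": float(fit.rvalue ** 2)}


def bias_summary(calls: pd.DataFrame) -> dict:
    """Tally of bias classes plus a volcano-plot table (log2 fold, -log10 p)."""
    counts = {k: int((calls["klass"] == k).sum())
              for k in (MATERNAL_BIAS, PATERNAL_BIAS, NO_BIAS)} if len(calls) else \
             {MATERNAL_BIAS: 0, PATERNAL_BIAS: 0, NO_BIAS: 0}
    counts["biased_total"] = counts[MATERNAL_BIAS] + counts[PATERNAL_BIAS]
    volcano = pd.DataFrame()
    if len(calls):
        with np.errstate(divide="ignore"):
            volcano = pd.DataFrame({
                "gene_id": calls.get("gene_id", pd.Series(range(len(calls)))),
                "log2_fold": calls["log2_fold"],
                "neg_log10_p": -np.log10(np.maximum(calls["p_value"], 1e-300)),
                "klass": calls["klass"]})
    return {"counts": counts, "volcano": volcano}
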