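"""Global methylome summaries.

Per-site methylation levels (mC/C), the binomial-vs-conversion-failure
methylated-site caller, per-context proportions of methylated cytosines,
per-chromosome mean levels with mid-parent values, gene metaplots
(upstream / body / downstream) and per-element-class levels, and the
lambda spike-in conversion rate.

Chromosome and element means are unweighted per-site means of mC/C over
sites passing the coverage floor (default 4 reads); a read-weighted
variant is available via ``weighted=True`` where noted.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ._intervals import merge_intervals, points_in_intervals
from ._stats import binom_greater_pvals
from .formats_io import CONTEXTS

DEFAULT_MIN_COV = 4


def methylation_level(record) -> float:
    """mC/C ratio of one record (``total_count`` must be >= 1)."""
    if record.total_count < 1:
        raise ValueError("methylation level undefined at total_count 0")
    return record.mc_count / record.total_count


def add_levels(df: pd.DataFrame) -> pd.DataFrame:
    """Return a copy with a ``level`` column (NaN where total_count is 0)."""
    out = df.copy()
    with np.errstate(invalid="ignore", divide="ignore"):
        out["level"] = np.where(out["total_count"] > 0,
                                out["mc_count"] / out["total_count"].clip(lower=1),
                                np.nan)
    return out


def call_methylated_sites(methylome: pd.DataFrame, fail_rate: float = 0.006,
                          alpha: float = 0.05) -> pd.DataFrame:
    """Sites whose mC counts exceed conversion failure (one-sided binomial).

    A site is methylated when P(X >= mc | total, fail_rate) <= alpha under
    Binomial(total, fail_rate).  No multiple-testing correction by default.
    """
    if not 0.0 <= fail_rate < 1.0:
        raise ValueError("fail_rate must be in [0, 1)")
    covered = methylome[methylome["total_count"] > 0]
    p = binom_greater_pvals(covered["mc_count"].to_numpy(),
                            covered["total_count"].to_numpy(), fail_rate)
    keep = (p <= alpha) & (covered["mc_count"] > 0)
    return covered.loc[keep].reset_index(drop=True)


def context_proportions(methylated_sites: pd.DataFrame) -> pd.DataFrame:
    """Counts and proportions of methylated cytosines per context.

    Returns one row per context with ``mc_sites`` and ``proportion``
    (fractions of the total, summing to 1).
    """
    if len(methylated_sites) == 0:
        raise ValueError("no methylated sites")
    counts = methylated_sites["context"].value_counts()
    counts = counts.reindex(CONTEXTS, fill_value=0)
    total = int(counts.sum())
    return pd.DataFrame({
        "context": CONTEXTS,
        "mc_sites": counts.to_numpy(),
        "proportion": counts.to_numpy() / total,
    })


def context_proportions_from_counts(counts: dict[str, int]) -> pd.DataFrame:
    """Context proportions from a per-context count table.

    Same output as :func:`context_proportions`, but starting from total
    methylated-cytosine counts per context (the form published summary
    tables take) instead of per-site records.
    """
    if set(counts) - set(CONTEXTS):
        raise ValueError(f"unknown context in {set(counts)}")
    total = sum(counts.values())
    if total == 0:
        raise ValueError("no methylated cytosines")
    return pd.DataFrame({
        "context": CONTEXTS,
        "mc_sites": [counts.get(c, 0) for c in CONTEXTS],
        "proportion": [counts.get(c, 0) / total for c in CONTEXTS],
    })


def chromosome_mean_levels(methylome: pd.DataFrame, context: str | None = None,
                           min_cov: int = DEFAULT_MIN_COV,
                           weighted: bool = False) -> pd.Series:
    """Mean methylation level per chromosome.

    Unweighted mean of per-site mC/C over sites with coverage >= ``min_cov``
    (set ``weighted=True`` for the pooled, read-weighted mean).  Chromosomes
    with no qualifying site are absent from the result.
    """
    df = methylome[methylome["total_count"] >= max(min_cov, 1)]
    if context is not None:
        df = df[df["context"] == context]
    if weighted:
        g = df.groupby("chrom")
        return g["mc_count"].sum() / g["total_count"].sum()
    df = add_levels(df)
    return df.groupby("chrom")["level"].mean()


def mid_parent_value(maternal_level, paternal_level):
    """Arithmetic mean of the two parental values (scalar or array)."""
    return (np.asarray(maternal_level) + np.asarray(paternal_level)) / 2.0


def conversion_rate(lambda_methylome: pd.DataFrame) -> float:
    """Bisulfite conversion rate: 1 - pooled mC/C over the lambda spike-in."""
    total = int(lambda_methylome["total_count"].sum())
    if total == 0:
        raise ValueError("lambda contig has zero coverage")
    return 1.0 - int(lambda_methylome["mc_count"].sum()) / total


def metaplot_profile(methylome: pd.DataFrame, genes: pd.DataFrame,
                     context: str, flank_bp: int = 2000, n_bins: int = 20,
                     min_cov: int = 1) -> pd.DataFrame:
    """Binned mean methylation over upstream flank, gene body, downstream flank.

    Bodies are length-normalized into ``n_bins`` bins; flanks are fixed-width
    bins.  Minus-strand genes are reversed so bin 1 is always the most
    upstream.  Returns a frame with ``region`` (upstream/body/downstream),
    ``bin`` (1-based within region) and ``mean_level`` (NaN where no sites).
    """
    if flank_bp < 0 or n_bins < 1:
        raise ValueError("flank_bp must be >= 0 and n_bins >= 1")
    df = methylome[(methylome["context"] == context)
                   & (methylome["total_count"] >= max(min_cov, 1))]
    df = add_levels(df)
    sums = np.zeros(3 * n_bins)
    counts = np.zeros(3 * n_bins)
    for chrom, sub in df.groupby("chrom", sort=False):
        pos = sub["pos"].to_numpy()
        lev = sub["level"].to_numpy()
        order = np.argsort(pos, kind="mergesort")
        pos, lev = pos[order], lev[order]
        for g in genes[genes["chrom"] == chrom].itertuples(index=False):
            lo, hi = g.start - flank_bp, g.end + flank_bp
            i0, i1 = np.searchsorted(pos, [lo, hi + 1])
            if i0 == i1:
                continue
            p = pos[i0:i1]
            v = lev[i0:i1]
            glen = g.end - g.start + 1
            # fractional coordinate: [-1,0) upstream, [0,1) body, [1,2) downstream
            frac = np.empty(len(p))
            up = p < g.start
            down = p > g.end
            body = ~up & ~down
            if flank_bp > 0:
                frac[up] = (p[up] - g.start) / flank_bp  # in [-1, 0)
                frac[down] = 1.0 + (p[down] - g.end - 1) / flank_bp
            else:
                frac[up | down] = np.nan
            frac[body] = (p[body] - g.start) / glen
            binidx = np.floor((frac + 1.0) * n_bins).astype(int)
            if g.strand == "-":
                binidx = 3 * n_bins - 1 - binidx  # exact bin-wise mirror
            ok = (binidx >= 0) & (binidx < 3 * n_bins) & ~np.isnan(v)
            np.add.at(sums, binidx[ok], v[ok])
            np.add.at(counts, binidx[ok], 1)
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    region = np.repeat(["upstream", "body", "downstream"], n_bins)
    return pd.DataFrame({
        "region": region,
        "bin": np.tile(np.arange(1, n_bins + 1), 3),
        "n_sites": counts.astype(int),
        "mean_level": means,
    })


def element_levels(methylome: pd.DataFrame, element_beds: dict[str, pd.DataFrame],
                   context: str, min_cov: int = DEFAULT_MIN_COV) -> pd.Series:
    """Unweighted mean site level per element class (CpG island, repeat, ...).

    ``element_beds`` maps class name to a frame of 1-based inclusive
    ``chrom, start, end`` intervals.  A site inside two classes counts in
    both; empty classes yield NaN.
    """
    df = methylome[(methylome["context"] == context)
                   & (methylome["total_count"] >= max(min_cov, 1))]
    df = add_levels(df)
    out = {}
    for name, bed in element_beds.items():
        mask = points_in_intervals(df, bed)
        out[name] = float(df.loc[mask, "level"].mean()) if mask.any() else np.nan
    return pd.Series(out, name=f"mean_level_{context}")


def profile_summary(methylomes: dict[str, pd.DataFrame],
                    lambda_methylome: pd.DataFrame | None = None,
                    fail_rate: float = 0.006, alpha: float = 0.05,
                    min_cov: int = DEFAULT_MIN_COV) -> dict[str, pd.DataFrame]:
    """Bundle the per-sample global summaries used by the CLI profile stage."""
    props = []
    chrom_rows = []
    for sample, meth in methylomes.items():
        called = call_methylated_sites(meth, fail_rate=fail_rate, alpha=alpha)
        cp = context_proportions(called).assign(sample=sample)
        props.append(cp)
        for ctx in CONTEXTS:
            means = chromosome_mean_levels(meth, ctx, min_cov=min_cov)
            for chrom, lev in means.items():
                chrom_rows.append((sample, ctx, chrom, lev))
    chrom_levels = pd.DataFrame(chrom_rows,
                                columns=["sample", "context", "chrom", "mean_level"])
    if {"mother", "father"} <= set(methylomes):
        wide = chrom_levels.pivot_table(index=["context", "chrom"],
                                        columns="sample", values="mean_level")
        wide["MPV"] = mid_parent_value(wide["mother"], wide["father"])
        chrom_levels = wide.reset_index()
    out = {"context_proportions": pd.concat(props, ignore_index=True),
           "chromosome_levels": chrom_levels}
    if lambda_methylome is not None:
        out["conversion_rate"] = pd.DataFrame(
            {"conversion_rate": [conversion_rate(lambda_methylome)]})
    return out
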