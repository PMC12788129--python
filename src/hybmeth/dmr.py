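"""Sliding-window differential methylation and DMR inheritance classification.

A window qualifies when it contains at least ``min_sites`` cytosines of the
requested context covered (>= ``min_cov`` reads) in BOTH samples.  Counts
are pooled per window and compared with a two-sided Fisher exact test;
windows with p <= 0.05 and >= 2-fold difference of pooled levels are
significant, and overlapping/adjacent significant windows with the same
direction are merged into DMRs (levels recomputed from the merged span,
p = minimum window p).

Inheritance of a parental (mother-vs-father) DMR is read off interval
overlaps with the two F1 comparisons: a parental DMR is LIKE_FATHER when
it overlaps an F1-vs-mother DMR whose direction is consistent with the F1
siding with the father, and overlaps no F1-vs-father DMR; LIKE_MOTHER is
symmetric; anything else is UNRESOLVED.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd

from ._intervals import cluster_membership, overlaps_any
from ._stats import fisher_exact_vec

EPS = 0.001  # pseudo-level for fold changes

DMR_COLUMNS = ["chrom", "start", "end", "context", "level_a", "level_b",
               "fold_change", "p_value", "direction", "site_count"]

LIKE_FATHER = "LIKE_FATHER"
LIKE_MOTHER = "LIKE_MOTHER"
UNRESOLVED = "UNRESOLVED"


def _joined_sites(meth_a: pd.DataFrame, meth_b: pd.DataFrame, context: str,
                  min_cov: int) -> pd.DataFrame:
    a = meth_a[(meth_a["context"] == context) & (meth_a["total_count"] >= min_cov)]
    b = meth_b[(meth_b["context"] == context) & (meth_b["total_count"] >= min_cov)]
    j = a.merge(b, on=["chrom", "pos", "strand"], suffixes=("_a", "_b"))
    return j.sort_values(["chrom", "pos", "strand"]).reset_index(drop=True)


def make_windows(meth_a: pd.DataFrame, meth_b: pd.DataFrame, context: str,
                 window_bp: int = 1000, step_bp: int = 100, min_sites: int = 5,
                 min_cov: int = 4) -> pd.DataFrame:
    """Sliding windows with pooled counts for both samples.

    Returns one row per qualifying window: ``chrom, start, end, site_count``
    and pooled ``mc_a, total_a, mc_b, total_b``.
    """
    if not window_bp >= step_bp >= 1:
        raise ValueError("need window_bp >= step_bp >= 1")
    j = _joined_sites(meth_a, meth_b, context, min_cov)
    rows = []
    for chrom, sub in j.groupby("chrom", sort=True):
        pos = sub["pos"].to_numpy()
        cum_mc_a = np.concatenate([[0], np.cumsum(sub["mc_count_a"].to_numpy())])
        cum_tot_a = np.concatenate([[0], np.cumsum(sub["total_count_a"].to_numpy())])
        cum_mc_b = np.concatenate([[0], np.cumsum(sub["mc_count_b"].to_numpy())])
        cum_tot_b = np.concatenate([[0], np.cumsum(sub["total_count_b"].to_numpy())])
        first = ((pos[0] - 1) // step_bp) * step_bp + 1 - (window_bp - step_bp)
        start = max(1, first)
        starts = np.arange(start, pos[-1] + 1, step_bp)
        ends = starts + window_bp - 1
        i0 = np.searchsorted(pos, starts, side="left")
        i1 = np.searchsorted(pos, ends, side="right")
        n_sites = i1 - i0
        ok = n_sites >= min_sites
        for s, e, a0, a1, ns in zip(starts[ok], ends[ok], i0[ok], i1[ok],
                                    n_sites[ok]):
            rows.append((chrom, int(s), int(e), int(ns),
                         int(cum_mc_a[a1] - cum_mc_a[a0]),
                         int(cum_tot_a[a1] - cum_tot_a[a0]),
                         int(cum_mc_b[a1] - cum_mc_b[a0]),
                         int(cum_tot_b[a1] - cum_tot_b[a0])))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "site_count",
                                       "mc_a", "total_a", "mc_b", "total_b"])


def _fold_and_direction(level_a: np.ndarray, level_b: np.ndarray):
    ratio = (level_a + EPS) / (level_b + EPS)
    fold = np.maximum(ratio, 1.0 / ratio)
    direction = np.where(level_a >= level_b, "a>b", "a<b")
    return fold, direction


def test_window(window) -> tuple[float, float, tuple[float, float]]:
    """Fisher p, fold change and pooled levels for one window row."""
    if window.total_a == 0 or window.total_b == 0:
        raise ValueError("window has zero pooled total in one sample")
    p = float(fisher_exact_vec(np.array([window.mc_a]), np.array([window.total_a]),
                               np.array([window.mc_b]), np.array([window.total_b]))[0])
    la = window.mc_a / window.total_a
    lb = window.mc_b / window.total_b
    fold, _ = _fold_and_direction(np.array([la]), np.array([lb]))
    return p, float(fold[0]), (la, lb)


def test_windows(windows: pd.DataFrame) -> pd.DataFrame:
    """Vectorized window testing; adds p_value, levels, fold and direction."""
    w = windows[(windows["total_a"] > 0) & (windows["total_b"] > 0)].copy()
    if len(w) == 0:
        return w.assign(level_a=[], level_b=[], fold_change=[], p_value=[],
                        direction=[])
    w["p_value"] = fisher_exact_vec(w["mc_a"].to_numpy(), w["total_a"].to_numpy(),
                                    w["mc_b"].to_numpy(), w["total_b"].to_numpy())
    w["level_a"] = w["mc_a"] / w["total_a"]
    w["level_b"] = w["mc_b"] / w["total_b"]
    fold, direction = _fold_and_direction(w["level_a"].to_numpy(),
                                          w["level_b"].to_numpy())
    w["fold_change"] = fold
    w["direction"] = direction
    return w


def call_dmrs(meth_a: pd.DataFrame, meth_b: pd.DataFrame, context: str,
              window_bp: int = 1000, step_bp: int = 100, min_sites: int = 5,
              min_cov: int = 4, max_p: float = 0.05,
              min_fold: float = 2.0) -> pd.DataFrame:
    """Call DMRs between two methylomes in one context.

    Significant windows (p <= ``max_p``, fold >= ``min_fold``) are merged
    when overlapping or adjacent with the same direction; merged DMRs carry
    pooled recomputed levels, the minimum window p, and the number of
    jointly covered sites in the merged span.  Every emitted DMR satisfies
    all thresholds.
    """
    windows = make_windows(meth_a, meth_b, context, window_bp, step_bp,
                           min_sites, min_cov)
    if len(windows) == 0:
        return pd.DataFrame(columns=DMR_COLUMNS)
    tested = test_windows(windows)
    sig = tested[(tested["p_value"] <= max_p)
                 & (tested["fold_change"] >= min_fold)]
    if len(sig) == 0:
        return pd.DataFrame(columns=DMR_COLUMNS)

    j = _joined_sites(meth_a, meth_b, context, min_cov)
    rows = []
    for (chrom, direction), sub in sig.groupby(["chrom", "direction"], sort=True):
        sub = sub.sort_values("start")
        cur = None
        merged = []
        for w in sub.itertuples(index=False):
            if cur is None:
                cur = [w.start, w.end, w.p_value]
            elif w.start <= cur[1] + 1:
                cur[1] = max(cur[1], w.end)
                cur[2] = min(cur[2], w.p_value)
            else:
                merged.append(cur)
                cur = [w.start, w.end, w.p_value]
        merged.append(cur)
        sites = j[j["chrom"] == chrom]
        pos = sites["pos"].to_numpy()
        for start, end, p in merged:
            i0, i1 = np.searchsorted(pos, [start, end + 1])
            span = sites.iloc[i0:i1]
            la = span["mc_count_a"].sum() / span["total_count_a"].sum()
            lb = span["mc_count_b"].sum() / span["total_count_b"].sum()
            fold, dirn = _fold_and_direction(np.array([la]), np.array([lb]))
            if fold[0] < min_fold or dirn[0] != direction:
                continue  # merged span no longer meets the thresholds
            rows.append((chrom, start, end, context, la, lb, float(fold[0]),
                         p, direction, int(i1 - i0)))
    out = pd.DataFrame(rows, columns=DMR_COLUMNS)
    return out.sort_values(["chrom", "start"]).reset_index(drop=True)


def classify_dmr_inheritance(parental: pd.DataFrame, f1_vs_father: pd.DataFrame,
                             f1_vs_mother: pd.DataFrame):
    """Classify parental DMR inheritance and count Venn regions.

    ``parental`` must be called as (mother, father), and the F1 sets as
    (F1, father) and (F1, mother), so that ``direction`` ``a>b`` means the
    first-named sample is more methylated.  Returns ``(calls, venn)``:
    ``calls`` has one row per parental DMR with a ``category`` column;
    ``venn`` counts interval clusters by membership in the three sets.
    """
    opposite = {"a>b": "a<b", "a<b": "a>b"}
    n = len(parental)
    categories = np.full(n, UNRESOLVED, dtype=object)
    for direction in ("a>b", "a<b"):
        pmask = (parental["direction"] == direction).to_numpy() if n else np.array([], bool)
        # F1 sides with father: F1 differs from mother the way father does
        # (F1-vs-mother direction opposite the mother-vs-father direction)
        # and is indistinguishable from father.
        fm_dir = f1_vs_mother["direction"] == opposite[direction]
        hit_fm = overlaps_any(parental, f1_vs_mother, fm_dir.to_numpy())
        hit_ff_any = overlaps_any(parental, f1_vs_father)
        like_father = pmask & hit_fm & ~hit_ff_any
        # F1 sides with mother: F1 differs from father the way mother does
        # (F1-vs-father direction equals the mother-vs-father direction).
        ff_dir = f1_vs_father["direction"] == direction
        hit_ff = overlaps_any(parental, f1_vs_father, ff_dir.to_numpy())
        hit_fm_any = overlaps_any(parental, f1_vs_mother)
        like_mother = pmask & hit_ff & ~hit_fm_any
        categories[like_father] = LIKE_FATHER
        categories[like_mother] = LIKE_MOTHER
    calls = parental.copy()
    calls["category"] = categories

    clusters = cluster_membership({"parental": parental,
                                   "f1_vs_father": f1_vs_father,
                                   "f1_vs_mother": f1_vs_mother})
    names = ["parental", "f1_vs_father", "f1_vs_mother"]
    venn_rows = []
    for combo in itertools.product([True, False], repeat=3):
        if not any(combo):
            continue
        if len(clusters):
            mask = np.ones(len(clusters), dtype=bool)
            for name, flag in zip(names, combo):
                mask &= clusters[name].to_numpy() == flag
            count = int(mask.sum())
        else:
            count = 0
        venn_rows.append((*combo, count))
    venn = pd.DataFrame(venn_rows, columns=[*names, "count"])
    return calls, venn


def transmitted_fraction(calls: pd.DataFrame, category: str) -> float:
    """Percentage (2 dp) of parental DMRs in the given inheritance category."""
    if len(calls) == 0:
        raise ValueError("no inheritance calls")
    frac = (calls["category"] == category).sum() / len(calls)
    return round(100.0 * frac, 2)
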