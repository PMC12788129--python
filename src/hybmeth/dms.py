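"""Per-site Fisher tests among the trio and eight-way inheritance classes.

Sites covered (>= ``min_cov`` reads) in all three samples are tested
pairwise (father PA vs mother PB, F1 vs PA, F1 vs PB) with two-sided
Fisher exact tests; a site is a DMS when any pairwise p < alpha
(default 0.01, uncorrected).  DMSs are then classified by the pattern of
significance and ordering of levels:

* parents differ (p_ab < alpha):
  ADDITIVE           F1 differs from both parents, level strictly between;
  LOW_PARENT         F1 indistinguishable from the lower parent,
                     distinguishable from the higher;
  HIGH_PARENT        symmetric;
  ABOVE_HIGH_PARENT  F1 differs from both and exceeds the higher parent;
  BELOW_LOW_PARENT   F1 differs from both and sits below the lower;
  AMBIGUOUS          any other pattern.
* parents indistinguishable (p_ab >= alpha):
  ABOVE_PARENT       F1 above both parents, significant against both;
  BELOW_PARENT       symmetric;
  AMBIGUOUS          otherwise.

Low-coverage sites are excluded before testing — they are untestable, not
ambiguous.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ._stats import fisher_exact_pair, fisher_exact_vec

CLASSES = ("ADDITIVE", "LOW_PARENT", "HIGH_PARENT", "ABOVE_HIGH_PARENT",
           "BELOW_LOW_PARENT", "ABOVE_PARENT", "BELOW_PARENT", "AMBIGUOUS")

DEFAULT_ALPHA = 0.01


def fisher_site_test(mc_a: int, uc_a: int, mc_b: int, uc_b: int) -> float:
    """Two-sided Fisher exact p for one site's 2x2 (mc, uc) table."""
    return fisher_exact_pair(mc_a, uc_a, mc_b, uc_b)


def build_site_table(father: pd.DataFrame, mother: pd.DataFrame,
                     f1: pd.DataFrame, min_cov: int = 4,
                     alpha: float = DEFAULT_ALPHA) -> pd.DataFrame:
    """Join the trio per site, compute pairwise Fisher p-values and levels.

    Returns sites covered in all three samples with columns
    ``level_pa, level_pb, level_f1, p_ab, p_fa, p_fb`` and ``is_dms``.
    """
    def prep(df, tag):
        d = df[df["total_count"] >= min_cov]
        d = d.rename(columns={"mc_count": f"mc_{tag}", "total_count": f"tot_{tag}"})
        return d[["chrom", "pos", "strand", "context", f"mc_{tag}", f"tot_{tag}"]]

    j = prep(father, "pa").merge(
        prep(mother, "pb").drop(columns="context"), on=["chrom", "pos", "strand"])
    j = j.merge(prep(f1, "f1").drop(columns="context"),
                on=["chrom", "pos", "strand"])
    for tag in ("pa", "pb", "f1"):
        j[f"level_{tag}"] = j[f"mc_{tag}"] / j[f"tot_{tag}"]
    mc = {t: j[f"mc_{t}"].to_numpy() for t in ("pa", "pb", "f1")}
    tot = {t: j[f"tot_{t}"].to_numpy() for t in ("pa", "pb", "f1")}
    j["p_ab"] = fisher_exact_vec(mc["pa"], tot["pa"], mc["pb"], tot["pb"])
    j["p_fa"] = fisher_exact_vec(mc["f1"], tot["f1"], mc["pa"], tot["pa"])
    j["p_fb"] = fisher_exact_vec(mc["f1"], tot["f1"], mc["pb"], tot["pb"])
    j["is_dms"] = ((j["p_ab"] < alpha) | (j["p_fa"] < alpha)
                   | (j["p_fb"] < alpha))
    return j.reset_index(drop=True)


def classify_dms_frame(sites: pd.DataFrame,
                       alpha: float = DEFAULT_ALPHA) -> pd.Series:
    """Vectorized eight-way classification of DMS rows (see module docstring).

    All rows must be DMSs (at least one pairwise p < alpha); raises
    otherwise.  The classification is total and exclusive.
    """
    any_sig = ((sites["p_ab"] < alpha) | (sites["p_fa"] < alpha)
               | (sites["p_fb"] < alpha))
    if not any_sig.all():
        raise ValueError("classify_dms requires DMS rows (some p < alpha)")
    la = sites["level_pa"].to_numpy()
    lb = sites["level_pb"].to_numpy()
    lf = sites["level_f1"].to_numpy()
    p_ab = sites["p_ab"].to_numpy()
    p_fa = sites["p_fa"].to_numpy()
    p_fb = sites["p_fb"].to_numpy()

    parents_differ = p_ab < alpha
    sig_fa = p_fa < alpha
    sig_fb = p_fb < alpha
    lo = np.minimum(la, lb)
    hi = np.maximum(la, lb)
    # pairwise p against the lower/higher-level parent
    a_is_low = la <= lb
    p_f_low = np.where(a_is_low, p_fa, p_fb)
    p_f_high = np.where(a_is_low, p_fb, p_fa)

    klass = np.full(len(sites), "AMBIGUOUS", dtype=object)
    both_sig = sig_fa & sig_fb
    m = parents_differ
    klass[m & both_sig & (lf > lo) & (lf < hi)] = "ADDITIVE"
    klass[m & both_sig & (lf > hi)] = "ABOVE_HIGH_PARENT"
    klass[m & both_sig & (lf < lo)] = "BELOW_LOW_PARENT"
    klass[m & (p_f_low >= alpha) & (p_f_high < alpha)] = "LOW_PARENT"
    klass[m & (p_f_high >= alpha) & (p_f_low < alpha)] = "HIGH_PARENT"
    e = ~parents_differ
    klass[e & both_sig & (lf > hi)] = "ABOVE_PARENT"
    klass[e & both_sig & (lf < lo)] = "BELOW_PARENT"
    return pd.Series(klass, index=sites.index, name="klass")


def classify_dms(record, alpha: float = DEFAULT_ALPHA) -> str:
    """Classify a single DMS (an object with level_* and p_* attributes)."""
    df = pd.DataFrame([{k: getattr(record, k) for k in
                        ("level_pa", "level_pb", "level_f1",
                         "p_ab", "p_fa", "p_fb")}])
    return classify_dms_frame(df, alpha=alpha).iloc[0]


def call_dms(father: pd.DataFrame, mother: pd.DataFrame, f1: pd.DataFrame,
             min_cov: int = 4, alpha: float = DEFAULT_ALPHA) -> pd.DataFrame:
    """Full DMS pipeline: join, test, keep DMSs, classify."""
    sites = build_site_table(father, mother, f1, min_cov=min_cov, alpha=alpha)
    dms = sites[sites["is_dms"]].reset_index(drop=True)
    if len(dms):
        dms["klass"] = classify_dms_frame(dms, alpha=alpha)
    else:
        dms["klass"] = pd.Series(dtype=object)
    return dms


def dms_class_proportions(records: pd.DataFrame,
                          by_chromosome: bool = True) -> pd.DataFrame:
    """Fraction of each inheritance class, per chromosome and globally.

    Rows sum to 1 within each chromosome (and in the ``all`` row).
    """
    if len(records) == 0:
        raise ValueError("no DMS records")
    groups = [("all", records)]
    if by_chromosome:
        groups += list(records.groupby("chrom", sort=True))
    rows = []
    for name, sub in groups:
        counts = sub["klass"].value_counts()
        total = len(sub)
        rows.append({"chrom": name, "n_dms": total,
                     **{k: counts.get(k, 0) / total for k in CLASSES}})
    return pd.DataFrame(rows)


def upset_counts(records: pd.DataFrame,
                 alpha: float = DEFAULT_ALPHA) -> pd.DataFrame:
    """Counts of the six directional pairwise-difference sets and intersections.

    Sets follow the A–F convention: A/B = father below/above mother,
    C/D = father below/above F1, E/F = mother below/above F1, each
    requiring the corresponding pairwise p < alpha.  Returns one row per
    observed membership pattern with its count; pattern totals over rows
    equal the number of DMSs.
    """
    flags = pd.DataFrame({
        "A": (records["p_ab"] < alpha) & (records["level_pa"] < records["level_pb"]),
        "B": (records["p_ab"] < alpha) & (records["level_pa"] > records["level_pb"]),
        "C": (records["p_fa"] < alpha) & (records["level_pa"] < records["level_f1"]),
        "D": (records["p_fa"] < alpha) & (records["level_pa"] > records["level_f1"]),
        "E": (records["p_fb"] < alpha) & (records["level_pb"] < records["level_f1"]),
        "F": (records["p_fb"] < alpha) & (records["level_pb"] > records["level_f1"]),
    })
    out = flags.value_counts().reset_index(name="count")
    return out.sort_values("count", ascending=False).reset_index(drop=True)
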