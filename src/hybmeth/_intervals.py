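"""Small interval utilities on 1-based inclusive coordinates.

Built on sorted arrays + searchsorted; enough for point-in-interval
membership, pairwise overlap queries and cross-set interval clustering.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def merge_intervals(df: pd.DataFrame) -> pd.DataFrame:
    """Merge overlapping-or-touching intervals per chromosome."""
    out = []
    for chrom, sub in df.sort_values(["chrom", "start"]).groupby("chrom", sort=True):
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        cur_s, cur_e = starts[0], ends[0]
        for s, e in zip(starts[1:], ends[1:]):
            if s <= cur_e + 1:
                cur_e = max(cur_e, e)
            else:
                out.append((chrom, cur_s, cur_e))
                cur_s, cur_e = s, e
        out.append((chrom, cur_s, cur_e))
    return pd.DataFrame(out, columns=["chrom", "start", "end"])


def points_in_intervals(points: pd.DataFrame, intervals: pd.DataFrame) -> np.ndarray:
    """Boolean mask: is each (chrom, pos) point inside any interval?

    Intervals may overlap; they are merged first so membership is well
    defined.
    """
    mask = np.zeros(len(points), dtype=bool)
    if len(intervals) == 0 or len(points) == 0:
        return mask
    merged = merge_intervals(intervals)
    for chrom, sub in merged.groupby("chrom", sort=False):
        sel = points["chrom"].to_numpy() == chrom
        if not sel.any():
            continue
        pos = points.loc[sel, "pos"].to_numpy()
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        idx = np.searchsorted(starts, pos, side="right") - 1
        ok = (idx >= 0) & (pos <= ends[np.clip(idx, 0, None)])
        mask[np.flatnonzero(sel)[ok]] = True
    return mask


def overlaps_any(query: pd.DataFrame, subject: pd.DataFrame,
                 subject_mask: np.ndarray | None = None) -> np.ndarray:
    """For each query interval, does it overlap (>= 1 bp) any subject interval?

    ``subject_mask`` optionally restricts the subject set.
    """
    res = np.zeros(len(query), dtype=bool)
    if len(query) == 0:
        return res
    sub = subject if subject_mask is None else subject.loc[subject_mask]
    if len(sub) == 0:
        return res
    for chrom, s in sub.groupby("chrom", sort=False):
        qsel = query["chrom"].to_numpy() == chrom
        if not qsel.any():
            continue
        # sort subject by start; an overlap with [qs, qe] exists iff some
        # subject has start <= qe and end >= qs
        order = np.argsort(s["start"].to_numpy(), kind="mergesort")
        starts = s["start"].to_numpy()[order]
        ends = s["end"].to_numpy()[order]
        cummax_end = np.maximum.accumulate(ends)
        qs = query.loc[qsel, "start"].to_numpy()
        qe = query.loc[qsel, "end"].to_numpy()
        k = np.searchsorted(starts, qe, side="right")  # subjects with start <= qe
        hit = (k > 0) & (cummax_end[np.clip(k - 1, 0, None)] >= qs)
        res[np.flatnonzero(qsel)[hit]] = True
    return res


def cluster_membership(sets: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Cluster intervals across named sets and report per-cluster membership.

    Intervals from all sets are pooled; clusters are maximal groups of
    mutually touching/overlapping intervals.  Returns one row per cluster
    with boolean columns per set name — the basis for Venn-region counts.
    """
    frames = []
    for name, df in sets.items():
        if len(df):
            frames.append(df[["chrom", "start", "end"]].assign(_set=name))
    if not frames:
        return pd.DataFrame(columns=["chrom", "start", "end", *sets])
    pool = pd.concat(frames, ignore_index=True)
    pool = pool.sort_values(["chrom", "start"]).reset_index(drop=True)
    rows = []
    for chrom, sub in pool.groupby("chrom", sort=True):
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        names = sub["_set"].to_numpy()
        cur_s, cur_e = starts[0], ends[0]
        members = {names[0]}
        for s, e, n in zip(starts[1:], ends[1:], names[1:]):
            if s <= cur_e:  # >=1bp overlap required to share a cluster
                cur_e = max(cur_e, e)
                members.add(n)
            else:
                rows.append((chrom, cur_s, cur_e, members))
                cur_s, cur_e, members = s, e, {n}
        rows.append((chrom, cur_s, cur_e, members))
    out = pd.DataFrame(rows, columns=["chrom", "start", "end", "_members"])
    for name in sets:
        out[name] = out["_members"].map(lambda m, n=name: n in m)
    return out.drop(columns="_members")
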