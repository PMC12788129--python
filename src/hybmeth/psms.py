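"""Parent-specific methylation site (PSMS) identification.

A PSMS is a cytosine that exists in only one parent's genome (a C<->non-C
SNP) and is methylated in the F1.  Five conjunctive rules are verified by
cross-checking resequencing genotypes against the WGBS tables:

  (i)   the parents are homozygous for different alleles at the SNP;
  (ii)  the F1 is heterozygous for exactly the two parental alleles;
  (iii) the resequencing genotype is concordant with WGBS: the C-carrying
        parent's methylome has a record at the position/strand and the
        non-C parent's has none (bisulfite reads cannot distinguish C->T
        variants directly, so concordance is checked as record
        presence/absence);
  (iv)  reads supporting methylation on the F1's non-C allele number
        exactly zero (no tolerance);
  (v)   the F1 cytosine is called methylated by the one-sided binomial
        test against the bisulfite conversion-failure rate.

The origin parent of an emitted PSMS is always the parent whose allele
carries the cytosine on the recorded strand.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import formats_io as fio
from ._stats import binom_greater_pvals

ALL_RULES = frozenset({"i", "ii", "iii", "iv", "v"})

PSMS_COLUMNS = ["chrom", "pos", "strand", "context", "origin",
                "f1_mc_count", "f1_total_count",
                "rule_i", "rule_ii", "rule_iii", "rule_iv", "rule_v"]


def _c_base(strand: str) -> str:
    return "C" if strand == "+" else "G"


def identify_psms(variants: pd.DataFrame, mother_meth: pd.DataFrame,
                  father_meth: pd.DataFrame, f1_meth: pd.DataFrame,
                  f1_allele_meth: pd.DataFrame | None,
                  fail_rate: float = 0.006, alpha: float = 0.05,
                  rules: frozenset = ALL_RULES,
                  mother: str = "mother", father: str = "father",
                  f1: str = "f1") -> pd.DataFrame:
    """Apply the five-rule procedure; emit sites passing every active rule.

    ``variants`` is a trio genotype frame (``read_vcf_minimal`` output).
    ``rules`` may be a subset for ablation studies — rules outside it are
    recorded but not enforced, so shrinking the set can only enlarge the
    output.  ``f1_allele_meth`` is required whenever rule iv is active.
    """
    if "iv" in rules and f1_allele_meth is None:
        raise ValueError("rule iv needs the allele-resolved F1 methylation table")
    if not 0.0 <= fail_rate < 1.0:
        raise ValueError("fail_rate must be in [0, 1)")

    def key(df):
        return pd.MultiIndex.from_frame(df[["chrom", "pos", "strand"]])

    meth_presence = {
        "mother": set(key(mother_meth[mother_meth["total_count"] > 0])),
        "father": set(key(father_meth[father_meth["total_count"] > 0])),
    }
    f1_idx = f1_meth.set_index(["chrom", "pos", "strand"])
    f1_p = pd.Series(
        binom_greater_pvals(f1_meth["mc_count"].to_numpy(),
                            f1_meth["total_count"].to_numpy(), fail_rate),
        index=f1_idx.index)
    if f1_allele_meth is not None:
        am = f1_allele_meth.set_index(["chrom", "pos", "strand", "allele"])
    else:
        am = None

    rows = []
    for v in variants.itertuples(index=False):
        gm = getattr(v, f"gt_{mother}")
        gf = getattr(v, f"gt_{father}")
        g1 = getattr(v, f"gt_{f1}")
        rule_i = (gm in (fio.HOM_REF, fio.HOM_ALT)
                  and gf in (fio.HOM_REF, fio.HOM_ALT) and gm != gf)
        rule_ii = g1 == fio.HET
        if ("i" in rules and not rule_i) or ("ii" in rules and not rule_ii):
            continue
        if not rule_i:
            # origin is undefined without homozygous-different parents
            continue
        mat_base = v.ref if gm == fio.HOM_REF else v.alt
        pat_base = v.ref if gf == fio.HOM_REF else v.alt
        for strand in ("+", "-"):
            cb = _c_base(strand)
            mat_has_c = mat_base == cb
            pat_has_c = pat_base == cb
            if mat_has_c == pat_has_c:
                continue  # not a C<->non-C SNP on this strand
            origin = "mother" if mat_has_c else "father"
            non_c_parent = "father" if mat_has_c else "mother"
            non_c_allele = "paternal" if mat_has_c else "maternal"
            k = (v.chrom, v.pos, strand)
            rule_iii = (k in meth_presence[origin]
                        and k not in meth_presence[non_c_parent])
            if am is not None:
                ak = (v.chrom, v.pos, strand, non_c_allele)
                rule_iv = (ak in am.index
                           and int(am.loc[ak, "mc_count"]) == 0)
            else:
                rule_iv = False
            if k in f1_idx.index:
                mc = int(f1_idx.loc[k, "mc_count"])
                tot = int(f1_idx.loc[k, "total_count"])
                rule_v = bool(f1_p.loc[k] <= alpha) and mc > 0
                ctx = f1_idx.loc[k, "context"]
            else:
                mc, tot, rule_v, ctx = 0, 0, False, None
            flags = {"i": rule_i, "ii": rule_ii, "iii": rule_iii,
                     "iv": rule_iv, "v": rule_v}
            if all(flags[r] for r in rules):
                rows.append((v.chrom, v.pos, strand, ctx, origin, mc, tot,
                             rule_i, rule_ii, rule_iii, rule_iv, rule_v))
    out = pd.DataFrame(rows, columns=PSMS_COLUMNS)
    return out.sort_values(["chrom", "pos", "strand"]).reset_index(drop=True)


def assign_psms_to_genes(psms: pd.DataFrame, annotation: pd.DataFrame,
                         flank_bp: int = 2000) -> pd.DataFrame:
    """Assign each PSMS to every gene whose span +- ``flank_bp`` contains it.

    Multi-assignment (overlapping genes) is allowed; returns one row per
    (gene, PSMS) pair with the PSMS columns plus ``gene_id``.
    """
    out = []
    for chrom, sub in psms.groupby("chrom", sort=False):
        genes = annotation[annotation["chrom"] == chrom]
        for g in genes.itertuples(index=False):
            lo, hi = g.start - flank_bp, g.end + flank_bp
            inside = (sub["pos"] >= lo) & (sub["pos"] <= hi)
            if inside.any():
                out.append(sub.loc[inside].assign(gene_id=g.gene_id))
    if not out:
        return psms.assign(gene_id=pd.Series(dtype=object)).iloc[0:0]
    res = pd.concat(out, ignore_index=True)
    return res.sort_values(["gene_id", "chrom", "pos", "strand"]).reset_index(drop=True)


def psms_precision_on_truth(psms: pd.DataFrame,
                            ground_truth: pd.DataFrame) -> tuple[float, float]:
    """Precision and recall of PSMS calls against simulation ground truth.

    Compared as sets of (chrom, pos, strand, origin).  An empty call set has
    precision NaN (by convention) and recall 0.
    """
    called = set(map(tuple, psms[["chrom", "pos", "strand", "origin"]].to_numpy()))
    truth = set(map(tuple,
                    ground_truth[["chrom", "pos", "strand", "origin"]].to_numpy()))
    tp = len(called & truth)
    precision = tp / len(called) if called else float("nan")
    recall = tp / len(truth) if truth else float("nan")
    return precision, recall
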