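"""Readers and writers for the on-disk formats the pipeline touches.

All coordinates are 1-based inclusive in memory; BED output is converted to
0-based half-open only at the file boundary.  Collections of records are
represented as :class:`pandas.DataFrame` objects with fixed column schemas
(the natural container for genome-scale tables); frozen dataclasses are
provided for single records and carry the per-record invariants.

Methylation call tables are a 6-column TSV::

    chrom  pos  strand  context  mc_count  total_count

with ``pos`` 1-based, ``strand`` in ``{+,-}``, ``context`` in
``{CG, CHG, CHH}`` read 5'->3' on the cytosine's own strand, and
``mc_count <= total_count``.  Plus- and minus-strand records at a CG dyad
are distinct records and are never pooled.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

CONTEXTS = ("CG", "CHG", "CHH")
STRANDS = ("+", "-")

#: genotype codes used throughout
HOM_REF = "hom_ref"
HET = "het"
HOM_ALT = "hom_alt"
MISSING = "missing"

METH_COLUMNS = ["chrom", "pos", "strand", "context", "mc_count", "total_count"]
ALLELE_METH_COLUMNS = [
    "chrom", "pos", "strand", "context", "allele", "mc_count", "total_count",
]
ALLELE_DEPTH_COLUMNS = ["chrom", "pos", "maternal_reads", "paternal_reads", "sample"]
GENE_COLUMNS = ["gene_id", "chrom", "start", "end", "strand"]

ALLELES = ("maternal", "paternal")


class FormatError(ValueError):
    """A file or record violates its format contract."""


@dataclass(frozen=True)
class MethCallRecord:
    """One cytosine's methylation evidence in one sample."""

    chrom: str
    pos: int
    strand: str
    context: str
    mc_count: int
    total_count: int

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise FormatError(f"pos must be >= 1, got {self.pos}")
        if self.strand not in STRANDS:
            raise FormatError(f"strand must be one of {STRANDS}, got {self.strand!r}")
        if self.context not in CONTEXTS:
            raise FormatError(f"context must be one of {CONTEXTS}, got {self.context!r}")
        if self.mc_count < 0 or self.total_count < 0:
            raise FormatError("counts must be non-negative")
        if self.mc_count > self.total_count:
            raise FormatError(
                f"mc_count {self.mc_count} exceeds total_count {self.total_count}"
            )


@dataclass(frozen=True)
class VariantRecord:
    """A biallelic SNP with per-sample diploid genotype calls."""

    chrom: str
    pos: int
    ref: str
    alt: str
    genotypes: dict  # sample -> one of HOM_REF/HET/HOM_ALT/MISSING
    depth: dict  # sample -> int >= 0

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise FormatError("ref and alt must differ")
        if len(self.ref) != 1 or len(self.alt) != 1:
            raise FormatError("only single-base SNPs are valid VariantRecords")


@dataclass(frozen=True)
class GeneAnnotation:
    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise FormatError(f"gene {self.gene_id}: start > end")


@dataclass(frozen=True)
class AlleleDepthRecord:
    """Allele-resolved RNA read counts at one PSNP in one sample."""

    chrom: str
    pos: int
    maternal_reads: int
    paternal_reads: int
    sample: str

    def __post_init__(self) -> None:
        if self.maternal_reads < 0 or self.paternal_reads < 0:
            raise FormatError("allele read counts must be non-negative")


# ---------------------------------------------------------------------------
# methylation call tables
# ---------------------------------------------------------------------------

def validate_meth_frame(df: pd.DataFrame, path: str | Path | None = None) -> pd.DataFrame:
    """Validate invariants on a methylation frame and sort by (chrom, pos, strand).

    Raises :class:`FormatError` naming the offending file line (header is
    line 1) on the first violation found.
    """
    src = f"{path}: " if path is not None else ""
    if list(df.columns) != METH_COLUMNS:
        raise FormatError(f"{src}expected columns {METH_COLUMNS}, got {list(df.columns)}")
    for col in ("pos", "mc_count", "total_count"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() | (vals != np.floor(vals.fillna(0)))
        if bad.any():
            line = int(np.flatnonzero(bad.to_numpy())[0]) + 2
            raise FormatError(f"{src}line {line}: non-integer {col!r}")
        df[col] = vals.astype(np.int64)

    def _first_bad(mask: pd.Series, msg: str) -> None:
        if mask.any():
            line = int(np.flatnonzero(mask.to_numpy())[0]) + 2
            raise FormatError(f"{src}line {line}: {msg}")

    _first_bad(df["pos"] < 1, "pos < 1")
    _first_bad(~df["strand"].isin(STRANDS), "invalid strand")
    _first_bad(~df["context"].isin(CONTEXTS), "invalid context")
    _first_bad((df["mc_count"] < 0) | (df["total_count"] < 0), "negative count")
    _first_bad(df["mc_count"] > df["total_count"], "mc_count > total_count")
    df = df.sort_values(["chrom", "pos", "strand"], kind="mergesort").reset_index(drop=True)
    df["chrom"] = df["chrom"].astype(str)
    return df


def read_meth_table(path: str | Path) -> pd.DataFrame:
    """Read a 6-column methylation TSV into a validated, sorted DataFrame."""
    try:
        df = pd.read_csv(path, sep="\t", header=0, dtype=str)
    except pd.errors.ParserError as exc:  # pragma: no cover - pandas message varies
        raise FormatError(f"{path}: malformed table: {exc}") from exc
    return validate_meth_frame(df, path=path)


def write_meth_table(records: pd.DataFrame | Iterable[MethCallRecord],
                     path: str | Path) -> None:
    """Write a methylation table; ``read_meth_table`` round-trips it exactly."""
    df = meth_frame(records) if not isinstance(records, pd.DataFrame) else records
    df = validate_meth_frame(df.copy())
    df.to_csv(path, sep="\t", index=False)


def meth_frame(records: Iterable[MethCallRecord]) -> pd.DataFrame:
    rows = [(r.chrom, r.pos, r.strand, r.context, r.mc_count, r.total_count)
            for r in records]
    return pd.DataFrame(rows, columns=METH_COLUMNS)


def meth_records(df: pd.DataFrame) -> list[MethCallRecord]:
    return [MethCallRecord(*row) for row in df[METH_COLUMNS].itertuples(index=False)]


# ---------------------------------------------------------------------------
# allele-resolved F1 methylation table
# ---------------------------------------------------------------------------

def read_allele_meth_table(path: str | Path) -> pd.DataFrame:
    """Read the F1 allele-resolved methylation table.

    Same dialect as the methylation table plus an ``allele`` column in
    ``{maternal, paternal}``; ``mc_count``/``total_count`` are the counts of
    reads assigned to that parental allele.
    """
    df = pd.read_csv(path, sep="\t", header=0, dtype=str)
    if list(df.columns) != ALLELE_METH_COLUMNS:
        raise FormatError(f"{path}: expected columns {ALLELE_METH_COLUMNS}")
    bad = ~df["allele"].isin(ALLELES)
    if bad.any():
        line = int(np.flatnonzero(bad.to_numpy())[0]) + 2
        raise FormatError(f"{path}: line {line}: invalid allele")
    for col in ("pos", "mc_count", "total_count"):
        df[col] = pd.to_numeric(df[col]).astype(np.int64)
    if (df["mc_count"] > df["total_count"]).any():
        raise FormatError(f"{path}: mc_count > total_count")
    return df.sort_values(["chrom", "pos", "strand", "allele"],
                          kind="mergesort").reset_index(drop=True)


def write_allele_meth_table(df: pd.DataFrame, path: str | Path) -> None:
    df[ALLELE_METH_COLUMNS].to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# allele depth (RNA) tables
# ---------------------------------------------------------------------------

def read_allele_depth_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=0, dtype=str)
    if list(df.columns) != ALLELE_DEPTH_COLUMNS:
        raise FormatError(f"{path}: expected columns {ALLELE_DEPTH_COLUMNS}")
    for col in ("pos", "maternal_reads", "paternal_reads"):
        df[col] = pd.to_numeric(df[col]).astype(np.int64)
        if (df[col] < 0).any():
            raise FormatError(f"{path}: negative {col}")
    return df.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)


def write_allele_depth_table(df: pd.DataFrame, path: str | Path) -> None:
    df[ALLELE_DEPTH_COLUMNS].to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# gene annotation
# ---------------------------------------------------------------------------

def read_gene_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=0, dtype=str)
    if list(df.columns) != GENE_COLUMNS:
        raise FormatError(f"{path}: expected columns {GENE_COLUMNS}")
    for col in ("start", "end"):
        df[col] = pd.to_numeric(df[col]).astype(np.int64)
    if (df["start"] > df["end"]).any():
        raise FormatError(f"{path}: start > end")
    if df["gene_id"].duplicated().any():
        raise FormatError(f"{path}: duplicate gene_id")
    return df.reset_index(drop=True)


def write_gene_table(df: pd.DataFrame, path: str | Path) -> None:
    df[GENE_COLUMNS].to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def _parse_gt(raw: str, where: str) -> str:
    alleles = raw.replace("|", "/").split("/")
    codes = []
    for a in alleles:
        if a == ".":
            continue
        if a not in ("0", "1"):
            raise FormatError(f"{where}: malformed GT {raw!r}")
        codes.append(int(a))
    if len(codes) < 2:
        return MISSING
    if codes[0] == codes[1]:
        return HOM_REF if codes[0] == 0 else HOM_ALT
    return HET


def read_vcf_minimal(path: str | Path) -> tuple[pd.DataFrame, int]:
    """Read biallelic SNP rows from a VCF 4.x with GT in FORMAT.

    Returns ``(frame, n_skipped)`` where the frame has columns
    ``chrom, pos, ref, alt`` plus ``gt_<sample>`` (genotype code) and
    ``dp_<sample>`` (depth, -1 when absent) per sample, and ``n_skipped``
    counts multiallelic/indel rows dropped.

    Parsed directly from the text (a genotype referencing an allele index
    outside the biallelic pair must raise a record-level error, which
    htslib-based readers silently coerce to missing).
    """
    samples: list[str] = []
    rows = []
    skipped = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if line.startswith("##") or not line:
                continue
            fields = line.split("\t")
            if line.startswith("#CHROM"):
                if len(fields) < 10:
                    raise FormatError(f"{path}: header has no samples")
                samples = fields[9:]
                continue
            if not samples:
                raise FormatError(f"{path}: missing #CHROM header line")
            if len(fields) != 9 + len(samples):
                raise FormatError(f"{path}: line {lineno}: wrong field count")
            chrom, pos, _, ref, alt, _, _, _, fmt = fields[:9]
            fmt_keys = fmt.split(":")
            if "GT" not in fmt_keys:
                raise FormatError(f"{path}: line {lineno}: FORMAT lacks GT")
            alts = alt.split(",")
            if len(alts) != 1 or len(ref) != 1 or len(alts[0]) != 1 \
                    or alts[0] == ".":
                skipped += 1
                continue
            row: dict = {"chrom": chrom, "pos": int(pos),
                         "ref": ref, "alt": alts[0]}
            gt_i = fmt_keys.index("GT")
            dp_i = fmt_keys.index("DP") if "DP" in fmt_keys else None
            for s, sample_field in zip(samples, fields[9:]):
                parts = sample_field.split(":")
                where = f"{path}: line {lineno}: sample {s}"
                if gt_i >= len(parts):
                    raise FormatError(f"{where}: missing GT value")
                row[f"gt_{s}"] = _parse_gt(parts[gt_i], where)
                dp = None
                if dp_i is not None and dp_i < len(parts) and parts[dp_i] != ".":
                    dp = int(parts[dp_i])
                row[f"dp_{s}"] = dp if dp is not None else -1
            rows.append(row)
    if skipped:
        logger.info("read_vcf_minimal: skipped %d non-biallelic-SNP rows", skipped)
    cols = ["chrom", "pos", "ref", "alt"]
    for s in samples:
        cols += [f"gt_{s}", f"dp_{s}"]
    df = pd.DataFrame(rows, columns=cols)
    if len(df):
        df["pos"] = df["pos"].astype(np.int64)
    return df, skipped


def write_vcf_minimal(df: pd.DataFrame, samples: Sequence[str],
                      contigs: dict[str, int], path: str | Path) -> None:
    """Write a minimal VCF 4.2 from a frame with gt_<sample>/dp_<sample> columns."""
    gt_str = {HOM_REF: "0/0", HET: "0/1", HOM_ALT: "1/1", MISSING: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for name, length in contigs.items():
            fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples) + "\n")
        for row in df.itertuples(index=False):
            fields = [row.chrom, str(row.pos), ".", row.ref, row.alt, ".", "PASS",
                      ".", "GT:DP"]
            for s in samples:
                gt = gt_str[getattr(row, f"gt_{s}")]
                dp = getattr(row, f"dp_{s}")
                fields.append(f"{gt}:{dp}" if dp >= 0 else f"{gt}:.")
            fh.write("\t".join(fields) + "\n")


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------

def write_bed(intervals: pd.DataFrame, path: str | Path) -> None:
    """Write 1-based inclusive intervals as BED (0-based half-open).

    ``intervals`` needs columns ``chrom, start, end`` and may carry
    ``name, score, strand`` (BED3+3).  ``start > end`` raises.
    """
    df = intervals.copy()
    if (df["start"] > df["end"]).any():
        raise FormatError("interval with start > end")
    if (df["start"] < 1).any():
        raise FormatError("interval with start < 1")
    out = pd.DataFrame({
        "chrom": df["chrom"],
        "start": df["start"].astype(np.int64) - 1,
        "end": df["end"].astype(np.int64),
    })
    for col, default in (("name", "."), ("score", 0), ("strand", ".")):
        if col in df.columns:
            out[col] = df[col]
        elif any(c in df.columns for c in ("name", "score", "strand")):
            out[col] = default
    out.to_csv(path, sep="\t", index=False, header=False)


def read_bed(path: str | Path) -> pd.DataFrame:
    """Read BED3(+) back to 1-based inclusive internal intervals."""
    df = pd.read_csv(path, sep="\t", header=None)
    df = df.rename(columns={0: "chrom", 1: "start", 2: "end", 3: "name",
                            4: "score", 5: "strand"})
    df["start"] = df["start"].astype(np.int64) + 1
    df["end"] = df["end"].astype(np.int64)
    return df
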