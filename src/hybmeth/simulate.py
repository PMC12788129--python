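"""Ground-truthed synthetic trio generator.

Emulates a cross between two diverged parents and their F1: two parental
genomes differing by homozygous SNPs (a configurable fraction of which
create or destroy a cytosine in exactly one parent), per-site latent
methylation propensities drawn from per-context beta distributions,
WGBS-style count tables with Poisson coverage and bisulfite conversion
failure, an unmethylated lambda spike-in contig, and negative-binomial
allele-resolved RNA counts with a configurable fraction of truly biased
genes.

The F1 methylome is an equal mixture of the two parental alleles.  Each
chromosome is tiled into regions that are assigned an inheritance mode:
``additive`` (alleles keep their parental propensities), ``maternal_like``
/ ``paternal_like`` (both alleles adopt one parent's propensity), or the
transgressive ``above_parent`` / ``below_parent`` (both alleles shifted
beyond the higher/lower parent by a fixed delta).  At a C<->non-C SNP the
parent lacking the cytosine emits no methylation record there, and F1
reads carrying the non-C allele contribute no methylation support (they
read as the alternate base) while still counting toward site depth.

Every random draw flows from ``SimulationConfig.seed`` through a single
``numpy.random.Generator``, so identical configs give byte-identical
outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import formats_io as fio

logger = logging.getLogger(__name__)

BASES = np.array(["A", "C", "G", "T"])

MODES = ("additive", "maternal_like", "paternal_like", "above_parent", "below_parent")


def _default_beta_params() -> dict:
    # U-shaped per-context propensity laws: means ~0.8 (CG), 0.7 (CHG), 0.2 (CHH)
    return {"CG": (0.8, 0.2), "CHG": (0.7, 0.3), "CHH": (0.2, 0.8)}


def _default_mode_weights() -> dict:
    return {"additive": 0.6, "maternal_like": 0.15, "paternal_like": 0.15,
            "above_parent": 0.05, "below_parent": 0.05}


@dataclass
class SimulationConfig:
    """All knobs of the generator; ``seed`` fixes every random draw."""

    seed: int = 0
    n_chromosomes: int = 2
    chrom_length: int = 250_000
    n_genes: int = 300
    snp_rate: float = 0.005
    c_snp_fraction: float = 0.5
    coverage: float = 15.0
    conversion_failure: float = 0.006
    beta_params: dict = field(default_factory=_default_beta_params)
    mode_weights: dict = field(default_factory=_default_mode_weights)
    region_bp: int = 5000
    transgressive_delta: float = 0.3
    parent_site_diff_prob: float = 0.02
    parent_region_diff_prob: float = 0.10
    gc_content: float = 0.38
    lambda_length: int = 48_502
    gene_length_min: int = 500
    gene_length_max: int = 1500
    aei_fraction: float = 0.1
    aei_fold: float = 3.0
    rna_mean: float = 300.0
    rna_dispersion: float = 0.1

    def __post_init__(self) -> None:
        for name in ("snp_rate", "c_snp_fraction", "conversion_failure",
                     "parent_site_diff_prob", "parent_region_diff_prob",
                     "gc_content", "aei_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        w = sum(self.mode_weights.values())
        if abs(w - 1.0) > 1e-9:
            raise ValueError(f"mode_weights must sum to 1, got {w}")
        if set(self.mode_weights) - set(MODES):
            raise ValueError(f"unknown inheritance mode in {self.mode_weights}")
        if self.aei_fold < 1.0:
            raise ValueError("aei_fold must be >= 1")
        if self.coverage <= 0:
            raise ValueError("coverage must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if "beta_params" in data:
            data["beta_params"] = {k: tuple(v) for k, v in data["beta_params"].items()}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        data = dataclasses.asdict(self)
        data["beta_params"] = {k: list(v) for k, v in data["beta_params"].items()}
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)


@dataclass
class GroundTruth:
    """Per-site, per-region, per-gene and per-PSMS truth for recovery tests."""

    sites: pd.DataFrame      # chrom,pos,strand,context,p_mother,p_father,p_f1_maternal,p_f1_paternal,mode
    regions: pd.DataFrame    # chrom,start,end,mode
    psms: pd.DataFrame       # chrom,pos,strand,origin
    genes: pd.DataFrame      # gene_id,klass,mu_maternal,mu_paternal  (filled by simulate_allelic_counts)


# ---------------------------------------------------------------------------
# genomes, SNPs, genes
# ---------------------------------------------------------------------------

def cytosine_sites(seq: np.ndarray) -> pd.DataFrame:
    """All cytosines (both strands) of a sequence with their context.

    ``seq`` is a 1-d array of single-character bases.  Returns 1-based
    ``pos``, ``strand`` and ``context``; cytosines within 2 bp of either
    chromosome end are skipped (context undefined).
    """
    L = len(seq)
    frames = []
    idx = np.flatnonzero(seq == "C")
    idx = idx[(idx >= 2) & (idx <= L - 3)]
    if len(idx):
        n1, n2 = seq[idx + 1], seq[idx + 2]
        ctx = np.where(n1 == "G", "CG", np.where(n2 == "G", "CHG", "CHH"))
        frames.append(pd.DataFrame({"pos": idx + 1, "strand": "+", "context": ctx}))
    idx = np.flatnonzero(seq == "G")
    idx = idx[(idx >= 2) & (idx <= L - 3)]
    if len(idx):
        n1, n2 = seq[idx - 1], seq[idx - 2]  # 5'->3' on minus strand, complemented
        ctx = np.where(n1 == "C", "CG", np.where(n2 == "C", "CHG", "CHH"))
        frames.append(pd.DataFrame({"pos": idx + 1, "strand": "-", "context": ctx}))
    if not frames:
        return pd.DataFrame(columns=["pos", "strand", "context"])
    out = pd.concat(frames, ignore_index=True)
    return out.sort_values(["pos", "strand"], kind="mergesort").reset_index(drop=True)


def _random_sequence(rng: np.random.Generator, length: int, gc: float) -> np.ndarray:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return rng.choice(BASES, size=length, p=probs)


def simulate_parental_genomes(config: SimulationConfig,
                              rng: np.random.Generator | None = None):
    """Simulate parental genomes, their homozygous-different SNPs, and genes.

    Returns ``(genomes, variants, genes)`` where ``genomes`` maps chromosome
    name to ``{"mother": seq, "father": seq}``.  The mother's genome is the
    reference (VCF REF alleles).  Variants carry ``c_parent``/``c_strand``
    marking parent-specific cytosines (the PSMS substrate); non-C SNPs are
    A<->T swaps so neither allele touches a cytosine.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    genomes: dict[str, dict[str, np.ndarray]] = {}
    var_rows = []
    gene_rows = []
    per_chrom = _split_evenly(config.n_genes, config.n_chromosomes)
    for ci in range(config.n_chromosomes):
        chrom = f"chr{ci + 1}"
        L = config.chrom_length
        mother = _random_sequence(rng, L, config.gc_content)
        father = mother.copy()

        n_snp = rng.binomial(L, config.snp_rate)
        n_c = rng.binomial(n_snp, config.c_snp_fraction)
        n_nc = n_snp - n_c
        interior = np.arange(2, L - 2)
        is_cg = np.isin(mother[interior], ["C", "G"])
        cg_pool = interior[is_cg]
        at_pool = interior[~is_cg]

        n_mother_origin = rng.binomial(n_c, 0.5)
        n_mother_origin = min(n_mother_origin, len(cg_pool))
        n_father_origin = n_c - n_mother_origin
        pos_mo = rng.choice(cg_pool, size=n_mother_origin, replace=False)
        remaining_at = np.setdiff1d(at_pool, [])
        pick = rng.choice(len(remaining_at), size=n_father_origin + n_nc, replace=False)
        pos_fo = remaining_at[pick[:n_father_origin]]
        pos_nc = remaining_at[pick[n_father_origin:]]

        # mother-origin C: mother keeps C (or G = minus-strand C), father -> A/T
        for p in np.sort(pos_mo):
            strand = "+" if mother[p] == "C" else "-"
            father[p] = rng.choice(["A", "T"])
            var_rows.append((chrom, p + 1, mother[p], father[p], "mother", strand))
        # father-origin C: mother has A/T, father gains C (plus) or G (minus)
        for p in np.sort(pos_fo):
            base = rng.choice(["C", "G"])
            strand = "+" if base == "C" else "-"
            father[p] = base
            var_rows.append((chrom, p + 1, mother[p], father[p], "father", strand))
        # non-C SNPs: A<->T swap
        for p in np.sort(pos_nc):
            father[p] = "T" if mother[p] == "A" else "A"
            var_rows.append((chrom, p + 1, mother[p], father[p], None, None))

        genomes[chrom] = {"mother": mother, "father": father}
        gene_rows += _place_genes(rng, chrom, L, per_chrom[ci], config)

    variants = pd.DataFrame(
        var_rows, columns=["chrom", "pos", "ref", "alt", "c_parent", "c_strand"])
    variants = variants.sort_values(["chrom", "pos"]).reset_index(drop=True)
    genes = pd.DataFrame(gene_rows, columns=fio.GENE_COLUMNS)
    return genomes, variants, genes


def _split_evenly(total: int, parts: int) -> list[int]:
    base = total // parts
    out = [base] * parts
    for i in range(total - base * parts):
        out[i] += 1
    return out


def _place_genes(rng, chrom, L, n, config) -> list[tuple]:
    if n == 0:
        return []
    lengths = rng.integers(config.gene_length_min, config.gene_length_max + 1, size=n)
    slack = L - int(lengths.sum())
    if slack < n + 1:
        raise ValueError(
            f"chrom_length {L} too small for {n} genes of length up to "
            f"{config.gene_length_max}")
    gaps = rng.multinomial(slack - (n + 1), np.full(n + 1, 1.0 / (n + 1))) + 1
    rows = []
    cursor = 1
    for i in range(n):
        cursor += int(gaps[i])
        start = cursor
        end = start + int(lengths[i]) - 1
        strand = "+" if rng.random() < 0.5 else "-"
        rows.append((f"gene_{chrom}_{i + 1:04d}", chrom, start, end, strand))
        cursor = end + 1
    return rows


# ---------------------------------------------------------------------------
# methylomes
# ---------------------------------------------------------------------------

def _draw_beta(rng, contexts: np.ndarray, beta_params: dict) -> np.ndarray:
    out = np.empty(len(contexts))
    for ctx, (a, b) in beta_params.items():
        m = contexts == ctx
        out[m] = rng.beta(a, b, size=int(m.sum()))
    return out


def _effective_rate(p: np.ndarray, fail: float) -> np.ndarray:
    # unmethylated reads escape conversion with probability `fail`
    return p * (1 - fail) + (1 - p) * fail


def simulate_methylomes(config: SimulationConfig, genomes: dict,
                        variants: pd.DataFrame,
                        rng: np.random.Generator | None = None):
    """Simulate WGBS call tables for mother, father, F1 plus the lambda contig.

    Returns a dict with keys ``mother``, ``father``, ``f1``, ``lambda``
    (methylation frames), ``f1_allele`` (allele-resolved F1 frame) and
    ``truth`` (:class:`GroundTruth` with empty ``genes``).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    fail = config.conversion_failure
    m_frames, f_frames, f1_frames, allele_frames = [], [], [], []
    truth_site_frames, truth_region_rows = [], []

    for chrom, seqs in genomes.items():
        sm = cytosine_sites(seqs["mother"]).rename(columns={"context": "context_m"})
        sf = cytosine_sites(seqs["father"]).rename(columns={"context": "context_f"})
        sites = sm.merge(sf, on=["pos", "strand"], how="outer", sort=True)
        sites["has_m"] = sites["context_m"].notna()
        sites["has_f"] = sites["context_f"].notna()
        ctx = sites["context_m"].where(sites["has_m"], sites["context_f"]).to_numpy()
        n = len(sites)
        pos = sites["pos"].to_numpy()

        p_base = _draw_beta(rng, ctx, config.beta_params)
        p_m = p_base.copy()
        p_f = p_base.copy()

        # region-scale parental divergence: one randomly chosen parent's
        # propensity is flipped to 1-p throughout the region
        n_regions = int(np.ceil(config.chrom_length / config.region_bp))
        divergent = rng.random(n_regions) < config.parent_region_diff_prob
        flip_to_father = rng.random(n_regions) < 0.5
        region_idx = (pos - 1) // config.region_bp
        div_sites = divergent[region_idx]
        to_f = div_sites & flip_to_father[region_idx]
        to_m = div_sites & ~flip_to_father[region_idx]
        p_f[to_f] = 1 - p_base[to_f]
        p_m[to_m] = 1 - p_base[to_m]

        # site-scale divergence: one parent redrawn from its context law
        redraw = rng.random(n) < config.parent_site_diff_prob
        which_f = rng.random(n) < 0.5
        rf = redraw & which_f
        rm = redraw & ~which_f
        p_f[rf] = _draw_beta(rng, ctx[rf], config.beta_params)
        p_m[rm] = _draw_beta(rng, ctx[rm], config.beta_params)

        has_m = sites["has_m"].to_numpy()
        has_f = sites["has_f"].to_numpy()
        p_m[~has_m] = np.nan
        p_f[~has_f] = np.nan

        # inheritance mode per region -> F1 allele propensities
        modes = np.array(list(config.mode_weights))
        weights = np.array([config.mode_weights[m] for m in modes])
        region_mode = rng.choice(modes, size=n_regions, p=weights)
        site_mode = region_mode[region_idx]
        for r in range(n_regions):
            start = r * config.region_bp + 1
            end = min((r + 1) * config.region_bp, config.chrom_length)
            truth_region_rows.append((chrom, start, end, region_mode[r]))

        pm_eff = np.where(np.isnan(p_m), p_f, p_m)
        pf_eff = np.where(np.isnan(p_f), p_m, p_f)
        hi = np.maximum(pm_eff, pf_eff)
        lo = np.minimum(pm_eff, pf_eff)
        delta = config.transgressive_delta
        p1m = np.select(
            [site_mode == "maternal_like", site_mode == "paternal_like",
             site_mode == "above_parent", site_mode == "below_parent"],
            [pm_eff, pf_eff, np.clip(hi + delta, 0, 1), np.clip(lo - delta, 0, 1)],
            default=pm_eff)
        p1p = np.select(
            [site_mode == "maternal_like", site_mode == "paternal_like",
             site_mode == "above_parent", site_mode == "below_parent"],
            [pm_eff, pf_eff, np.clip(hi + delta, 0, 1), np.clip(lo - delta, 0, 1)],
            default=pf_eff)
        # an allele without a cytosine has no methylation propensity
        p1m[~has_m] = np.nan
        p1p[~has_f] = np.nan

        # parental counts
        for p_arr, has, ctx_col, frames in (
                (p_m, has_m, "context_m", m_frames),
                (p_f, has_f, "context_f", f_frames)):
            cov = rng.poisson(config.coverage, size=int(has.sum()))
            eff = _effective_rate(p_arr[has], fail)
            mc = rng.binomial(cov, eff)
            frames.append(pd.DataFrame({
                "chrom": chrom, "pos": pos[has],
                "strand": sites["strand"].to_numpy()[has],
                "context": sites[ctx_col].to_numpy()[has],
                "mc_count": mc, "total_count": cov}))

        # F1: per-read fair allele choice; non-C alleles give no mC support
        cov = rng.poisson(config.coverage, size=n)
        a_reads = rng.binomial(cov, 0.5)
        p_reads = cov - a_reads
        mc_m = np.where(has_m, rng.binomial(a_reads, _effective_rate(
            np.nan_to_num(p1m), fail)), 0)
        mc_p = np.where(has_f, rng.binomial(p_reads, _effective_rate(
            np.nan_to_num(p1p), fail)), 0)
        strand = sites["strand"].to_numpy()
        f1_frames.append(pd.DataFrame({
            "chrom": chrom, "pos": pos, "strand": strand, "context": ctx,
            "mc_count": mc_m + mc_p, "total_count": cov}))
        allele_frames.append(pd.DataFrame({
            "chrom": np.repeat(chrom, 2 * n),
            "pos": np.repeat(pos, 2),
            "strand": np.repeat(strand, 2),
            "context": np.repeat(ctx, 2),
            "allele": np.tile(np.array(["maternal", "paternal"]), n),
            "mc_count": np.column_stack([mc_m, mc_p]).reshape(-1),
            "total_count": np.column_stack([a_reads, p_reads]).reshape(-1)}))

        truth_site_frames.append(pd.DataFrame({
            "chrom": chrom, "pos": pos, "strand": strand, "context": ctx,
            "p_mother": p_m, "p_father": p_f,
            "p_f1_maternal": p1m, "p_f1_paternal": p1p, "mode": site_mode}))

    # lambda spike-in: fully unmethylated
    lam_seq = _random_sequence(rng, config.lambda_length, 0.5)
    lam_sites = cytosine_sites(lam_seq)
    cov = rng.poisson(config.coverage, size=len(lam_sites))
    mc = rng.binomial(cov, fail)
    lam = pd.DataFrame({
        "chrom": "lambda", "pos": lam_sites["pos"], "strand": lam_sites["strand"],
        "context": lam_sites["context"], "mc_count": mc, "total_count": cov})

    psms_truth = variants.loc[variants["c_parent"].notna(),
                              ["chrom", "pos", "c_strand", "c_parent"]]
    psms_truth = psms_truth.rename(columns={"c_strand": "strand",
                                            "c_parent": "origin"}).reset_index(drop=True)
    truth = GroundTruth(
        sites=pd.concat(truth_site_frames, ignore_index=True),
        regions=pd.DataFrame(truth_region_rows,
                             columns=["chrom", "start", "end", "mode"]),
        psms=psms_truth,
        genes=pd.DataFrame(columns=["gene_id", "klass", "mu_maternal", "mu_paternal"]))

    def _cat(frames):
        df = pd.concat(frames, ignore_index=True)[fio.METH_COLUMNS]
        return df.sort_values(["chrom", "pos", "strand"],
                              kind="mergesort").reset_index(drop=True)

    return {
        "mother": _cat(m_frames),
        "father": _cat(f_frames),
        "f1": _cat(f1_frames),
        "lambda": lam[fio.METH_COLUMNS].reset_index(drop=True),
        "f1_allele": pd.concat(allele_frames, ignore_index=True)[
            fio.ALLELE_METH_COLUMNS].reset_index(drop=True),
        "truth": truth,
    }


# ---------------------------------------------------------------------------
# allelic RNA counts
# ---------------------------------------------------------------------------

def _nb_draw(rng, mean: float, dispersion: float, size: int) -> np.ndarray:
    if dispersion <= 0:
        return rng.poisson(mean, size=size)
    r = 1.0 / dispersion
    return rng.negative_binomial(r, r / (r + mean), size=size)


def simulate_allelic_counts(config: SimulationConfig, variants: pd.DataFrame,
                            genes: pd.DataFrame,
                            rng: np.random.Generator | None = None):
    """Simulate allele-resolved RNA read counts at PSNPs inside genes.

    Biased genes (fraction ``aei_fraction``, direction fair) have expected
    maternal:paternal ratio ``aei_fold`` (or its inverse) with the total
    held at ``2 * rna_mean``; counts are negative-binomial per PSNP per
    allele.  Genes without a PSNP are excluded (logged).  Returns
    ``(allele_depth_frame, gene_truth_frame)``.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 2)
    rows = []
    truth_rows = []
    v_by_chrom = {c: sub for c, sub in variants.groupby("chrom")}
    n_skipped = 0
    for g in genes.itertuples(index=False):
        sub = v_by_chrom.get(g.chrom)
        psnp_pos = np.array([], dtype=np.int64)
        if sub is not None:
            within = (sub["pos"] >= g.start) & (sub["pos"] <= g.end)
            psnp_pos = sub.loc[within, "pos"].to_numpy()
        if len(psnp_pos) == 0:
            n_skipped += 1
            continue
        biased = rng.random() < config.aei_fraction
        fold = config.aei_fold
        if biased:
            maternal_up = rng.random() < 0.5
            ratio = fold if maternal_up else 1.0 / fold
            klass = "MATERNAL_BIAS" if maternal_up else "PATERNAL_BIAS"
        else:
            ratio = 1.0
            klass = "NONE"
        mu_m = 2 * config.rna_mean * ratio / (1 + ratio)
        mu_p = 2 * config.rna_mean - mu_m
        mat = _nb_draw(rng, mu_m, config.rna_dispersion, len(psnp_pos))
        pat = _nb_draw(rng, mu_p, config.rna_dispersion, len(psnp_pos))
        for p, m_reads, p_reads in zip(psnp_pos, mat, pat):
            rows.append((g.chrom, int(p), int(m_reads), int(p_reads), "f1"))
        truth_rows.append((g.gene_id, klass, mu_m, mu_p))
    if n_skipped:
        logger.info("simulate_allelic_counts: %d genes without PSNPs excluded",
                    n_skipped)
    depths = pd.DataFrame(rows, columns=fio.ALLELE_DEPTH_COLUMNS)
    truth = pd.DataFrame(truth_rows,
                         columns=["gene_id", "klass", "mu_maternal", "mu_paternal"])
    return depths, truth


# ---------------------------------------------------------------------------
# dataset emission
# ---------------------------------------------------------------------------

def emit_dataset(config: SimulationConfig, out_dir: str | Path,
                 force: bool = False) -> dict:
    """Simulate everything and write the dataset + ground truth to a directory.

    Refuses to write into an existing non-empty directory unless ``force``.
    Returns the manifest (also written as ``manifest.json``).
    """
    out = Path(out_dir)
    if out.exists() and any(out.iterdir()) and not force:
        raise FileExistsError(f"{out} exists and is not empty (use force)")
    out.mkdir(parents=True, exist_ok=True)

    rng = np.random.default_rng(config.seed)
    genomes, variants, genes = simulate_parental_genomes(config, rng)
    meth = simulate_methylomes(config, genomes, variants, rng)
    depths, gene_truth = simulate_allelic_counts(config, variants, genes, rng)
    truth: GroundTruth = meth["truth"]
    truth.genes = gene_truth

    fio.write_meth_table(meth["mother"], out / "mother.meth.tsv")
    fio.write_meth_table(meth["father"], out / "father.meth.tsv")
    fio.write_meth_table(meth["f1"], out / "f1.meth.tsv")
    fio.write_meth_table(meth["lambda"], out / "lambda.meth.tsv")
    fio.write_allele_meth_table(meth["f1_allele"], out / "f1_allele.meth.tsv")
    fio.write_gene_table(genes, out / "genes.tsv")
    fio.write_allele_depth_table(depths, out / "allele_depths.tsv")

    vcf_df = variants.assign(
        gt_mother=fio.HOM_REF, gt_father=fio.HOM_ALT, gt_f1=fio.HET,
        dp_mother=-1, dp_father=-1, dp_f1=-1)
    contigs = {c: config.chrom_length for c in genomes}
    fio.write_vcf_minimal(vcf_df, ["mother", "father", "f1"], contigs,
                          out / "trio.vcf")

    truth.sites.to_csv(out / "truth_sites.tsv", sep="\t", index=False)
    truth.regions.to_csv(out / "truth_regions.tsv", sep="\t", index=False)
    truth.psms.to_csv(out / "truth_psms.tsv", sep="\t", index=False)
    truth.genes.to_csv(out / "truth_genes.tsv", sep="\t", index=False)
    config.to_yaml(out / "config.yaml")

    manifest = {"files": {}}
    for name, df in [("mother.meth.tsv", meth["mother"]),
                     ("father.meth.tsv", meth["father"]),
                     ("f1.meth.tsv", meth["f1"]),
                     ("lambda.meth.tsv", meth["lambda"]),
                     ("f1_allele.meth.tsv", meth["f1_allele"]),
                     ("genes.tsv", genes),
                     ("allele_depths.tsv", depths),
                     ("trio.vcf", variants),
                     ("truth_sites.tsv", truth.sites),
                     ("truth_regions.tsv", truth.regions),
                     ("truth_psms.tsv", truth.psms),
                     ("truth_genes.tsv", truth.genes)]:
        manifest["files"][name] = int(len(df))
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
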