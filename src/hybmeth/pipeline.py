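"""End-to-end orchestration of the analysis stages.

``run_all`` drives simulate -> profile -> DMR -> DMS -> allelic -> PSMS ->
integrate on one output directory, writing every intermediate as a TSV
re-readable by :mod:`hybmeth.formats_io` plus a run manifest with stage
row counts and parameters.  All randomness flows from the simulation
config seed, so a rerun with the same config reproduces every numeric
output byte for byte (no timestamps are written).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import allelic, dmr, dms, integrate, profile, psms, simulate
from . import formats_io as fio

logger = logging.getLogger(__name__)

CONTEXTS_ANALYZED = ("CG", "CHG", "CHH")


@dataclass
class PipelineConfig:
    """Stage parameters for a full run on a simulated dataset."""

    simulation: simulate.SimulationConfig = field(
        default_factory=simulate.SimulationConfig)
    fail_rate: float | None = None  # None: use the simulated conversion failure
    mc_alpha: float = 0.05
    min_cov: int = 4
    window_bp: int = 1000
    step_bp: int = 100
    min_sites: int = 5
    dmr_max_p: float = 0.05
    dmr_min_fold: float = 2.0
    dms_alpha: float = 0.01
    bias_fold_threshold: float = 1.5
    bias_alpha: float = 0.05
    psms_alpha: float = 0.05
    flank_bp: int = 2000
    dmr_contexts: tuple = ("CG",)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["simulation"]["beta_params"] = {
            k: list(v) for k, v in d["simulation"]["beta_params"].items()}
        d["dmr_contexts"] = list(self.dmr_contexts)
        return d


def run_all(config: PipelineConfig, out_dir: str | Path,
            force: bool = False) -> dict:
    """Run every stage; returns the manifest (also written to manifest.json)."""
    out = Path(out_dir)
    stages: dict[str, dict] = {}

    def done(name, **counts):
        stages[name] = {k: int(v) for k, v in counts.items()}
        logger.info("stage %s complete: %s", name, stages[name])

    # 1. simulate
    data_dir = out / "data"
    sim_manifest = simulate.emit_dataset(config.simulation, data_dir, force=force)
    done("simulate", **{k: v for k, v in sim_manifest["files"].items()
                        if k.endswith(".tsv") or k.endswith(".vcf")})

    mother = fio.read_meth_table(data_dir / "mother.meth.tsv")
    father = fio.read_meth_table(data_dir / "father.meth.tsv")
    f1 = fio.read_meth_table(data_dir / "f1.meth.tsv")
    lam = fio.read_meth_table(data_dir / "lambda.meth.tsv")
    f1_allele = fio.read_allele_meth_table(data_dir / "f1_allele.meth.tsv")
    genes = fio.read_gene_table(data_dir / "genes.tsv")
    depths = fio.read_allele_depth_table(data_dir / "allele_depths.tsv")
    variants, _ = fio.read_vcf_minimal(data_dir / "trio.vcf")

    fail = config.fail_rate
    if fail is None:
        fail = config.simulation.conversion_failure

    res_dir = out / "results"
    res_dir.mkdir(parents=True, exist_ok=True)

    # 2. profile
    prof = profile.profile_summary(
        {"mother": mother, "father": father, "f1": f1}, lam,
        fail_rate=fail, alpha=config.mc_alpha, min_cov=config.min_cov)
    for name, df in prof.items():
        df.to_csv(res_dir / f"profile_{name}.tsv", sep="\t", index=False)
    done("profile", conversion_rate_rows=len(prof.get("conversion_rate", [])),
         context_rows=len(prof["context_proportions"]))

    # 3. DMR + inheritance
    dmr_frames = []
    venn_frames = []
    call_frames = []
    for ctx in config.dmr_contexts:
        kw = dict(window_bp=config.window_bp, step_bp=config.step_bp,
                  min_sites=config.min_sites, min_cov=config.min_cov,
                  max_p=config.dmr_max_p, min_fold=config.dmr_min_fold)
        parental = dmr.call_dmrs(mother, father, ctx, **kw)
        f1_vs_father = dmr.call_dmrs(f1, father, ctx, **kw)
        f1_vs_mother = dmr.call_dmrs(f1, mother, ctx, **kw)
        calls, venn = dmr.classify_dmr_inheritance(parental, f1_vs_father,
                                                   f1_vs_mother)
        dmr_frames.append(parental.assign(comparison="mother_vs_father"))
        dmr_frames.append(f1_vs_father.assign(comparison="f1_vs_father"))
        dmr_frames.append(f1_vs_mother.assign(comparison="f1_vs_mother"))
        call_frames.append(calls.assign(context=ctx))
        venn_frames.append(venn.assign(context=ctx))
    def _cat(frames, fallback_cols):
        kept = [f for f in frames if len(f)]
        if not kept:
            return pd.DataFrame(columns=fallback_cols)
        return pd.concat(kept, ignore_index=True)

    all_dmrs = _cat(dmr_frames, [*dmr.DMR_COLUMNS, "comparison"])
    all_calls = _cat(call_frames, [*dmr.DMR_COLUMNS, "category", "context"])
    all_dmrs.to_csv(res_dir / "dmrs.tsv", sep="\t", index=False)
    all_calls.to_csv(res_dir / "dmr_inheritance.tsv", sep="\t", index=False)
    pd.concat(venn_frames, ignore_index=True).to_csv(
        res_dir / "dmr_venn.tsv", sep="\t", index=False)
    parental_all = all_dmrs[all_dmrs["comparison"] == "mother_vs_father"]
    if len(parental_all):
        bed = parental_all.assign(
            name=parental_all["context"],
            score=-np.log10(np.maximum(parental_all["p_value"], 1e-300)),
            strand=".")
        fio.write_bed(bed, res_dir / "dmrs_parental.bed")
    done("dmr", dmrs=len(all_dmrs), inheritance_calls=len(all_calls))

    # 4. DMS
    dms_table = dms.call_dms(father, mother, f1, min_cov=config.min_cov,
                             alpha=config.dms_alpha)
    dms_table.to_csv(res_dir / "dms.tsv", sep="\t", index=False)
    if len(dms_table):
        props = dms.dms_class_proportions(dms_table)
        props.to_csv(res_dir / "dms_proportions.tsv", sep="\t", index=False)
    done("dms", dms=len(dms_table))

    # 5. allelic expression
    psnps = allelic.identify_psnps(variants, genes)
    gene_counts = allelic.aggregate_allele_counts(depths, psnps)
    bias = allelic.call_allelic_bias(gene_counts,
                                     fold_threshold=config.bias_fold_threshold,
                                     alpha=config.bias_alpha)
    bias.to_csv(res_dir / "allelic_bias.tsv", sep="\t", index=False)
    total = bias["norm_maternal"] + bias["norm_paternal"]
    reg_m = allelic.allelic_total_regression(bias["norm_maternal"], total)
    reg_p = allelic.allelic_total_regression(bias["norm_paternal"], total)
    pd.DataFrame([{"allele": "maternal", **reg_m},
                  {"allele": "paternal", **reg_p}]).to_csv(
        res_dir / "allelic_regression.tsv", sep="\t", index=False)
    done("allelic", psnps=len(psnps), genes_tested=len(bias),
         biased=int((bias["klass"] != allelic.NO_BIAS).sum()))

    # 6. PSMS
    psms_table = psms.identify_psms(variants, mother, father, f1, f1_allele,
                                    fail_rate=fail, alpha=config.psms_alpha)
    psms_table.to_csv(res_dir / "psms.tsv", sep="\t", index=False)
    assigned = psms.assign_psms_to_genes(psms_table, genes,
                                         flank_bp=config.flank_bp)
    assigned.to_csv(res_dir / "psms_genes.tsv", sep="\t", index=False)
    done("psms", psms=len(psms_table), assignments=len(assigned))

    # 7. integrate
    gene_table = integrate.build_gene_table(assigned, f1_allele, bias)
    gene_table.to_csv(res_dir / "integration.tsv", sep="\t", index=False)
    summaries = {}
    for origin in ("mother", "father"):
        try:
            summaries[f"crosstab_{origin}"] = integrate.cross_tabulate(
                gene_table, origin)
        except ValueError:
            pass
    summaries["coregulation"] = integrate.coregulation_sets(gene_table)
    summaries["monoallelic"] = integrate.monoallelic_summary(gene_table)
    for name, df in summaries.items():
        df.to_csv(res_dir / f"integration_{name}.tsv", sep="\t", index=False)
    done("integrate", genes=len(gene_table))

    manifest = {"stages": stages, "parameters": config.to_dict()}
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
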