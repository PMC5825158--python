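"""End-to-end orchestration: simulate/load -> qc -> rates -> diversity -> selection -> gwas."""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, association, diversity, lineage_qc, rates, selection
from .io_core import (
    HerbclockError,
    PhenotypeTable,
    read_annotations,
    read_phenotypes,
    read_sample_meta,
    read_vcf,
    classify_sites,
    write_sample_meta,
    write_vcf,
    write_phenotypes,
)
from .synthetic_data import SimConfig, simulate_lineage, simulate_phenotypes

log = logging.getLogger(__name__)

REPORT_SCHEMA_VERSION = 1


@dataclasses.dataclass
class RunConfig:
    """Configuration for a full analysis run (paths or a simulation block)."""

    out_dir: str = "herbclock_out"
    seed: int = 0
    vcf: str | None = None
    meta: str | None = None
    annotations: str | None = None
    annotation_dialect: str = "gff3"
    phenotypes: str | None = None
    simulate: dict | None = None
    stages: list[str] = dataclasses.field(
        default_factory=lambda: ["qc", "rate", "diversity", "selection", "gwas"]
    )
    maf_min: float = 0.05
    frequency_cutoff: float = 0.05
    n_boot: int = 1000
    n_perm: int = 1000
    generation_time: float = 1.3
    min_call_rate: float = 0.8

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        fields = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - fields
        if unknown:
            raise HerbclockError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def _load_inputs(config: RunConfig, out: Path):
    if config.simulate is not None:
        sim_kwargs = dict(config.simulate)
        sim_kwargs.setdefault("seed", config.seed)
        years = sim_kwargs.pop("sample_years", None)
        if years is not None:
            sim_kwargs["sample_years"] = [(int(y), str(e)) for y, e in years]
        sc = SimConfig(**sim_kwargs)
        v, meta, truth = simulate_lineage(sc)
        pheno, ptruth = (None, None)
        if "gwas" in config.stages:
            pheno, ptruth = simulate_phenotypes(v, sc)
        write_vcf(v, out / "simulated.vcf")
        write_sample_meta(meta, out / "simulated_meta.tsv")
        if pheno is not None:
            write_phenotypes(pheno, out / "simulated_phenotypes.tsv")
        truth_blob = truth.to_dict()
        if ptruth is not None:
            truth_blob["phenotype"] = ptruth.to_dict()
        (out / "simulated_truth.json").write_text(json.dumps(truth_blob, indent=1))
        return v, meta, pheno
    if not config.vcf or not config.meta:
        raise HerbclockError("either a simulate block or vcf+meta paths are required")
    meta = read_sample_meta(config.meta)
    v = read_vcf(config.vcf, meta)
    if config.annotations:
        amap = read_annotations(config.annotations, config.annotation_dialect)
        v = classify_sites(v, amap)
    pheno = read_phenotypes(config.phenotypes, meta) if config.phenotypes else None
    return v, meta, pheno


def run_full_analysis(config: RunConfig) -> dict:
    """Execute the configured stages in dependency order; return the report."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "herbclock_version": __version__,
        "seed": config.seed,
        "stages": {},
    }
    v, meta, pheno = _load_inputs(config, out)
    if v.n_samples == 0 or not meta:
        raise HerbclockError("empty sample set")
    total_bp = v.accessible_length.get("total")

    def stage(name):
        return name in config.stages

    if stage("qc"):
        t0 = time.time()
        d = lineage_qc.pairwise_distance_matrix(v, meta)
        d.to_frame().to_csv(out / "distances.tsv", sep="\t")
        newick = lineage_qc.nj_tree(d) if v.n_samples >= 3 else None
        if newick:
            (out / "nj_tree.nwk").write_text(newick + "\n")
        n_bad, flagged = lineage_qc.four_gamete_screen(v)
        qc_block = {
            "incompatible_pairs": n_bad,
            "flagged_samples": flagged,
            "runtime_s": round(time.time() - t0, 3),
        }
        if total_bp:
            qc_block["min_identity_pct"] = lineage_qc.identity_summary(d, int(total_bp))
        report["stages"]["qc"] = qc_block

    if stage("rate"):
        t0 = time.time()
        if not total_bp:
            raise HerbclockError("rate stage needs a total accessible length")
        pairs = rates.net_distance_pairs(v, meta)
        est = rates.fit_rate(pairs, total_bp, n_boot=config.n_boot, seed=config.seed)
        gen = rates.per_generation_rate(est, config.generation_time)
        d_per_site = rates.mean_pairwise_distance_per_site(v, total_bp)
        mean_year = float(np.mean([m.year for m in meta]))
        tmrca_len, root_year = rates.estimate_tmrca(d_per_site, est.point, mean_year)
        block = {
            "rate_per_site_year": est.point,
            "ci95": [est.ci_low, est.ci_high],
            "slope_snps_per_year": est.slope,
            "intercept": est.intercept,
            "n_pairs": len(pairs),
            "rate_per_site_generation": gen.point,
            "generation_ci95": [gen.ci_low, gen.ci_high],
            "generation_time_years": config.generation_time,
            "tmrca_years": tmrca_len,
            "root_year": root_year,
            "units": "substitutions per site",
            "runtime_s": round(time.time() - t0, 3),
        }
        classes = sorted(set(v.sites["annotation_class"]) & set(v.accessible_length))
        if classes:
            per_class = rates.stratify_rates(v, meta, classes,
                                             n_boot=config.n_boot, seed=config.seed)
            block["per_class"] = {
                c: {"rate": r.point, "ci95": [r.ci_low, r.ci_high]}
                for c, r in per_class.items()
            }
        report["stages"]["rate"] = block
        pairs.to_csv(out / "net_distance_pairs.tsv", sep="\t", index=False)

    sfs = None
    if stage("diversity") or stage("selection"):
        sfs = diversity.unfolded_sfs(v, meta, min_call_rate=config.min_call_rate)

    if stage("diversity"):
        t0 = time.time()
        summary = diversity.diversity_summary(v, total_bp)
        summary["units"] = "per accessible site"
        summary["runtime_s"] = round(time.time() - t0, 3)
        report["stages"]["diversity"] = summary
        sfs.to_frame().to_csv(out / "sfs.tsv", sep="\t", index=False)

    if stage("selection"):
        t0 = time.time()
        contrasts = {}
        for cls in ("intergenic", "intronic", "noncoding"):
            try:
                dep = selection.annotation_depletion_test(v, "coding", cls)
                freq = selection.frequency_class_test(sfs, "coding", cls,
                                                     cutoff=config.frequency_cutoff)
                ks_d, ks_p = selection.sfs_ks_test(
                    sfs.class_frequencies("coding"), sfs.class_frequencies(cls),
                    n_boot=min(config.n_boot, 2000), seed=config.seed,
                )
                contrasts[f"coding_vs_{cls}"] = {
                    "depletion_or": dep.odds_ratio,
                    "depletion_p": dep.p_value,
                    "frequency_or": freq.odds_ratio,
                    "frequency_p": freq.p_value,
                    "ks_d": ks_d,
                    "ks_p": ks_p,
                }
            except HerbclockError as e:
                contrasts[f"coding_vs_{cls}"] = {"error": str(e)}
        report["stages"]["selection"] = {
            "contrasts": contrasts,
            "frequency_cutoff": config.frequency_cutoff,
            "runtime_s": round(time.time() - t0, 3),
        }

    if stage("gwas"):
        t0 = time.time()
        if pheno is None:
            raise HerbclockError("gwas stage needs phenotypes (file or simulate block)")
        traits = pheno.traits()
        gwas_block = {}
        for trait in traits:
            means = pheno.accession_means(trait)
            keep = [s for s in v.samples if s in means.index]
            sub = v.subset_samples(keep)
            y = means.loc[keep].to_numpy()
            K = association.kinship_matrix(sub, maf_min=config.maf_min)
            h2 = association.chip_heritability(y, K)
            res = association.associate(
                y, sub, n_perm=config.n_perm, n_phenos=len(traits),
                seed=config.seed, maf_min=config.maf_min,
            )
            res.to_csv(out / f"gwas_{trait}.tsv", sep="\t", index=False)
            gwas_block[trait] = {
                "h2": h2.h2,
                "h2_lrt_p": h2.lrt_p,
                "n_snps": len(res),
                "n_hits_permutation": int(res["passes_permutation"].sum()),
                "n_hits_double_bonferroni": int(res["passes_double_bonferroni"].sum()),
                "permutation_threshold": res.attrs["permutation_threshold"],
                "bonferroni_threshold": res.attrs["bonferroni_threshold"],
            }
        gwas_block["runtime_s"] = round(time.time() - t0, 3)
        report["stages"]["gwas"] = gwas_block

    (out / "report.json").write_text(json.dumps(report, indent=1, default=float))
    return report
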