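# herbclock

Population-genomic analysis of quasi-clonal selfing lineages sampled through
time: tip-dated substitution-rate estimation by net-distance regression,
founding-date (TMRCA) inference, annotation-stratified rates,
purifying-selection tests on the unfolded site frequency spectrum, and
mutation-driven trait association with a permutation null — all exercisable
on synthetic data from a bundled dated-lineage simulator.

## What it does

Given haploid/homozygous SNP calls against a lineage pseudo-reference (VCF),
dated sample metadata, genome annotations (GFF3/BED) and phenotypes, the
pipeline runs:

1. **lineage_qc** — pairwise SNP distances, neighbor-joining tree,
   four-gamete recombinant screen, minimum percent-identity summary.
2. **rates** — net genetic distances `D'_ij = D_ic − D_jc` between modern
   and herbarium samples regressed on collection-time deltas
   (`D' = a + bT'`); slope / accessible length = substitutions site⁻¹ yr⁻¹,
   with bootstrap CIs, per-annotation stratification, generation-time
   rescaling (default 1.3 yr/gen) and TMRCA via `d = 2Lμ`. Also a
   mutation-accumulation-line rate estimator.
3. **diversity** — Watterson's θ, π, Tajima's D, and the unfolded SFS
   oriented by order of first appearance in dated herbarium samples.
4. **selection** — one-tailed Fisher tests on bp-vs-SNP and 5%-cutoff
   frequency-class contingency tables, plus bootstrap two-sample
   Kolmogorov–Smirnov comparisons of cumulative spectra.
5. **association** — MAF>5% kinship matrix, REML chip heritability
   (`y = Zu + ε`), single-SNP GWA (`y = Xb + ε`) with a 1,000-permutation
   empirical null and double-Bonferroni threshold, LD statistics
   (r², D, D′) and Grantham amino-acid distance scoring.
6. **synthetic_data** — a simulator of dated selfing lineages (star,
   growth-coalescent or forward Wright–Fisher genealogies with seed-bank
   generation intervals), phenotypes at a target heritability, MA lines and
   climate covariates, with full ground truth recorded for estimator
   scoring.

## CLI

Every stage is a subcommand of `herbclock`:

```bash
# generate a synthetic dated-lineage dataset (VCF + metadata + phenotypes + truth)
herbclock simulate --seed 1 --out sim/

# quasi-clonality checks
herbclock qc --vcf sim/simulated.vcf --meta sim/simulated_meta.tsv --out qc/

# substitution rate, generation rescaling, TMRCA
herbclock rate --vcf sim/simulated.vcf --meta sim/simulated_meta.tsv \
    --accessible-bp 1.08e8 --boot 1000 --seed 1 --out rate.json

# diversity statistics and the unfolded SFS
herbclock diversity --vcf ... --meta ... --accessible-bp 1.08e8 --out div/

# purifying-selection contrasts
herbclock selection --vcf ... --meta ... --annotations genes.gff3 --out sel.json

# heritability + permutation GWA
herbclock gwas --vcf ... --meta ... --pheno phenos.tsv --perms 1000 --seed 1 --out gwas/

# full pipeline from one YAML config
herbclock all --config run.yaml
```

A `run.yaml` can either point at input files (`vcf`, `meta`, `annotations`,
`phenotypes`) or contain a `simulate:` block of simulator settings; see
`herbclock.pipeline.RunConfig` for all keys.

## File formats

- genotypes: VCF 4.x, haploid or homozygous-diploid GT (heterozygotes are
  fatal by default — the lineage is selfing — or downgraded to missing with
  `het_policy="missing"`);
- annotations: GFF3 (1-based closed) or BED (0-based half-open, converted on
  read); overlaps resolved by precedence coding > UTR > intronic >
  transposon > pseudogene; unannotated positions are intergenic;
- sample metadata / phenotypes: TSV
  (`sample_id year latitude longitude era`, `sample_id trait replicate value`);
- outputs: TSV and JSON (report schema is versioned).
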