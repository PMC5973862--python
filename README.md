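# lrldkit

Toolkit for long-range linkage-disequilibrium (LRLD) analysis of
case-control SNP data, built around the APOE region workflow:

- **PLINK I/O** — read/write PLINK v1 `.bed/.bim/.fam` filesets, per-marker
  statistics (MAF, call rate, exact Hardy-Weinberg test) and marker/sample
  filters (`lrldkit.genotype_io`).
- **Two-locus LD** — EM haplotype-frequency estimation from unphased
  genotypes; signed D, D', r², and the df=1 chi-square LD test
  (χ² = 2·N·r²); greedy LD pruning (`lrldkit.ld_core`).
- **LRLD procedures** — the D' ≥ 0.2 & p < 0.05 call rule, a MAF-matched
  bootstrap null (empirical p against B random markers with MAF in
  [0.20, 0.40] off the index chromosome), a sliding-window chromosome LD
  profile (1.7 Mb windows, 0.1 Mb step, pair separation 50–500 kb,
  MAF ≥ 0.2), and an ε2-carrier Bonferroni marker scan
  (`lrldkit.lrld_scan`).
- **APOE strata** — ε diplotype calls from rs429358/rs7412 under an absent
  ε1 (T–T) haplotype, and the ε2-carrier / ε4-carrier / ε3ε3 strata with
  ε2ε4 exclusion (`lrldkit.apoe_strata`).
- **Association** — allelic 2×2 test with Wald OR/CI (Haldane correction on
  zero cells), additive logistic regression via IRLS with sex/age/ε4
  covariates, per-stratum association (`lrldkit.association`).
- **Meta-analysis** — CI→SE conversion, inverse-variance fixed effects,
  Cochran's Q / I², DerSimonian-Laird random effects, and the
  model-selection rule (random iff I² > 50% and Q p < 0.05)
  (`lrldkit.meta_analysis`).
- **Structure diagnostics** — mean Wright's F = 1 − Ho/He with the standard
  filters, and PCA on an LD-pruned, standardized genotype matrix
  (`lrldkit.population_structure`).
- **Synthetic data** — genotype simulator with exact-target-D' haplotype
  blocks, an APOE-like two-SNP block with the T–T haplotype absent,
  background markers under HWE, and case/control labels from an additive
  logistic model (`lrldkit.synthetic_data`).

## Command line

All subcommands write headered TSV (stdout or `--out`):

```sh
lrldkit simulate   --config sim.yaml --out-prefix data/study
lrldkit ld-pair    --bfile data/study --snp1 rs429358 --snp2 rs7412
lrldkit ld-scan    --bfile data/study --chrom 19 --window-bp 1700000 --step-bp 100000
lrldkit lrld-null  --bfile data/study --anchor rs7412 --target rs3865444 \
                   --b 10000 --maf-min 0.2 --maf-max 0.4 --seed 7
lrldkit apoe-call  --bfile data/study
lrldkit assoc      --bfile data/study --snp rs3865444 --stratify
lrldkit meta       --input studies.tsv --model auto
lrldkit inbreeding --bfile data/study
lrldkit pca        --bfile data/study --n-components 10 --prune-r2 0.3
lrldkit run        --config pipeline.yaml   # full pipeline, one YAML
```

`studies.tsv` needs columns `label`, `or`, `ci_low`, `ci_high`. The
pipeline YAML takes `bfile`, `out_dir` and optional `apoe`, `ld_pairs`,
`scan`, `bootstrap`, `assoc`, `meta_input`, `inbreeding`, `pca` sections
(see `lrldkit.pipeline.PipelineConfig`); defaults follow the standard
thresholds above. Runs are deterministic given their seeds.

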