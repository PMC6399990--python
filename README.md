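# prstrat

An APOE-stratified polygenic risk score (PRS) analysis pipeline for
case/control cohorts, with a built-in synthetic cohort generator so every
stage is testable end to end without external data.

Stages (each is an importable module and a CLI subcommand):

| module | role |
|---|---|
| `prstrat.simulate` | block-LD cohort simulator (Gaussian-copula haplotypes, APOE locus, liability model, imputation-style probability blur) and discovery summary-statistic simulation with configurable test-sample overlap |
| `prstrat.genio` | Oxford GEN/SAMPLE and summary-statistic TSV IO, hard-calling (max probability > 0.9), Info/MAF QC filters |
| `prstrat.gwas` | per-SNP logistic regression (IRLS, Wald tests) with sex/PC covariates; PCA of the dosage matrix |
| `prstrat.clumping` | p-value-ordered greedy LD pruning (r² ≤ 0.1 within ±500 kb by default) |
| `prstrat.prs` | allele alignment, p-value-threshold SNP selection, APOE-region exclusion, score standardization and PC residualization |
| `prstrat.stratify` | APOE genotype classification from rs429358/rs7412 dosages; cohort strata (all / non-E4 / E3E3 / E4 carriers / E4-or-E2 carriers) |
| `prstrat.evaluate` | Mann–Whitney AUC, DeLong confidence intervals, in-sample logistic predictors, extreme-tail counts |
| `prstrat.burden` | per-person risk/alternative allele counts and the 2×2 chi-square stratum comparison |
| `prstrat.overlap` | overlap-inflation adjustment: perturb discovery betas with N(β, (c·SE)²) noise and average AUC over replicates |
| `prstrat.pipeline` / `prstrat.cli` | deterministic end-to-end orchestration from a JSON config |

## CLI

```sh
# simulate a cohort + discovery summary statistics
prstrat simulate --config sim.json --seed 1 --out-prefix out/cohort

# QC, clump, score, evaluate, adjust
prstrat qc --gen out/cohort.gen --sample out/cohort.sample \
    --info out/cohort.info.tsv --out-prefix out/qc
prstrat clump --sumstats out/cohort.sumstats.tsv --gen out/qc.gen \
    --sample out/qc.sample --r2 0.1 --window-kb 500 --out out/retained.txt
prstrat score --sumstats out/cohort.sumstats.tsv --gen out/qc.gen \
    --sample out/qc.sample --retained out/retained.txt --p-threshold 0.5 \
    --out out/scores.tsv
prstrat evaluate --scores out/scores.tsv --stratum e3e3 --out out/eval.json
prstrat adjust --sumstats out/cohort.sumstats.tsv --gen out/qc.gen \
    --sample out/qc.sample --retained out/retained.txt \
    --n-sims 1000 --coefficient 0.12 --seed 1 --out out/adjusted.json

# or everything at once
prstrat run-all --config pipeline.json --seed 1 --out out/
```

`run-all` emits the stratified AUC grid (`auc_grid.tsv`, strata ×
{p ≤ 0.001, p ≤ 0.5} × {APOE region included, excluded}), per-status allele
burden tables, extreme-tail counts at ±1.5/±2, an adjusted-AUC report, and
a run manifest. Outputs are byte-identical for identical config + seed.

A minimal pipeline config:

```json
{
  "seed": 1,
  "simulate": {"n_cases": 1000, "n_controls": 1000, "n_snps": 2000,
               "n_causal": 200},
  "adjust": {"n_sims": 1000, "coefficient": 0.12, "stratum": "e3e3"}
}
```

Use `"inputs": {"gen": ..., "sample": ..., "sumstats": ...}` instead of
`"simulate"` to run on existing files.

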