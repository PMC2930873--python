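# genactiv

Gene–physical-activity interaction analysis of BMI and obesity risk.

`genactiv` builds an unweighted genetic predisposition score (0–24 risk
alleles over a 12-SNP panel, with mean substitution for up to three
missing genotypes), derives a four-level physical-activity index from
occupation and daily recreational activity, and fits cross-sectional and
longitudinal regression models testing whether activity attenuates the
per-allele effect on BMI and obesity odds. A synthetic-cohort generator
with a configurable score × activity interaction makes the whole
pipeline testable end to end by parameter recovery.

## Modules

- `genactiv.simulate` — cohort generator: Hardy–Weinberg genotypes,
  phenotypes with a per-allele BMI effect declining linearly in activity
  level, follow-up drift, genotype missingness and dropout; TSV/VCF
  export.
- `genactiv.genotypes` — genotype TSV/VCF readers, HWE chi-square test,
  call-rate/HWE QC filter (strict thresholds: call rate > 0.95,
  HWE p > 0.05), score computation with substitution bookkeeping.
- `genactiv.phenotypes` — activity classification, weekly→daily hours,
  annual changes, BMI categories, ordered exclusion rules (prevalent
  diabetes; missing baseline phenotypes; |ΔBMI| > 2 kg/m²/y or
  |Δwaist| > 7 cm/y where follow-up exists; optional CVD/cancer
  sensitivity rule).
- `genactiv.models` — OLS and logistic fits, adjusted score main
  effects, score × activity interaction tests (ordinal or binary
  coding), stratified per-allele effects with gram conversion at 1.70 m,
  median-dichotomized susceptibility contrasts, per-SNP interaction scan
  with Bonferroni adjustment, rank-based inverse-normal transform,
  longitudinal annual-BMI-change interaction model.
- `genactiv.discrimination` — incremental R², Mann–Whitney rank AUC with
  Hanley–McNeil CI, stratified bootstrap AUC contrast.
- `genactiv.pipeline` / `genactiv.cli` — YAML-configured end-to-end run
  producing a deterministic TSV/JSON report bundle.

## CLI

```sh
# generate a synthetic cohort
genactiv simulate --n 20000 --seed 1 --out cohort/

# QC and scores from a genotype table
genactiv qc --genotypes cohort/genotypes.tsv --snp-sheet cohort/snp_sheet.tsv --out qc.tsv
genactiv score --genotypes cohort/genotypes.tsv --snp-sheet cohort/snp_sheet.tsv --out scores.tsv

# full analysis from a YAML config (file inputs or a simulation block)
genactiv analyze --config run.yaml --seed 1 --out results/

# one-shot simulated report bundle
genactiv report --n 20000 --seed 1 --out results/
```

A minimal `run.yaml`:

```yaml
simulation:
  n_subjects: 20000
  seed: 1
seed: 1
output_dir: results
```

Identical config + seed reproduces the report bundle byte for byte.

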