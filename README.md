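# polymix

Multi-ancestry, multi-trait polygenic score construction and clinical
evaluation, exercised end-to-end on synthetic cohorts. The pipeline:

1. **simcohort** — simulates block-diagonal LD reference panels with
   ancestry divergence, genotype dosages (latent-Gaussian thresholding
   calibrated to the target LD), correlated causal effects across
   ancestries and traits, liability-threshold prevalent disease,
   exponential incident event times, and per-ancestry GWAS summary
   statistics.
2. **shrink** — LD-score-regression heritability, then spike-and-slab
   Gibbs shrinkage of marginal effects over a hyperparameter grid
   (17 causal fractions × 3 heritability scales × sparse-LD on/off =
   102 candidates per GWAS), emitting PGS-Catalog-style scoring files.
3. **score** — allele matching (swap / strand-flip / ambiguous-drop),
   dosage×weight accumulation, PC residualization and per-ancestry
   standardization with persisted training constants.
4. **mix** — best-candidate tuning per GWAS, bidirectional stepwise AIC
   selection, logistic mixing (layer 1 across ancestries within a trait,
   layer 2 across traits), and flattening the two-layer model into a
   single variant-level weight file.
5. **evalrisk** — OR/SD and HR/SD with CIs, Nagelkerke ΔR² and
   liability-scale R², percentile-prevalence tables, tail odds scans,
   risk-equivalence search, Harrell's C, categorical/continuous NRI with
   bootstrap CIs, and the clinical×genetic Cox interaction model with
   standardized 10-year incidence curves.

## CLI

```bash
polymix run config.yaml --out runs/          # full pipeline from a YAML config
polymix run --seed 1                         # default config
polymix validate config.yaml                 # schema-check + print defaults
polymix simulate config.yaml --out runs/     # stop after simulation artifacts
polymix shrink --sumstats ss.tsv --panel panels/EUR --out weights/
polymix score --weights weights/final.tsv --cohort cohorts/validation --out scores.tsv
polymix evaluate --scores scores.tsv --cohort cohorts/validation \
    --prevalence 0.12 --threshold 0.075 --boot 100 --seed 1 --out report/
```

A run directory contains every intermediate artifact (panels, summary
statistics, candidate/tuned/final weight files, mixing models, score
tables, evaluation report) plus `manifest.json` with SHA-256 hashes;
rerunning the same config + seed reproduces the manifest bit-for-bit.

Minimal config (all other keys have defaults; unknown keys are rejected):

```yaml
name: demo
seed: 1
```

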