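# gmspipe

Genotype-stratified analysis linking alcohol consumption, gut microbial
species and insulin resistance, built around a weighted gut microbiome score
`GMS = beta @ Sigma^(-1/2) @ X` (log-fold-change weights applied to
correlation-whitened CLR abundances), plus a synthetic cohort generator so
every stage is verifiable by parameter recovery.

## Modules

| module | what it does |
| --- | --- |
| `gmspipe.synth` | logistic-normal-multinomial cohort simulator with planted genotype-specific species effects, a latent score modifier of the alcohol/insulin-resistance relation, and a `SimTruth` ground-truth record |
| `gmspipe.metabolic` | HOMA-IR / HOMA-B, insulin-resistance classification (cutoff 2.5, inclusive), diabetes exclusion criteria, ordinal alcohol-level coding (0-3) |
| `gmspipe.prep` | prevalence (>20%) / mean-count (>50) species filtering and the centered log-ratio transform (pseudocount 0.5) |
| `gmspipe.diffabund` | per-species log-fold change of abundance per alcohol level within a genotype stratum, with a simplified sampling-fraction bias correction, BH-FDR, and a genotype x alcohol product-term test |
| `gmspipe.score` | score model building (species selected at p<0.05, symmetric inverse-sqrt whitening with eigenvalue floor), per-sample scores, tertile assignment, trend validation |
| `gmspipe.assoc` | logistic trend and category contrasts for insulin resistance, tertile-stratified effects with pooled product-term interaction tests, rank-inverse-normal + HC3 "rank-based robust" regression, per-trait interaction grid |
| `gmspipe.pipeline` | end-to-end orchestration from a YAML config with per-stage logging and a JSON + TSV report |

## CLI

```bash
# simulate a cohort (cohort.tsv, counts.tsv, truth.json)
gmspipe simulate --config sim.yaml --out-dir data/ --seed 1

# stage by stage
gmspipe filter data/counts.tsv --prevalence 0.20 --mean-count 50 --out data/filtered.tsv
gmspipe clr data/filtered.tsv --pseudocount 0.5 --out data/clr.tsv
gmspipe diffabund --counts data/filtered.tsv --cohort data/cohort.tsv \
    --stratum noncarrier --out data/diff.tsv
gmspipe gms build --diff data/diff.tsv --clr data/clr.tsv --out data/model.json
gmspipe gms score --model data/model.json --clr data/clr.tsv --out data/scores.tsv
gmspipe gms validate --scores data/scores.tsv --cohort data/cohort.tsv --stratum noncarrier
gmspipe analyze --cohort data/cohort.tsv --scores data/scores.tsv --out data/interaction.tsv

# everything at once
gmspipe pipeline run --config pipeline.yaml
```

A pipeline config is a YAML mapping of `PipelineConfig` fields:

```yaml
cohort_path: data/cohort.tsv
counts_path: data/counts.tsv
out_dir: results/
covariates: [age, sex, site, smoking, diet_score]
prevalence_min: 0.20
mean_count_min: 50
pseudocount: 0.5
p_cutoff: 0.05
fdr_cutoff: 0.05
ir_cutoff: 2.5
seed: 1
```

## Data layout

* **Cohort table** (TSV, one row per participant): `sample_id`, `genotype`
  (CC/CT/TT), `genotype_group`, `alcohol_level` (0-3), `weekly_drinks`,
  `current_drinker`, covariates (`age`, `sex`, `site`, `smoking`,
  `diet_score`), metabolic measurements (`fasting_glucose` mg/dL,
  `fasting_insulin` mU/L, `hba1c` %, `ogtt_2h_glucose` mg/dL,
  `fasting_time` h, `on_antidiabetic_med`, `self_reported_t2d`, `bmi`,
  `hdl_c`, `ldl_c`, `triglycerides`).
* **Count table** (TSV): species x samples, non-negative integers, first
  column `species_id`.
* **Truth sidecar** (JSON, simulator only): planted log-fold changes per
  stratum, true sampling-fraction offsets, null/non-null species sets,
  per-sample true HOMA-IR and latent modifier.

## Notes on fidelity

The differential-abundance stage is a deliberately simplified bias-corrected
regression: per-sample offsets are the centered mean log counts after
removing per-species baselines (no mixture model over null/non-null taxa, no
structural-zero detection, no small-sample variance correction). Estimated
log-fold changes are therefore centered across modelled species; with few
and/or sign-balanced true effects this bias is negligible, and the
simplification makes the offsets exactly depth-invariant, which the test
suite exploits.
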