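# ohcasim

Synthetic out-of-hospital cardiac arrest (OHCA) registry cohorts and a
simulation harness for studying how complete-case analysis and four
single-imputation methods affect a multivariable logistic association
analysis under MAR (missing-at-random) missingness.

The pipeline has five stages, one module each:

| Stage | Module | What it does |
|---|---|---|
| generate | `ohcasim.synthetic_cohort` | Builds OHCA-like cohorts: *table-faithful* mode reproduces a packaged stratified count table exactly; *model-based* mode draws the binary outcome (bystander CPR) from a logistic model with known coefficients and a calibrated intercept. |
| ampute | `ohcasim.amputer` | Introduces MAR missingness into one of {age, witness type, call time} per affected case, with missingness probability driven by fully observed covariates through a logistic link and a root-found intercept shift that hits the target overall proportion. |
| impute | `ohcasim.imputers` | Four single imputers built from scratch: mean/mode (MM), missingness-indicator (MxI), Gower-distance KNN, and an iterative random-forest imputer (MF). |
| analyse | `ohcasim.association_model` | The fixed logistic model `bcpr ~ alert_issued + age + gender + witness_type + call_time + arrest_location + first_rhythm`, the complete-case path, Wald CIs, AIC and probability-scale RMSE. |
| repeat | `ohcasim.sim_harness` | Repeats ampute → impute → analyse, and summarises bias, empirical SE, and 95% CI coverage per method × term × missingness proportion with Monte-Carlo standard errors. |

Serialization (CSV cohorts, JSON fits, YAML configs) and the CLI live in
`ohcasim.cli_io`.

## CLI

```sh
# 13,274-row cohort reproducing the packaged count table exactly
ohcasim generate --mode table --scale 1 --seed 1 --out cohort.csv

# 20% MAR missingness
ohcasim ampute --in cohort.csv --out amputed.csv --mask-out mask.csv \
    --proportion 0.2 --seed 2

# one imputation method (mm | mxi | mf | knn)
ohcasim impute --method knn --in amputed.csv --out imputed.csv --k 5

# association fit -> JSON
ohcasim fit --in imputed.csv --method knn --out fit.json

# the full repetition loop from a YAML config
ohcasim simulate --config config.yaml --out results/
```

Every command honours `--seed`, writes a provenance record (config hash,
seed, package version) next to its outputs, and exits non-zero with a
one-line diagnostic on error. A minimal `config.yaml` for `simulate`:

```yaml
cohort: {mode: model, n: 13274, seed: 1}
simulation:
  reps: 200
  proportions: [0.3]
  methods: [cc, mm, mxi, mf, knn]
  base_seed: 0
```

Unset keys take the documented defaults; unknown keys are rejected.

## Cohort CSV dialect

Header exactly
`case_id,age,gender,witness_type,arrest_location,call_time,first_rhythm,alert_issued,bcpr`,
lowercase category tokens, empty fields for missing cells, UTF-8, LF line
endings. The missingness-indicator imputer appends an `age_missing` column
and uses an explicit `missing` category level.

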